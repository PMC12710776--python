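"""Exception taxonomy for the FFA quantification pipeline.

Every stage raises a subclass of :class:`FfaError` so batch drivers can
distinguish recoverable per-frame problems (skip and log) from
configuration or study-level failures (abort the series).
"""


class FfaError(Exception):
    """Base class for all pipeline errors."""


# --- image_io ---------------------------------------------------------------

class DecodeError(FfaError):
    """File exists but could not be decoded as an image."""


class FormatError(FfaError):
    """Unsupported file extension / container."""


class MissingTimeError(FfaError):
    """No configured source yielded an acquisition time for a frame."""


class AmbiguousOcrError(FfaError):
    """Two glyph templates matched a timestamp digit almost equally well."""


class EmptyStudyError(FfaError):
    """Study root contains no ingestible frames."""


class DuplicateFrameError(FfaError):
    """Two frames share the same series key and acquisition time."""


# --- preprocess -------------------------------------------------------------

class OverCropError(FfaError):
    """Cropping would leave less than the 64x64 minimum interior."""


class ParameterError(FfaError):
    """A numeric parameter is outside its documented range."""


class FovDetectionError(FfaError):
    """Field-of-view auto-detection found no plausible imaged disk."""


# --- registration -----------------------------------------------------------

class SizeError(FfaError):
    """Image too small for the requested operation."""


class InsufficientFeaturesError(FfaError):
    """Too few keypoints to attempt a transform (e.g. a dark/blink frame)."""


class NoConsensusError(FfaError):
    """RANSAC could not find enough inliers for a trustworthy transform."""


class DegenerateInputError(FfaError):
    """Input carries no usable signal (all-zero spectrum, constant image)."""


class RegistrationFailureError(FfaError):
    """More than half the frames of a series failed to register."""


class EmptySeriesError(FfaError):
    """No registered frames available for projection/quantification."""


# --- segmentation -----------------------------------------------------------

class GridPlacementError(FfaError):
    """ETDRS central disk would be clipped by the image border."""


class ConfigurationError(FfaError):
    """Study configuration missing or inconsistent."""


class OcclusionError(FfaError):
    """A grid region contains zero valid pixels after masking."""


# --- temporal metrics -------------------------------------------------------

class NoCommonTimepointsError(FfaError):
    """Cohort series share no nominal timepoint; cumulative metric undefined."""


class DegenerateProfileError(FfaError):
    """Temporal profile has no positive intensity; decay undefined."""


class UndefinedBaselineError(FfaError):
    """AM baseline <= 0; percent change undefined for the pair."""


# --- stats engine -----------------------------------------------------------

class DegenerateSampleError(FfaError):
    """Constant sample; normality test undefined."""


class SampleSizeError(FfaError):
    """Sample too small for the requested test."""


class NoInformationError(FfaError):
    """All paired differences are zero."""


class AnalysisError(FfaError):
    """Cohort-level analysis cannot proceed (e.g. zero complete pairs)."""
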