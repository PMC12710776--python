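"""Intra-session frame alignment for FFA series.

Two species-dispatched strategies:

* **keypoint** (primates) — FAST corners with orientation-steered binary
  descriptors matched by Hamming distance, similarity transform by
  seeded RANSAC. Fundus cameras rotate/zoom slightly between captures,
  so the transform class is similarity rather than pure translation.
* **frequency** (rodents) — phase correlation (normalized cross-power
  spectrum) recovering pure translation with sub-pixel refinement.
  Murine frames rarely yield enough stable corners for matching.

Frames that fail their strategy's quality gates are excluded with a
reason code rather than silently degrading the series; the maximum
intensity projection (MIP) is then built from registered frames only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform, warp

from .errors import (
    DegenerateInputError,
    EmptySeriesError,
    InsufficientFeaturesError,
    NoConsensusError,
    RegistrationFailureError,
    SizeError,
)
from .image_io import Frame, ImageSeries
from .preprocess import FovMask, detect_fov_mask
from .errors import FovDetectionError

# ---------------------------------------------------------------------------
# transforms

@dataclass
class Transform2D:
    """Similarity (or pure translation) map from moving to reference coords.

    Points are (x, y) = (col, row):  p_ref = scale * R(rotation) @ p_mov + t.
    """

    kind: str = "translation"  # {"translation", "similarity"}
    tx: float = 0.0
    ty: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("translation", "similarity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not (0.5 < self.scale < 2.0):
            raise ValueError(f"scale {self.scale} outside (0.5, 2)")
        for v in (self.tx, self.ty, self.rotation_deg, self.scale):
            if not np.isfinite(v):
                raise ValueError("transform parameters must be finite")
        if self.kind == "translation" and (self.rotation_deg != 0 or self.scale != 1):
            raise ValueError("translation transform must have rotation 0, scale 1")

    @classmethod
    def identity(cls) -> "Transform2D":
        return cls()

    def as_skimage(self) -> SimilarityTransform:
        return SimilarityTransform(
            scale=self.scale,
            rotation=np.deg2rad(self.rotation_deg),
            translation=(self.tx, self.ty),
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map Nx2 (x, y) points from moving into reference coordinates."""
        return self.as_skimage()(np.asarray(points, dtype=float))

    def inverse(self) -> "Transform2D":
        inv = SimilarityTransform(matrix=np.linalg.inv(self.as_skimage().params))
        return Transform2D(
            kind=self.kind,
            tx=float(inv.translation[0]),
            ty=float(inv.translation[1]),
            rotation_deg=float(np.rad2deg(inv.rotation)),
            scale=float(inv.scale),
        )

    def compose(self, first: "Transform2D") -> "Transform2D":
        """Return the transform equivalent to applying *first*, then self."""
        m = self.as_skimage().params @ first.as_skimage().params
        t = SimilarityTransform(matrix=m)
        kind = "translation" if self.kind == first.kind == "translation" else "similarity"
        return Transform2D(
            kind=kind,
            tx=float(t.translation[0]),
            ty=float(t.translation[1]),
            rotation_deg=float(np.rad2deg(t.rotation)),
            scale=float(t.scale),
        )


@dataclass
class Keypoint:
    """A FAST corner: position, response score, optional binary descriptor."""

    x: int
    y: int
    score: float
    descriptor: np.ndarray | None = None  # 32 x uint8 = 256 bits


@dataclass
class FrameRecord:
    index: int
    transform: Transform2D | None
    status: str  # {"registered", "excluded"}
    reason: str = ""
    n_keypoints: int = 0
    n_matches: int = 0
    n_inliers: int = 0
    mean_residual: float = float("nan")
    peak_ratio: float = float("nan")


@dataclass
class RegistrationResult:
    reference_index: int
    records: list[FrameRecord] = field(default_factory=list)

    @property
    def n_registered(self) -> int:
        return sum(1 for r in self.records if r.status == "registered")

    def record_for(self, index: int) -> FrameRecord:
        return next(r for r in self.records if r.index == index)


# ---------------------------------------------------------------------------
# FAST corner detection

# radius-3 Bresenham circle, 16 pixels, clockwise from 12 o'clock; (drow, dcol)
_CIRCLE = [(-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
           (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1)]

DEFAULT_KEYPOINT_CAP = 15000


def fast_score_map(image: np.ndarray, arc_length: int = 9) -> np.ndarray:
    """Segment-test corner score at every interior pixel.

    A pixel is a corner at threshold t iff >= ``arc_length`` contiguous
    circle pixels are all brighter than center+t or all darker than
    center-t. The score is the largest such t (the max over contiguous
    windows of the window's minimum margin); corner(t) <=> score > t.
    Border pixels (within 3 px) score -inf.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if h < 7 or w < 7:
        raise SizeError(f"image {image.shape} too small for FAST (needs >= 7x7)")
    if not (9 <= arc_length <= 12):
        raise ValueError("arc_length must be in [9, 12]")
    center = image[3:h - 3, 3:w - 3]
    margins = np.stack(
        [image[3 + dr:h - 3 + dr, 3 + dc:w - 3 + dc] - center for dr, dc in _CIRCLE]
    )

    def arc_score(m: np.ndarray) -> np.ndarray:
        best = np.full(m.shape[1:], -np.inf)
        for s in range(16):
            window = m[s % 16]
            for k in range(1, arc_length):
                window = np.minimum(window, m[(s + k) % 16])
            best = np.maximum(best, window)
        return best

    score = np.maximum(arc_score(margins), arc_score(-margins))
    full = np.full((h, w), -np.inf)
    full[3:h - 3, 3:w - 3] = score
    return full


def detect_fast(
    image: np.ndarray,
    threshold: float = 0.05,
    arc_length: int = 9,
    cap: int = DEFAULT_KEYPOINT_CAP,
) -> list[Keypoint]:
    """FAST corners with 3x3 non-maximum suppression and a retention cap.

    If more than ``cap`` corners survive suppression, the ``cap``
    highest-scoring are kept (ties broken by row-major position).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    score = fast_score_map(image, arc_length)
    is_corner = score > threshold
    local_max = ndimage.maximum_filter(score, size=3, mode="constant", cval=-np.inf)
    keep = is_corner & (score >= local_max)
    ys, xs = np.nonzero(keep)
    sc = score[ys, xs]
    order = np.lexsort((xs, ys, -sc))  # score desc, then row-major
    order = order[:cap]
    return [Keypoint(x=int(xs[i]), y=int(ys[i]), score=float(sc[i])) for i in order]


# ---------------------------------------------------------------------------
# oriented binary descriptors

_PATCH_RADIUS = 15
# Fixed descriptor sampling pattern: 256 point pairs, packaged as a constant
# table (seeded PCG64 draw, identical on every platform) so that descriptors
# and therefore registrations are machine-independent.
_PATTERN = np.clip(
    np.round(np.random.default_rng(0x0FFA).normal(0.0, 5.0, size=(256, 2, 2))),
    -12, 12,
).astype(int)  # (pair, point, (dx, dy))

_oc_dy, _oc_dx = np.mgrid[-_PATCH_RADIUS:_PATCH_RADIUS + 1,
                          -_PATCH_RADIUS:_PATCH_RADIUS + 1]
_oc_in = (_oc_dx ** 2 + _oc_dy ** 2) <= _PATCH_RADIUS ** 2
_OC_DY, _OC_DX = _oc_dy[_oc_in], _oc_dx[_oc_in]


def _keypoint_arrays(kps: list[Keypoint]) -> tuple[np.ndarray, np.ndarray]:
    return (np.array([k.y for k in kps], dtype=int),
            np.array([k.x for k in kps], dtype=int))


def compute_orientations(image: np.ndarray, kps: list[Keypoint]) -> np.ndarray:
    """Intensity-centroid orientation (radians) over a radius-15 patch."""
    ys, xs = _keypoint_arrays(kps)
    vals = image[ys[:, None] + _OC_DY[None, :], xs[:, None] + _OC_DX[None, :]]
    m10 = (vals * _OC_DX[None, :]).sum(axis=1)
    m01 = (vals * _OC_DY[None, :]).sum(axis=1)
    return np.arctan2(m01, m10)


def compute_descriptors(
    image: np.ndarray, kps: list[Keypoint]
) -> tuple[list[Keypoint], np.ndarray]:
    """Attach 256-bit steered binary descriptors; drops border keypoints.

    Returns the surviving keypoints (with ``descriptor`` set) and the
    packed (N, 32) uint8 descriptor matrix.
    """
    h, w = image.shape
    margin = _PATCH_RADIUS + 13  # patch + max rotated sample offset
    kps = [k for k in kps
           if margin <= k.y < h - margin and margin <= k.x < w - margin]
    if not kps:
        return [], np.empty((0, 32), dtype=np.uint8)
    angles = compute_orientations(image, kps)
    ys, xs = _keypoint_arrays(kps)
    c, s = np.cos(angles), np.sin(angles)
    dx = _PATTERN[:, :, 0][None, :, :]  # (1, 256, 2)
    dy = _PATTERN[:, :, 1][None, :, :]
    rx = np.round(c[:, None, None] * dx - s[:, None, None] * dy).astype(int)
    ry = np.round(s[:, None, None] * dx + c[:, None, None] * dy).astype(int)
    samples = image[ys[:, None, None] + ry, xs[:, None, None] + rx]  # (N, 256, 2)
    bits = samples[:, :, 0] < samples[:, :, 1]
    packed = np.packbits(bits.astype(np.uint8), axis=1)
    for k, d in zip(kps, packed):
        k.descriptor = d
    return kps, packed


def match_hamming(
    d_ref: np.ndarray, d_mov: np.ndarray, ratio: float = 0.8, chunk: int = 512
) -> np.ndarray:
    """Lowe-ratio Hamming matches; rows are (mov_index, ref_index)."""
    if len(d_ref) < 2 or len(d_mov) == 0:
        return np.empty((0, 2), dtype=int)
    out = []
    for start in range(0, len(d_mov), chunk):
        block = d_mov[start:start + chunk]
        dists = np.bitwise_count(
            block[:, None, :] ^ d_ref[None, :, :]
        ).sum(axis=2)
        part = np.argpartition(dists, 1, axis=1)[:, :2]
        rows = np.arange(len(block))[:, None]
        two = dists[rows, part]
        swap = two[:, 0] > two[:, 1]
        part[swap] = part[swap][:, ::-1]
        two[swap] = two[swap][:, ::-1]
        ok = two[:, 0] < ratio * np.maximum(two[:, 1], 1)
        for i in np.nonzero(ok)[0]:
            out.append((start + i, part[i, 0]))
    return np.array(out, dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# similarity estimation (seeded RANSAC)

def _similarity_from_complex(a: complex, b: complex) -> Transform2D:
    return Transform2D(
        kind="similarity",
        tx=float(b.real),
        ty=float(b.imag),
        rotation_deg=float(np.rad2deg(np.angle(a))),
        scale=float(abs(a)),
    )


def estimate_similarity_ransac(
    src: np.ndarray,
    dst: np.ndarray,
    iters: int = 2000,
    inlier_tol: float = 2.0,
    seed: int = 0,
    min_inliers: int = 10,
) -> tuple[Transform2D, np.ndarray, float]:
    """Seeded RANSAC fit of p_dst = a * p_src + b (complex similarity).

    Returns (transform, inlier mask, mean inlier residual). Identical
    inputs and seed give identical output — the reproducibility contract.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 2:
        raise NoConsensusError("need at least 2 correspondences")
    z = src[:, 0] + 1j * src[:, 1]
    wv = dst[:, 0] + 1j * dst[:, 1]
    rng = np.random.default_rng(seed)
    pairs = rng.integers(0, n, size=(iters, 2))
    best_count, best_inliers = 0, None
    for i, j in pairs:
        if i == j or z[i] == z[j]:
            continue
        a = (wv[j] - wv[i]) / (z[j] - z[i])
        if not (0.5 < abs(a) < 2.0):
            continue
        b = wv[i] - a * z[i]
        resid = np.abs(a * z + b - wv)
        inl = resid < inlier_tol
        cnt = int(inl.sum())
        if cnt > best_count:
            best_count, best_inliers = cnt, inl
    if best_inliers is None or best_count < min_inliers:
        raise NoConsensusError(
            f"RANSAC found only {best_count} inliers (< {min_inliers})"
        )
    # least-squares refinement on the consensus set
    zi, wi = z[best_inliers], wv[best_inliers]
    A = np.column_stack([zi, np.ones_like(zi)])
    coef, *_ = np.linalg.lstsq(A, wi, rcond=None)
    a, b = complex(coef[0]), complex(coef[1])
    resid = np.abs(a * z + b - wv)
    inl = resid < inlier_tol
    tform = _similarity_from_complex(a, b)
    return tform, inl, float(resid[inl].mean())


# ---------------------------------------------------------------------------
# strategies

@dataclass
class KeypointParams:
    fast_threshold: float = 0.04
    arc_length: int = 9
    cap: int = DEFAULT_KEYPOINT_CAP
    ratio: float = 0.8
    ransac_iters: int = 2000
    inlier_tol: float = 2.0
    seed: int = 0
    min_keypoints: int = 50
    min_inliers: int = 10
    max_residual: float = 3.0


def register_keypoint(
    reference: Frame | np.ndarray,
    moving: Frame | np.ndarray,
    params: KeypointParams | None = None,
) -> tuple[Transform2D, dict]:
    """ORB-style keypoint registration of *moving* onto *reference*."""
    if params is None:
        params = KeypointParams()
    ref = reference.pixels if isinstance(reference, Frame) else np.asarray(reference)
    mov = moving.pixels if isinstance(moving, Frame) else np.asarray(moving)
    if ref.shape != mov.shape:
        raise SizeError("reference and moving frames must share a shape")
    kp_ref = detect_fast(ref, params.fast_threshold, params.arc_length, params.cap)
    kp_mov = detect_fast(mov, params.fast_threshold, params.arc_length, params.cap)
    if min(len(kp_ref), len(kp_mov)) < params.min_keypoints:
        raise InsufficientFeaturesError(
            f"{len(kp_ref)} reference / {len(kp_mov)} moving keypoints "
            f"(need >= {params.min_keypoints})"
        )
    kp_ref, d_ref = compute_descriptors(ref, kp_ref)
    kp_mov, d_mov = compute_descriptors(mov, kp_mov)
    if min(len(kp_ref), len(kp_mov)) < params.min_keypoints:
        raise InsufficientFeaturesError("too few describable keypoints")
    matches = match_hamming(d_ref, d_mov, ratio=params.ratio)
    if len(matches) < params.min_inliers:
        raise NoConsensusError(f"only {len(matches)} ratio-test matches")
    src = np.array([[kp_mov[i].x, kp_mov[i].y] for i, _ in matches], dtype=float)
    dst = np.array([[kp_ref[j].x, kp_ref[j].y] for _, j in matches], dtype=float)
    tform, inliers, mean_resid = estimate_similarity_ransac(
        src, dst, iters=params.ransac_iters, inlier_tol=params.inlier_tol,
        seed=params.seed, min_inliers=params.min_inliers,
    )
    metrics = {
        "n_keypoints": min(len(kp_ref), len(kp_mov)),
        "n_matches": len(matches),
        "n_inliers": int(inliers.sum()),
        "mean_residual": mean_resid,
    }
    return tform, metrics


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def register_frequency(
    reference: Frame | np.ndarray,
    moving: Frame | np.ndarray,
    upsample_factor: int = 20,
) -> tuple[Transform2D, float]:
    """Phase-correlation translation with sub-pixel refinement.

    Both frames are raised-cosine windowed to suppress edge wrap-around.
    ``peak_ratio`` = highest correlation peak / second-highest
    non-adjacent peak; low values flag unreliable alignments.
    """
    ref = reference.pixels if isinstance(reference, Frame) else np.asarray(reference)
    mov = moving.pixels if isinstance(moving, Frame) else np.asarray(moving)
    if ref.shape != mov.shape:
        raise SizeError("reference and moving frames must share a shape")
    win = _hann2d(ref.shape)
    rw = (ref - ref.mean()) * win
    mw = (mov - mov.mean()) * win
    if rw.std() < 1e-12 or mw.std() < 1e-12:
        raise DegenerateInputError("constant frame: spectrum carries no signal")
    f_ref, f_mov = np.fft.fft2(rw), np.fft.fft2(mw)
    cross = f_ref * np.conj(f_mov)
    mag = np.abs(cross)
    corr = np.real(np.fft.ifft2(cross / np.maximum(mag, 1e-15)))
    flat = np.argmax(corr)
    py, px = np.unravel_index(flat, corr.shape)
    peak = corr[py, px]
    # exclude the 5x5 wrap-aware neighbourhood of the main peak
    masked = corr.copy()
    for dy in range(-2, 3):
        for dx in range(-2, 3):
            masked[(py + dy) % corr.shape[0], (px + dx) % corr.shape[1]] = -np.inf
    second = masked.max()
    peak_ratio = float(peak / max(second, 1e-12)) if second > 0 else float("inf")
    shift, _, _ = phase_cross_correlation(
        rw, mw, upsample_factor=upsample_factor, normalization="phase"
    )
    tform = Transform2D(kind="translation", tx=float(shift[1]), ty=float(shift[0]))
    return tform, peak_ratio


# ---------------------------------------------------------------------------
# series-level registration

@dataclass
class AlignedFrame:
    """A frame resampled into the reference canvas with a validity mask."""

    index: int
    t_acq: float
    pixels: np.ndarray
    valid: np.ndarray


def warp_to_reference(
    pixels: np.ndarray, tform: Transform2D
) -> tuple[np.ndarray, np.ndarray]:
    """Resample *pixels* into reference coordinates (bilinear); returns
    the warped image and a mask of pixels that came from inside the canvas."""
    sk = tform.as_skimage()
    warped = warp(pixels, sk.inverse, order=1, mode="constant", cval=0.0,
                  preserve_range=True)
    ones = warp(np.ones_like(pixels), sk.inverse, order=1, mode="constant",
                cval=0.0, preserve_range=True)
    return warped, ones > 0.999


MIN_BRIGHTNESS = 0.02
MIN_SHARPNESS_RATIO = 0.1
MIN_PEAK_RATIO = 1.5


def _sharpness(px: np.ndarray) -> float:
    return float(ndimage.laplace(px).var())


def register_series(
    series: ImageSeries,
    strategy: str = "auto",
    fov: FovMask | None = None,
    keypoint_params: KeypointParams | None = None,
    min_peak_ratio: float = MIN_PEAK_RATIO,
) -> tuple[RegistrationResult, list[AlignedFrame]]:
    """Register every frame of a series to its brightest frame.

    The reference is the frame with maximal mean intensity inside the
    FOV (the early bright angiographic phase). Quality gates: dark
    frames (mean < 0.02 in FOV) and badly blurred frames (Laplacian
    energy < 10% of the reference's) are excluded up front; keypoint
    failures, residual > 3 px, or peak_ratio < 1.5 exclude a frame with
    the corresponding reason code. More than 50% exclusions fail the
    series.
    """
    if len(series.frames) < 2:
        raise EmptySeriesError("series needs >= 2 frames")
    if strategy == "auto":
        strategy = "frequency" if series.key.species == "mouse" else "keypoint"
    if strategy not in ("keypoint", "frequency"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if keypoint_params is None:
        keypoint_params = KeypointParams()

    if fov is None:
        try:
            fov = detect_fov_mask(series.frames[0])
        except FovDetectionError:
            fov = FovMask(mask=np.ones(series.frames[0].shape, dtype=bool))
    fmask = fov.mask

    means = [float(f.pixels[fmask].mean()) for f in series.frames]
    ref_idx = int(np.argmax(means))
    ref_frame = series.frames[ref_idx]
    ref_sharp = _sharpness(ref_frame.pixels)

    result = RegistrationResult(reference_index=ref_idx)
    aligned: list[AlignedFrame] = []
    for i, frame in enumerate(series.frames):
        if i == ref_idx:
            result.records.append(FrameRecord(
                index=i, transform=Transform2D.identity(), status="registered"))
            aligned.append(AlignedFrame(
                index=i, t_acq=frame.t_acq, pixels=frame.pixels.copy(),
                valid=np.ones(frame.shape, dtype=bool)))
            continue
        if means[i] < MIN_BRIGHTNESS:
            result.records.append(FrameRecord(
                index=i, transform=None, status="excluded",
                reason="insufficient-features (dark frame)"))
            continue
        if ref_sharp > 0 and _sharpness(frame.pixels) < MIN_SHARPNESS_RATIO * ref_sharp:
            result.records.append(FrameRecord(
                index=i, transform=None, status="excluded", reason="blurred"))
            continue
        rec = FrameRecord(index=i, transform=None, status="excluded")
        try:
            if strategy == "keypoint":
                tform, metrics = register_keypoint(ref_frame, frame, keypoint_params)
                rec.n_keypoints = metrics["n_keypoints"]
                rec.n_matches = metrics["n_matches"]
                rec.n_inliers = metrics["n_inliers"]
                rec.mean_residual = metrics["mean_residual"]
                if rec.mean_residual > keypoint_params.max_residual:
                    rec.reason = "high-residual"
                    result.records.append(rec)
                    continue
            else:
                tform, peak_ratio = register_frequency(ref_frame, frame)
                rec.peak_ratio = peak_ratio
                if peak_ratio < min_peak_ratio:
                    rec.reason = "low-peak-ratio"
                    result.records.append(rec)
                    continue
        except InsufficientFeaturesError:
            rec.reason = "insufficient-features"
            result.records.append(rec)
            continue
        except NoConsensusError:
            rec.reason = "no-consensus"
            result.records.append(rec)
            continue
        except DegenerateInputError:
            rec.reason = "degenerate-input"
            result.records.append(rec)
            continue
        rec.transform = tform
        rec.status = "registered"
        result.records.append(rec)
        warped, valid = warp_to_reference(frame.pixels, tform)
        aligned.append(AlignedFrame(index=i, t_acq=frame.t_acq,
                                    pixels=warped, valid=valid))

    n_excluded = len(series.frames) - result.n_registered
    if n_excluded > 0.5 * len(series.frames):
        raise RegistrationFailureError(
            f"{n_excluded}/{len(series.frames)} frames excluded in "
            f"{series.key.label()}"
        )
    return result, aligned


def max_intensity_projection(
    aligned: list[AlignedFrame],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel maximum over registered frames, ignoring invalid pixels.

    Returns (mip, any_valid); pixels valid in no frame are 0 and flagged
    False in ``any_valid``.
    """
    if not aligned:
        raise EmptySeriesError("no registered frames to project")
    stack = np.stack([a.pixels for a in aligned])
    valid = np.stack([a.valid for a in aligned])
    masked = np.where(valid, stack, -np.inf)
    mip = masked.max(axis=0)
    any_valid = valid.any(axis=0)
    mip = np.where(any_valid, mip, 0.0)
    return mip, any_valid
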