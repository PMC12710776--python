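"""Frame preparation ahead of registration and quantification.

Fundus exports often carry machine-information panels, vignetting/shadow
gradients, and resolutions far beyond what registration needs. This
module crops panels, flattens slow illumination with a morphological
white top-hat, bounds image size by area-averaged downscaling, and
locates the circular imaged field of view (FOV) so that all downstream
statistics are restricted to imaged pixels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform

from .errors import FovDetectionError, OverCropError, ParameterError
from .image_io import Frame

MIN_INTERIOR = 64


@dataclass(frozen=True)
class CropSpec:
    """Margins (px) to remove per side, or auto-detection of constant panels."""

    top: int = 0
    bottom: int = 0
    left: int = 0
    right: int = 0
    auto: bool = False

    def __post_init__(self) -> None:
        if min(self.top, self.bottom, self.left, self.right) < 0:
            raise ParameterError("crop margins must be >= 0")


@dataclass
class FovMask:
    """Boolean mask of the imaged circular field of view."""

    mask: np.ndarray

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def _auto_margins(px: np.ndarray, var_tol: float = 1e-6) -> tuple[int, int, int, int]:
    """Maximal border strips whose per-row/column variance is below tolerance."""
    row_var = px.var(axis=1)
    col_var = px.var(axis=0)

    def run(v: np.ndarray) -> int:
        n = 0
        for x in v:
            if x < var_tol:
                n += 1
            else:
                break
        return n

    return run(row_var), run(row_var[::-1]), run(col_var), run(col_var[::-1])


def crop_info_panel(frame: Frame, spec: CropSpec) -> Frame:
    """Remove machine info panels adjacent to the fundus image.

    With ``spec.auto`` the panel is detected as a full-height/width
    constant-intensity border strip (per-line variance < 1e-6).
    """
    px = frame.pixels
    h, w = px.shape
    if spec.auto:
        top, bottom, left, right = _auto_margins(px)
    else:
        top, bottom, left, right = spec.top, spec.bottom, spec.left, spec.right
    if h - top - bottom < MIN_INTERIOR or w - left - right < MIN_INTERIOR:
        raise OverCropError(
            f"crop ({top},{bottom},{left},{right}) leaves less than "
            f"{MIN_INTERIOR}x{MIN_INTERIOR} of a {h}x{w} frame"
        )
    if (top, bottom, left, right) == (0, 0, 0, 0):
        return frame
    cropped = px[top:h - bottom, left:w - right]
    return frame.with_pixels(cropped.copy())


def default_element_radius(shape: tuple[int, int]) -> int:
    """Disk radius for illumination correction: ceil(min(h, w) / 8).

    Large enough to exceed the widest retinal vessel at typical fundus
    resolutions while passing vasculature-scale structure.
    """
    return int(np.ceil(min(shape) / 8))


def correct_illumination(frame: Frame, element_radius: int | None = None) -> Frame:
    """Flatten slow background illumination with a white top-hat.

    Output = frame - morphological opening with a disk of
    ``element_radius``; structures wider than ~2x the radius (shadows,
    vignetting shoulders) are suppressed, vessels and focal leakage pass.
    """
    px = frame.pixels
    if element_radius is None:
        element_radius = default_element_radius(px.shape)
    if element_radius < 1 or element_radius >= min(px.shape) / 2:
        raise ParameterError(
            f"element_radius {element_radius} out of range for shape {px.shape}"
        )
    selem = morphology.disk(element_radius)
    opened = morphology.opening(px, selem)
    out = np.clip(px - opened, 0.0, 1.0)
    return frame.with_pixels(out)


def resize_frame(frame: Frame, max_dim: int = 1024) -> tuple[Frame, float]:
    """Downscale isotropically (area averaging) so max(h, w) == max_dim.

    Returns the resized frame and the applied scale (1.0 when no resize
    was needed). Pixel-scale metadata (µm/px) is divided by the scale so
    physical sizes stay correct.
    """
    if max_dim < MIN_INTERIOR:
        raise ParameterError(f"max_dim must be >= {MIN_INTERIOR}")
    h, w = frame.shape
    if max(h, w) <= max_dim:
        return frame, 1.0
    scale = max_dim / max(h, w)
    out_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
    resized = transform.resize_local_mean(frame.pixels, out_shape)
    resized = np.clip(resized, 0.0, 1.0)
    new_um = None
    if frame.pixel_scale_um is not None:
        new_um = frame.pixel_scale_um / scale
    return frame.with_pixels(resized, pixel_scale_um=new_um), scale


def detect_fov_mask(
    frame: Frame,
    smooth_sigma: float = 8.0,
    min_fraction: float = 0.2,
    override_radius: int | None = None,
) -> FovMask:
    """Locate the imaged circular field against the dark aperture surround.

    Threshold a heavily smoothed copy at Otsu's level, keep the largest
    connected component, fill holes. ``override_radius`` forces a
    centered disk instead (for hardware without a dark surround).
    """
    px = frame.pixels
    h, w = px.shape
    if override_radius is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= override_radius ** 2
        return FovMask(mask=mask)
    smoothed = ndimage.gaussian_filter(px, smooth_sigma)
    if smoothed.max() - smoothed.min() < 1e-6:
        if smoothed.mean() > 0.05:
            return FovMask(mask=np.ones((h, w), dtype=bool))  # all-bright: no surround
        raise FovDetectionError("frame is uniformly dark; no field of view found")
    thr = filters.threshold_otsu(smoothed)
    binary = smoothed > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise FovDetectionError("no connected bright region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    if mask.mean() < min_fraction:
        raise FovDetectionError(
            f"largest bright component covers {mask.mean():.1%} < {min_fraction:.0%}"
        )
    return FovMask(mask=mask)
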