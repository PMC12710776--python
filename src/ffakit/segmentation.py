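"""Macular region partition and regional intensity extraction.

For primates the macula is partitioned with the standard ETDRS grid —
central disk (fovea), inner annulus (parafovea), outer annulus
(perifovea), and everything beyond inside the field of view
(extrafovea). Mice carry no macula, so the whole field of view is the
single analysis region. Large vessels are bright tubes in FFA and would
swamp parenchymal leakage signal; they are masked by a multi-scale
Hessian ridge (Sato) filter at large-vessel scales before averaging.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, morphology

from .errors import ConfigurationError, GridPlacementError, OcclusionError, ParameterError
from .image_io import SeriesKey
from .preprocess import FovMask
from .registration import AlignedFrame

log = logging.getLogger(__name__)

REGION_LABELS = ("fovea", "parafovea", "perifovea", "extrafovea")
ALL_REGIONS = "all_regions"
FOV_REGION = "fov"  # whole-field region used for mice

#: standard ETDRS ring diameters (mm)
DEFAULT_DIAMETERS_MM = (1.0, 3.0, 6.0)
#: fallback fractional radii (of image width) when no pixel scale is known
FALLBACK_RADIUS_FRACTIONS = (0.055, 0.165, 0.33)


@dataclass
class EtdrsGrid:
    """Concentric macular partition around an explicit center.

    Region masks are rasterized by pixel-center-in-region, so the three
    inner regions tile disk(r3) exactly and are pairwise disjoint.
    """

    center: tuple[float, float]  # (x, y) px
    radii_px: tuple[float, float, float]
    pixel_scale_um: float | None
    shape: tuple[int, int]
    masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def region_mask(self, label: str) -> np.ndarray:
        return self.masks[label]


def build_etdrs_grid(
    center: tuple[float, float],
    shape: tuple[int, int],
    pixel_scale_um: float | None = None,
    diameters_mm: tuple[float, float, float] = DEFAULT_DIAMETERS_MM,
) -> EtdrsGrid:
    """Place an ETDRS grid at *center* (x, y) on an image of *shape*.

    Radii are (d/2)*1000/pixel_scale_um px; without a pixel scale the
    standard fallback of fractional image-width radii is used (flagged
    in the log). The central disk must fit fully inside the image.
    """
    h, w = shape
    d1, d2, d3 = diameters_mm
    if not (d1 < d2 < d3):
        raise ParameterError("ETDRS diameters must be strictly increasing")
    if pixel_scale_um is not None:
        if pixel_scale_um <= 0:
            raise ConfigurationError("pixel_scale_um must be positive")
        radii = tuple((d / 2.0) * 1000.0 / pixel_scale_um for d in (d1, d2, d3))
    else:
        log.warning(
            "no pixel scale configured; using fractional fallback radii "
            "%s x image width", FALLBACK_RADIUS_FRACTIONS,
        )
        radii = tuple(f * w for f in FALLBACK_RADIUS_FRACTIONS)
    cx, cy = center
    r1, r2, r3 = radii
    if cx - r1 < 0 or cx + r1 > w - 1 or cy - r1 < 0 or cy + r1 > h - 1:
        raise GridPlacementError(
            f"fovea disk (r={r1:.1f}px) at ({cx:.0f},{cy:.0f}) clipped by "
            f"the {h}x{w} image border"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - cx, yy - cy)
    masks = {
        "fovea": d <= r1,
        "parafovea": (d > r1) & (d <= r2),
        "perifovea": (d > r2) & (d <= r3),
        "extrafovea": d > r3,
    }
    return EtdrsGrid(center=(cx, cy), radii_px=radii,
                     pixel_scale_um=pixel_scale_um, shape=shape, masks=masks)


@dataclass
class VesselMask:
    """Large-vessel pixels to exclude from parenchymal intensity."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ParameterError("vessel mask must be boolean")


DEFAULT_VESSEL_SCALES = (2.0, 3.0, 4.5, 6.0, 8.0)
DEFAULT_VESSEL_QUANTILE = 0.85
DEFAULT_VESSEL_DILATE_PX = 3
MAX_MASK_FRACTION = 0.5


def compute_vessel_mask(
    mip: np.ndarray,
    fov: FovMask,
    scales: tuple[float, ...] = DEFAULT_VESSEL_SCALES,
    threshold_quantile: float = DEFAULT_VESSEL_QUANTILE,
    dilate_px: int = DEFAULT_VESSEL_DILATE_PX,
) -> VesselMask:
    """Mask large vessels on the MIP by multi-scale ridge response.

    Sato tubeness with bright-tube polarity (vessels are bright in FFA)
    at the configured large-vessel scales only; the mask is the response
    above its in-FOV quantile, dilated by ``dilate_px``. Microvessels
    far below the chosen scales respond weakly and are left unmasked.
    A mask covering more than half the FOV raises; an empty mask on a
    structured image is a warning, not an error.
    """
    if not 0 < threshold_quantile < 1:
        raise ParameterError("threshold_quantile must be in (0, 1)")
    fmask = fov.mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sato warns on constant images
        response = filters.sato(mip, sigmas=scales, black_ridges=False, mode="reflect")
    in_fov = response[fmask]
    if in_fov.size == 0 or in_fov.max() <= 0:
        log.warning("vessel masking: no ridge response inside FOV; empty mask")
        return VesselMask(mask=np.zeros_like(fmask))
    thr = float(np.quantile(in_fov, threshold_quantile))
    if thr <= 0:
        log.warning("vessel masking: quantile threshold is 0; empty mask")
        return VesselMask(mask=np.zeros_like(fmask))
    mask = (response > thr) & fmask
    if dilate_px > 0:
        mask = morphology.dilation(mask, morphology.disk(dilate_px)) & fmask
    frac = mask.sum() / max(fmask.sum(), 1)
    if frac > MAX_MASK_FRACTION:
        raise ParameterError(
            f"vessel mask covers {frac:.0%} of FOV (> {MAX_MASK_FRACTION:.0%}); "
            "lower the scales or raise the threshold quantile"
        )
    return VesselMask(mask=mask)


@dataclass
class IntensityRecord:
    """Mean parenchymal intensity of one region in one frame."""

    key: SeriesKey
    region: str
    t_acq: float
    mean_intensity: float
    n_pixels: int


def extract_region_intensities(
    aligned: list[AlignedFrame],
    key: SeriesKey,
    fov: FovMask,
    grid: EtdrsGrid | None = None,
    vessel_mask: VesselMask | None = None,
) -> list[IntensityRecord]:
    """Per-frame, per-region mean intensities.

    Pixels counted for a region are region ∩ FOV ∖ vessel mask ∖
    invalid-resample pixels. Mice (no grid) use the whole FOV as one
    region; primates use the four ETDRS regions. An ``all_regions``
    aggregate (pixel-count-weighted mean) is emitted per frame. Fully
    occluded regions are logged and omitted.
    """
    fmask = fov.mask
    vmask = vessel_mask.mask if vessel_mask is not None else np.zeros_like(fmask)
    if grid is not None:
        regions = {label: grid.region_mask(label) for label in REGION_LABELS}
    else:
        regions = {FOV_REGION: np.ones_like(fmask)}
    records: list[IntensityRecord] = []
    for frame in aligned:
        base = fmask & ~vmask & frame.valid
        total_sum, total_n = 0.0, 0
        for label, rmask in regions.items():
            sel = rmask & base
            n = int(sel.sum())
            if n == 0:
                log.warning(
                    "region %s fully occluded at t=%.0f s in %s; record omitted",
                    label, frame.t_acq, key.label(),
                )
                continue
            s = float(frame.pixels[sel].sum())
            records.append(IntensityRecord(
                key=key, region=label, t_acq=frame.t_acq,
                mean_intensity=s / n, n_pixels=n))
            total_sum += s
            total_n += n
        if total_n == 0:
            raise OcclusionError(
                f"no valid pixels in any region at t={frame.t_acq} in {key.label()}"
            )
        records.append(IntensityRecord(
            key=key, region=ALL_REGIONS, t_acq=frame.t_acq,
            mean_intensity=total_sum / total_n, n_pixels=total_n))
    return records


def records_to_frame(records: list[IntensityRecord]) -> pd.DataFrame:
    """Long-format table: subject,eye,session,species,region,t_sec,mean_intensity,n_pixels."""
    return pd.DataFrame([
        {
            "subject": r.key.subject_id,
            "eye": r.key.eye,
            "session": r.key.session,
            "species": r.key.species,
            "region": r.region,
            "t_sec": r.t_acq,
            "mean_intensity": r.mean_intensity,
            "n_pixels": r.n_pixels,
        }
        for r in records
    ])
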