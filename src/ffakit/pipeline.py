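"""End-to-end orchestration: process image series, analyze cohorts.

``process_series`` runs preprocess → register → mask → extract for one
series; ``process_study``/``analyze_study`` drive whole cohorts and
produce the comparison report. Registration may run on
illumination-corrected copies of the frames, but intensities are always
extracted from the aligned *raw* frames: diffuse leakage is a broad
background signal that a morphological high-pass would subtract away.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, registration, segmentation, stats_engine, temporal_metrics
from .errors import AnalysisError, ConfigurationError, FovDetectionError
from .image_io import ImageSeries
from .preprocess import CropSpec, FovMask
from .registration import AlignedFrame, KeypointParams, RegistrationResult
from .segmentation import EtdrsGrid, VesselMask

log = logging.getLogger(__name__)


@dataclass
class ProcessOptions:
    strategy: str = "auto"
    crop: CropSpec | None = None
    max_dim: int = 1024
    #: disk radius for registration-side illumination correction; None = off
    illumination_radius: int | None = None
    fov_override_radius: int | None = None
    vessel_scales: tuple[float, ...] = segmentation.DEFAULT_VESSEL_SCALES
    vessel_quantile: float = segmentation.DEFAULT_VESSEL_QUANTILE
    vessel_dilate_px: int = segmentation.DEFAULT_VESSEL_DILATE_PX
    mask_vessels: bool = True
    etdrs_diameters_mm: tuple[float, float, float] = segmentation.DEFAULT_DIAMETERS_MM
    pixel_scale_um: float | None = None
    keypoint_params: KeypointParams = field(default_factory=KeypointParams)


@dataclass
class ProcessedSeries:
    series: ImageSeries
    fov: FovMask
    registration: RegistrationResult
    aligned: list[AlignedFrame]
    mip: np.ndarray
    mip_valid: np.ndarray
    grid: EtdrsGrid | None
    vessel_mask: VesselMask | None
    records: pd.DataFrame


def _prepare(series: ImageSeries, opts: ProcessOptions) -> ImageSeries:
    frames = []
    for f in series.frames:
        if opts.crop is not None:
            f = preprocess.crop_info_panel(f, opts.crop)
        f, scale = preprocess.resize_frame(f, opts.max_dim)
        if opts.pixel_scale_um is not None and f.pixel_scale_um is None:
            f = f.with_pixels(f.pixels, pixel_scale_um=opts.pixel_scale_um / scale)
        frames.append(f)
    return ImageSeries(key=series.key, frames=frames).finalize()


def process_series(
    series: ImageSeries,
    opts: ProcessOptions | None = None,
    macula_center: tuple[float, float] | None = None,
) -> ProcessedSeries:
    """Run one series through preprocessing, registration and extraction.

    Primate series require a macula center (the ETDRS grid anchor);
    mouse series quantify the whole field of view.
    """
    if opts is None:
        opts = ProcessOptions()
    series = _prepare(series, opts)
    is_primate = series.key.species in ("nhp", "human")
    if is_primate and macula_center is None:
        raise ConfigurationError(
            f"series {series.key.label()}: primate species needs a macula center"
        )
    try:
        fov = preprocess.detect_fov_mask(
            series.frames[0], override_radius=opts.fov_override_radius)
    except FovDetectionError:
        log.warning("%s: FOV detection failed; using full-image mask",
                    series.key.label())
        fov = FovMask(mask=np.ones(series.frames[0].shape, dtype=bool))

    reg_input = series
    if opts.illumination_radius is not None:
        reg_input = ImageSeries(
            key=series.key,
            frames=[preprocess.correct_illumination(f, opts.illumination_radius)
                    for f in series.frames],
        )
    result, aligned_reg = registration.register_series(
        reg_input, strategy=opts.strategy, fov=fov,
        keypoint_params=opts.keypoint_params)
    # re-warp the RAW frames with the recovered transforms for quantification
    aligned: list[AlignedFrame] = []
    for rec in result.records:
        if rec.status != "registered":
            continue
        raw = series.frames[rec.index]
        warped, valid = registration.warp_to_reference(raw.pixels, rec.transform)
        aligned.append(AlignedFrame(index=rec.index, t_acq=raw.t_acq,
                                    pixels=warped, valid=valid))
    mip, mip_valid = registration.max_intensity_projection(aligned)

    grid = None
    if is_primate:
        ref_frame = series.frames[result.reference_index]
        grid = segmentation.build_etdrs_grid(
            macula_center, shape=ref_frame.shape,
            pixel_scale_um=ref_frame.pixel_scale_um or opts.pixel_scale_um,
            diameters_mm=opts.etdrs_diameters_mm)
    vmask = None
    if opts.mask_vessels:
        vmask = segmentation.compute_vessel_mask(
            mip, fov, scales=opts.vessel_scales,
            threshold_quantile=opts.vessel_quantile,
            dilate_px=opts.vessel_dilate_px)
    records = segmentation.extract_region_intensities(
        aligned, series.key, fov, grid=grid, vessel_mask=vmask)
    return ProcessedSeries(
        series=series, fov=fov, registration=result, aligned=aligned,
        mip=mip, mip_valid=mip_valid, grid=grid, vessel_mask=vmask,
        records=segmentation.records_to_frame(records),
    )


def process_study(
    series_list: list[ImageSeries],
    opts: ProcessOptions | None = None,
    macula_centers: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, ProcessedSeries]]:
    """Process every series; returns the pooled long table and per-series results."""
    macula_centers = macula_centers or {}
    tables, processed = [], {}
    for series in series_list:
        center = macula_centers.get(series.key.label())
        ps = process_series(series, opts, macula_center=center)
        tables.append(ps.records)
        processed[series.key.label()] = ps
    if not tables:
        raise AnalysisError("no series processed")
    return pd.concat(tables, ignore_index=True), processed


@dataclass
class AnalysisOptions:
    schedule: tuple[float, ...] = temporal_metrics.DEFAULT_SCHEDULE
    bin_tolerance: float = 0.25
    windows: temporal_metrics.PhaseWindows = field(
        default_factory=temporal_metrics.PhaseWindows)
    metric: str = "late_phase"  # {"late_phase", "cumulative"}
    alpha: float = 0.05


def analyze_study(records: pd.DataFrame, opts: AnalysisOptions | None = None) -> dict:
    """Cohort AM-vs-PM analysis of a pooled intensity table.

    Bins records to the nominal schedule, computes the chosen metric per
    series and region, pairs sessions per (subject, eye), and runs the
    normality-gated paired comparison per region with family-wise Šidák
    adjustment. Subjects with one session only are excluded with a log
    entry.
    """
    if opts is None:
        opts = AnalysisOptions()
    binned = temporal_metrics.bin_to_nominal(
        records, schedule=opts.schedule, tolerance=opts.bin_tolerance)
    phases = temporal_metrics.phase_summary(binned, opts.windows)
    if opts.metric == "late_phase":
        metric = phases[(phases["phase"] == "late") & (phases["n_frames"] > 0)]
        metric = metric.rename(columns={"mean_intensity": "value"})
    elif opts.metric == "cumulative":
        rows = []
        for region in binned["region"].unique():
            sums, _ = temporal_metrics.cumulative_intensity(binned, region)
            for (subject, eye, session), v in sums.items():
                rows.append({"subject": subject, "eye": eye, "session": session,
                             "region": region, "value": v})
        metric = pd.DataFrame(rows)
    else:
        raise ConfigurationError(f"unknown metric {opts.metric!r}")
    pairs = temporal_metrics.session_pairs(metric)
    if pairs.empty:
        raise AnalysisError("zero complete AM/PM pairs")
    comparisons = []
    for region, sub in pairs.groupby("region"):
        if len(sub) < 3:
            log.warning("region %s has %d pairs (< 3); skipped", region, len(sub))
            continue
        comparisons.append(stats_engine.compare_paired(
            sub["AM"].to_numpy(), sub["PM"].to_numpy(),
            region=region, metric=opts.metric, alpha=opts.alpha))
    stats_engine.adjust_family(comparisons)
    return {
        "binned": binned,
        "phase_summary": phases,
        "pairs": pairs,
        "pct_change": temporal_metrics.cohort_percent_change(pairs),
        "comparisons": stats_engine.results_to_frame(comparisons),
    }


# ---------------------------------------------------------------------------
# QC artifacts

def write_qc(ps: ProcessedSeries, out_dir: str | Path) -> dict[str, Path]:
    """Write the QC bundle: MIP PNG, frame montage PNG, aligned TIFF stack,
    and the per-frame registration report CSV."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = ps.series.key.label()
    paths = {}
    mip8 = np.round(np.clip(ps.mip, 0, 1) * 255).astype(np.uint8)
    paths["mip"] = out / f"{label}_mip.png"
    iio.imwrite(paths["mip"], mip8)
    n = len(ps.aligned)
    cols = int(np.ceil(np.sqrt(n)))
    rows_n = int(np.ceil(n / cols))
    h, w = ps.mip.shape
    montage = np.zeros((rows_n * h, cols * w), dtype=np.uint8)
    for i, a in enumerate(ps.aligned):
        r, c = divmod(i, cols)
        montage[r * h:(r + 1) * h, c * w:(c + 1) * w] = \
            np.round(np.clip(a.pixels, 0, 1) * 255).astype(np.uint8)
    paths["montage"] = out / f"{label}_montage.png"
    iio.imwrite(paths["montage"], montage)
    stack = np.stack([np.round(np.clip(a.pixels, 0, 1) * 65535).astype(np.uint16)
                      for a in ps.aligned])
    paths["stack"] = out / f"{label}_aligned.tif"
    tifffile.imwrite(paths["stack"], stack)
    rows = []
    for rec in ps.registration.records:
        rows.append({
            "index": rec.index, "status": rec.status, "reason": rec.reason,
            "n_keypoints": rec.n_keypoints, "n_matches": rec.n_matches,
            "n_inliers": rec.n_inliers, "mean_residual": rec.mean_residual,
            "peak_ratio": rec.peak_ratio,
            "tx": rec.transform.tx if rec.transform else np.nan,
            "ty": rec.transform.ty if rec.transform else np.nan,
            "rotation_deg": rec.transform.rotation_deg if rec.transform else np.nan,
            "scale": rec.transform.scale if rec.transform else np.nan,
        })
    paths["report"] = out / f"{label}_registration.csv"
    pd.DataFrame(rows).to_csv(paths["report"], index=False)
    return paths
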