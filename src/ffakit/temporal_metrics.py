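"""Temporal leakage readouts from regional intensity tables.

Input is the long-format table produced by the segmentation stage
(``subject,eye,session,species,region,t_sec,mean_intensity,n_pixels``).
Frames are first snapped to the nominal acquisition schedule (real
timestamps jitter around it), then summarized as:

* cumulative intensity over the timepoints present in *every* series of
  the cohort (so missing captures cannot bias the sum),
* per-phase means over the standard angiographic windows — early
  (first minute), intermediate (2–4 min), late (> 4 min),
* decay profiles as percent of the temporal maximum, with a clearance
  time readout,
* AM-vs-PM percent change per subject, averaged to the cohort, and a
  ring-map rendering of regional evening leakage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glyphs
from .errors import (
    ConfigurationError,
    DegenerateProfileError,
    NoCommonTimepointsError,
    ParameterError,
    UndefinedBaselineError,
)
from .segmentation import EtdrsGrid

log = logging.getLogger(__name__)

SERIES_COLS = ["subject", "eye", "session"]


@dataclass(frozen=True)
class PhaseWindows:
    """Angiographic phase windows (seconds post-injection).

    early is [lo, hi); mid is [lo, hi]; late is (lo, hi]. The default
    60–120 s gap between early and mid is intentionally unassigned.
    """

    early: tuple[float, float] = (0.0, 60.0)
    mid: tuple[float, float] = (120.0, 240.0)
    late: tuple[float, float] = (240.0, float("inf"))

    def __post_init__(self) -> None:
        e, m, l = self.early, self.mid, self.late
        if not (e[0] < e[1] and m[0] < m[1] and l[0] < l[1]):
            raise ConfigurationError("each phase window must have lo < hi")
        if not (e[1] <= m[0] and m[1] <= l[0]):
            raise ConfigurationError("phase windows must be non-overlapping and increasing")

    def phase_of(self, t: float) -> str | None:
        if self.early[0] <= t < self.early[1]:
            return "early"
        if self.mid[0] <= t <= self.mid[1]:
            return "mid"
        if self.late[0] < t <= self.late[1]:
            return "late"
        return None


DEFAULT_SCHEDULE = tuple(float(t) for t in range(30, 601, 30))


def bin_to_nominal(
    records: pd.DataFrame,
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
    tolerance: float = 0.25,
) -> pd.DataFrame:
    """Snap each record's ``t_sec`` to the nearest schedule time.

    A record is assigned iff |t - nominal| <= tolerance * (schedule
    step); otherwise ``nominal_t`` is NaN and ``off_schedule`` True.
    When two records of one series map to the same nominal time the
    nearer wins and the loser is logged and flagged off-schedule.
    """
    if len(schedule) == 0:
        raise ParameterError("schedule must be non-empty")
    sched = np.asarray(schedule, dtype=float)
    if np.any(np.diff(sched) <= 0):
        raise ParameterError("schedule must be strictly increasing")
    if not 0 < tolerance <= 0.5:
        raise ParameterError("tolerance must be in (0, 0.5]")
    step = float(np.median(np.diff(sched))) if len(sched) > 1 else float(sched[0])
    out = records.copy()
    idx = np.clip(np.searchsorted(sched, out["t_sec"].to_numpy()), 1, len(sched) - 1)
    lower, upper = sched[idx - 1], sched[np.minimum(idx, len(sched) - 1)]
    t = out["t_sec"].to_numpy(dtype=float)
    nominal = np.where(np.abs(t - lower) <= np.abs(t - upper), lower, upper)
    dist = np.abs(t - nominal)
    ok = dist <= tolerance * step
    out["nominal_t"] = np.where(ok, nominal, np.nan)
    out["off_schedule"] = ~ok
    # collision resolution: nearest record wins per (series, region, nominal)
    assigned = out[~out["off_schedule"]]
    group_cols = SERIES_COLS + ["region", "nominal_t"]
    dists = np.abs(assigned["t_sec"] - assigned["nominal_t"])
    keep = dists.groupby([assigned[c] for c in group_cols]).idxmin()
    losers = assigned.index.difference(keep)
    if len(losers):
        for i in losers:
            log.info("off-schedule duplicate: t=%.1f s lost nominal %.0f s",
                     out.loc[i, "t_sec"], out.loc[i, "nominal_t"])
        out.loc[losers, "nominal_t"] = np.nan
        out.loc[losers, "off_schedule"] = True
    return out


def cumulative_intensity(
    records: pd.DataFrame, region: str
) -> tuple[pd.Series, list[float]]:
    """Sum of regional mean intensity over the cohort-common nominal grid.

    The common grid is the intersection of nominal timepoints present in
    every series of the cohort; series-specific extra captures are
    ignored so every sum spans identical times.
    """
    df = records[(records["region"] == region) & records["nominal_t"].notna()]
    if df.empty:
        raise NoCommonTimepointsError(f"no binned records for region {region!r}")
    grids = df.groupby(SERIES_COLS)["nominal_t"].apply(set)
    common = set.intersection(*grids.tolist())
    if not common:
        coverage = {"/".join(map(str, k)): sorted(v) for k, v in grids.items()}
        raise NoCommonTimepointsError(
            f"series share no nominal timepoint; per-series coverage: {coverage}"
        )
    sel = df[df["nominal_t"].isin(common)]
    sums = sel.groupby(SERIES_COLS)["mean_intensity"].sum()
    sums.name = "cumulative_intensity"
    return sums, sorted(common)


def phase_summary(
    records: pd.DataFrame, windows: PhaseWindows = PhaseWindows()
) -> pd.DataFrame:
    """Per (series, region, phase) unweighted mean of frame-level means.

    Cells with no frames in the window are reported explicitly with
    ``n_frames = 0`` and NaN mean.
    """
    df = records[records["nominal_t"].notna()].copy()
    df["phase"] = df["nominal_t"].map(windows.phase_of)
    df = df[df["phase"].notna()]
    grouped = df.groupby(SERIES_COLS + ["region", "phase"])["mean_intensity"].agg(
        ["mean", "size"]
    ).rename(columns={"mean": "mean_intensity", "size": "n_frames"})
    series_idx = records[SERIES_COLS + ["region"]].drop_duplicates()
    full = pd.MultiIndex.from_frame(
        series_idx.merge(pd.DataFrame({"phase": ["early", "mid", "late"]}), how="cross")
    )
    out = grouped.reindex(full)
    out["n_frames"] = out["n_frames"].fillna(0).astype(int)
    return out.reset_index()


def decay_profile(
    t: np.ndarray,
    intensity: np.ndarray,
    clearance_threshold_pct: float = 50.0,
) -> dict:
    """Percent-of-max decay curve with peak time and clearance time.

    Returns ``{"t", "pct_of_max", "t_peak", "t_clearance"}``;
    ``t_clearance`` is the first post-peak time the curve is at or
    below the threshold, or None if never reached.
    """
    t = np.asarray(t, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(t) < 2:
        raise ParameterError("decay profile needs >= 2 points")
    if intensity.max() <= 0:
        raise DegenerateProfileError("all-zero intensity curve")
    order = np.argsort(t)
    t, intensity = t[order], intensity[order]
    pct = 100.0 * (intensity / intensity.max())  # ratio first: peak exactly 100
    t_peak = float(t[np.argmax(intensity)])
    below = np.nonzero((t > t_peak) & (pct <= clearance_threshold_pct))[0]
    t_clear = float(t[below[0]]) if len(below) else None
    return {"t": t, "pct_of_max": pct, "t_peak": t_peak, "t_clearance": t_clear}


def percent_change(am: float, pm: float) -> float:
    """Evening change relative to morning: 100 * (PM - AM) / AM."""
    if am <= 0:
        raise UndefinedBaselineError(f"AM baseline {am} <= 0")
    return 100.0 * (pm - am) / am


def session_pairs(metric: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Pivot per-(subject, eye, region) metric values into (AM, PM) pairs.

    Incomplete pairs (one session missing) are dropped with a log entry.
    """
    wide = metric.pivot_table(
        index=["subject", "eye", "region"], columns="session",
        values=value_col, aggfunc="first",
    )
    for col in ("AM", "PM"):
        if col not in wide:
            wide[col] = np.nan
    incomplete = wide[wide[["AM", "PM"]].isna().any(axis=1)]
    for idx in incomplete.index:
        log.info("dropping incomplete AM/PM pair: %s", (idx,))
    wide = wide.dropna(subset=["AM", "PM"])
    return wide.reset_index()[["subject", "eye", "region", "AM", "PM"]]


def cohort_percent_change(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-subject evening percent change, then cohort mean and median per region.

    Per-subject-first averaging matches the pairing of the downstream
    matched tests. Pairs with a non-positive AM baseline are dropped and
    logged.
    """
    rows = []
    for region, sub in pairs.groupby("region"):
        deltas = []
        for _, r in sub.iterrows():
            try:
                deltas.append(percent_change(r["AM"], r["PM"]))
            except UndefinedBaselineError as exc:
                log.warning("dropping pair %s/%s in %s: %s",
                            r["subject"], r["eye"], region, exc)
        if deltas:
            rows.append({
                "region": region,
                "n_pairs": len(deltas),
                "mean_pct_change": float(np.mean(deltas)),
                "median_pct_change": float(np.median(deltas)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leakage ring map

_RING_OUTLINE = (60, 60, 60)


def _red_ramp(frac: float) -> tuple[int, int, int]:
    """White at 0 to dark red at 1."""
    frac = float(np.clip(frac, 0.0, 1.0))
    r = int(round(255 - frac * (255 - 120)))
    gb = int(round(255 * (1 - frac)))
    return (r, gb, gb)


def leakage_color_map(
    delta_pct: dict[str, float],
    grid: EtdrsGrid,
    max_delta_pct: float | None = None,
    size: int = 480,
) -> np.ndarray:
    """Render ETDRS rings shaded by evening leakage (percent change).

    Progressively darker red marks greater evening leakage; regions with
    delta <= 0 (or missing) stay uncolored. A numeric ramp legend is
    embedded using the packaged glyph atlas. Output is a deterministic
    RGB uint8 array.
    """
    if max_delta_pct is None:
        positives = [v for v in delta_pct.values() if v > 0]
        max_delta_pct = max(positives) if positives else 1.0
    if max_delta_pct <= 0:
        max_delta_pct = 1.0
    r1, r2, r3 = grid.radii_px
    # normalized display radii: outer ring at 40% of canvas
    disp = np.array([r1, r2, r3]) / r3 * (0.4 * size)
    cx = cy = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(xx - cx, yy - cy)
    regions = {
        "fovea": d <= disp[0],
        "parafovea": (d > disp[0]) & (d <= disp[1]),
        "perifovea": (d > disp[1]) & (d <= disp[2]),
        "extrafovea": (d > disp[2]) & (d <= disp[2] * 1.2),
    }
    img = np.full((size, size, 3), 255, dtype=np.uint8)
    for label, mask in regions.items():
        v = delta_pct.get(label)
        if v is None or v <= 0:
            continue
        img[mask] = _red_ramp(v / max_delta_pct)
    # ring outlines
    for rr in list(disp) + [disp[2] * 1.2]:
        ring = np.abs(d - rr) <= 1.0
        img[ring] = _RING_OUTLINE
    # legend: vertical ramp bar + numeric endpoints
    bar_x0, bar_w = size - 40, 14
    bar_y0, bar_h = size // 5, size * 3 // 5
    fr = (np.arange(bar_h) / (bar_h - 1))[::-1]
    for i, f in enumerate(fr):
        img[bar_y0 + i, bar_x0:bar_x0 + bar_w] = _red_ramp(f)
    img[bar_y0 - 1, bar_x0 - 1:bar_x0 + bar_w + 1] = _RING_OUTLINE
    img[bar_y0 + bar_h, bar_x0 - 1:bar_x0 + bar_w + 1] = _RING_OUTLINE
    top_label = glyphs.render_text(f"{max_delta_pct:.0f}", scale=1)
    zero_label = glyphs.render_text("0", scale=1)
    for lab, y in ((top_label, bar_y0 - 10), (zero_label, bar_y0 + bar_h + 3)):
        lh, lw = lab.shape
        x0 = bar_x0 + bar_w - lw
        patch = img[y:y + lh, x0:x0 + lw]
        patch[lab > 0.5] = _RING_OUTLINE
    return img
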