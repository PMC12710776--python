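"""Ground-truthed synthetic FFA studies.

Every pipeline stage needs an oracle: this module renders angiography
series with known vessel centerlines, known per-frame rigid motion, and
known dye kinetics, so registration, masking, extraction and the
circadian statistics can all be checked against generated truth.

The scene model: a branching vessel tree (bright tubes) over a weakly
textured background inside a circular field of view, dark aperture
surround, radial vignetting, and sensor noise. Dye kinetics follow a
gamma-variate bolus passage (fast rise, peak ~30 s, exponential-like
decline) plus a saturating extravascular leakage plateau; the evening
session's plateau amplitude is scaled by (1 + delta), the programmable
circadian leakage differential. Motion is modelled as rigid jitter of
the whole imaged field (camera/head motion), so the applied transform
is exactly the quantity registration should recover.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import SimilarityTransform, warp

from . import glyphs
from .image_io import Frame, ImageSeries, SeriesKey
from .registration import Transform2D


@dataclass
class KineticParams:
    """Gamma-variate bolus + saturating leakage plateau.

    The vascular term peaks (value K) at ``t0 + alpha * beta`` seconds;
    the leakage term rises monotonically to the plateau amplitude L with
    time constant tau_L. Defaults put the peak at 30 s post-injection
    with a slow recirculation-like decline, so vessels stay visible
    (and registrable) through the late phase while the whole-field mean
    still peaks early and settles toward a leakage-dependent plateau.
    """

    t0: float = 2.0      # bolus arrival (s)
    alpha: float = 0.15  # rise shape (small: fast fill, slow recirculation decay)
    beta: float = 186.67  # decay scale (s); peak at t0 + alpha*beta = 30 s
    K: float = 0.55      # vascular amplitude
    L: float = 0.025     # leakage plateau amplitude
    tau_L: float = 120.0  # plateau rise time constant (s)

    def __post_init__(self) -> None:
        if self.t0 < 0 or min(self.alpha, self.beta, self.K, self.tau_L) <= 0:
            raise ValueError("kinetic parameters must be positive (t0 >= 0)")
        if self.L < 0:
            raise ValueError("leakage amplitude must be >= 0")

    @property
    def t_peak(self) -> float:
        return self.t0 + self.alpha * self.beta


def vascular_term(t: float | np.ndarray, p: KineticParams) -> np.ndarray:
    """Normalized gamma-variate: 0 before bolus arrival, max K at t_peak."""
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - p.t0, 0.0)
    x = dt / (p.alpha * p.beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = p.K * np.where(dt > 0, x ** p.alpha * np.exp(p.alpha - dt / p.beta), 0.0)
    return v


def leakage_term(t: float | np.ndarray, p: KineticParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - p.t0, 0.0)
    return p.L * np.where(dt > 0, 1.0 - np.exp(-dt / p.tau_L), 0.0)


def kinetic_intensity(t: float | np.ndarray, p: KineticParams) -> np.ndarray:
    """Total intensity multiplier: vascular + leakage terms."""
    return vascular_term(t, p) + leakage_term(t, p)


# ---------------------------------------------------------------------------
# vessel tree

@dataclass
class VesselTreeParams:
    depth: int = 4
    n_trunks: int = 6
    trunk_width: float = 6.0
    trunk_length_frac: float = 0.16  # of image size
    branch_angle_deg: float = 32.0
    length_decay: float = 0.85


@dataclass
class VesselSegment:
    x0: float
    y0: float
    x1: float
    y1: float
    width: float

    def centerline(self, spacing: float = 1.0) -> np.ndarray:
        """(N, 2) (x, y) points sampled along the segment."""
        length = float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))
        n = max(2, int(length / spacing) + 1)
        ts = np.linspace(0.0, 1.0, n)
        return np.column_stack([
            self.x0 + ts * (self.x1 - self.x0),
            self.y0 + ts * (self.y1 - self.y0),
        ])


def _render_segment(canvas: np.ndarray, seg: VesselSegment) -> None:
    """Draw one anti-aliased bright tube by signed distance to the segment."""
    h, w = canvas.shape
    half = seg.width / 2.0
    pad = int(np.ceil(half)) + 2
    x_lo = max(0, int(min(seg.x0, seg.x1)) - pad)
    x_hi = min(w, int(max(seg.x0, seg.x1)) + pad + 1)
    y_lo = max(0, int(min(seg.y0, seg.y1)) - pad)
    y_hi = min(h, int(max(seg.y0, seg.y1)) + pad + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    vx, vy = seg.x1 - seg.x0, seg.y1 - seg.y0
    den = vx * vx + vy * vy
    if den == 0:
        dist = np.hypot(xx - seg.x0, yy - seg.y0)
    else:
        tt = np.clip(((xx - seg.x0) * vx + (yy - seg.y0) * vy) / den, 0.0, 1.0)
        dist = np.hypot(xx - (seg.x0 + tt * vx), yy - (seg.y0 + tt * vy))
    profile = np.clip(half + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[y_lo:y_hi, x_lo:x_hi], profile,
               out=canvas[y_lo:y_hi, x_lo:x_hi])


def generate_vessel_tree(
    seed: int,
    size: int = 256,
    params: VesselTreeParams | None = None,
) -> tuple[np.ndarray, list[VesselSegment]]:
    """Recursive bifurcating vessel tree radiating from the disc.

    Child widths follow Murray-style ``w_child = w_parent * 2^(-1/3)``;
    branch directions jitter inside the configured cone. Returns the
    rendered [0, 1] canvas and the ground-truth segments.
    """
    if params is None:
        params = VesselTreeParams()
    if params.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    cx = cy = size / 2.0
    segments: list[VesselSegment] = []

    def grow(x: float, y: float, angle: float, width: float,
             length: float, depth: int) -> None:
        x1 = x + length * np.cos(angle)
        y1 = y + length * np.sin(angle)
        segments.append(VesselSegment(x, y, x1, y1, width))
        if depth <= 1 or width < 1.0:
            return
        spread = np.deg2rad(params.branch_angle_deg)
        for sign in (-1.0, 1.0):
            child_angle = angle + sign * spread * rng.uniform(0.35, 1.0)
            grow(x1, y1, child_angle, width * 2 ** (-1.0 / 3.0),
                 length * params.length_decay, depth - 1)

    trunk_len = params.trunk_length_frac * size
    base_angles = np.linspace(0, 2 * np.pi, params.n_trunks, endpoint=False)
    for a in base_angles:
        angle = a + rng.uniform(-0.3, 0.3)
        grow(cx, cy, angle, params.trunk_width, trunk_len, params.depth)

    canvas = np.zeros((size, size))
    for seg in segments:
        _render_segment(canvas, seg)
    return canvas, segments


# ---------------------------------------------------------------------------
# frame rendering

@dataclass
class SceneModel:
    """Static per-eye anatomy: vessel tree, background texture, FOV geometry."""

    size: int
    tree: np.ndarray
    segments: list[VesselSegment]
    background_level: float
    texture: np.ndarray
    fov_radius: float
    vignette_strength: float
    surround_level: float = 0.012

    @property
    def fov_mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0:self.size, 0:self.size]
        c = self.size / 2.0
        return (xx - c) ** 2 + (yy - c) ** 2 <= self.fov_radius ** 2

    @property
    def vignette(self) -> np.ndarray:
        yy, xx = np.mgrid[0:self.size, 0:self.size]
        c = self.size / 2.0
        r2 = ((xx - c) ** 2 + (yy - c) ** 2) / self.fov_radius ** 2
        return 1.0 - self.vignette_strength * np.clip(r2, 0.0, 1.0)


def build_scene(
    seed: int,
    size: int = 256,
    tree_params: VesselTreeParams | None = None,
    background_level: float = 0.08,
    texture_amplitude: float = 0.035,
    vignette_strength: float = 0.15,
) -> SceneModel:
    rng = np.random.default_rng(seed)
    tree, segments = generate_vessel_tree(
        int(rng.integers(2 ** 31)), size=size, params=tree_params)
    # two-scale anatomical texture (RPE granularity + choroidal pattern):
    # late-phase frames, where the vascular term has decayed, still need
    # realistic broadband structure for registration to lock onto
    fine = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 2.0)
    coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 6.0)
    texture = fine / max(fine.std(), 1e-12) + coarse / max(coarse.std(), 1e-12)
    texture *= texture_amplitude / max(texture.std(), 1e-12)
    return SceneModel(
        size=size, tree=tree, segments=segments,
        background_level=background_level, texture=texture,
        fov_radius=0.46 * size, vignette_strength=vignette_strength,
    )


def analytic_scene(scene: SceneModel, t: float, kin: KineticParams) -> np.ndarray:
    """Noiseless, motion-free frame at time t (the identity-path oracle)."""
    vasc = float(vascular_term(t, kin))
    leak = float(leakage_term(t, kin))
    interior = np.clip(
        scene.background_level + scene.texture + leak + scene.tree * vasc, 0.0, 1.0
    ) * scene.vignette
    return np.where(scene.fov_mask, interior, scene.surround_level)


def render_frame(
    t: float,
    scene: SceneModel,
    kin: KineticParams,
    motion: Transform2D | None = None,
    read_noise_sd: float = 0.01,
    shot_noise_sd: float = 0.02,
    timestamp_overlay: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Frame, dict]:
    """Render one frame plus its ground-truth record.

    Motion warps the whole imaged field; noise is additive Gaussian plus
    a signal-dependent term; an optional ``mm:ss`` timestamp from the
    packaged glyph atlas is burned into the corner after warping.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    clean = analytic_scene(scene, t, kin)
    tform = motion if motion is not None else Transform2D.identity()
    sk = tform.as_skimage()
    warped = warp(clean, sk.inverse, order=1, mode="constant",
                  cval=scene.surround_level, preserve_range=True)
    noisy = warped + rng.normal(0.0, read_noise_sd, warped.shape)
    if shot_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, 1.0, warped.shape) * \
            shot_noise_sd * np.sqrt(np.clip(warped, 0.0, 1.0))
    noisy = np.clip(noisy, 0.0, 1.0)
    if timestamp_overlay:
        mm, ss = int(t) // 60, int(t) % 60
        noisy = glyphs.stamp_text(noisy, f"{mm:02d}:{ss:02d}", origin=(4, 4),
                                  scale=2, intensity=1.0)
    vessel_gt = scene.tree > 0.1
    sel = scene.fov_mask & ~vessel_gt
    truth = {
        "t": float(t),
        "transform": {"tx": tform.tx, "ty": tform.ty,
                      "rotation_deg": tform.rotation_deg, "scale": tform.scale},
        "clean_fov_mean": float(clean[scene.fov_mask].mean()),
        "clean_parenchyma_mean": float(clean[sel].mean()),
        "vascular": float(vascular_term(t, kin)),
        "leakage": float(leakage_term(t, kin)),
    }
    frame = Frame(pixels=noisy, t_acq=float(t), dialect="fundus",
                  source_path=f"synthetic:t={t:g}")
    return frame, truth


# ---------------------------------------------------------------------------
# study generation

@dataclass
class SyntheticStudyConfig:
    """Conditions of a simulated circadian FFA study.

    ``delta`` scales the evening leakage plateau: L_PM = (1+delta)*L_AM.
    A fixed seed makes the whole study byte-identical.
    """

    n_subjects: int = 15
    schedule: tuple[float, ...] = tuple(float(t) for t in range(30, 601, 30))
    species: str = "mouse"
    size: int = 256
    tree_params: VesselTreeParams = field(default_factory=VesselTreeParams)
    motion_px: float = 6.0
    motion_deg: float = 2.0  # used for primate (keypoint) species only
    read_noise_sd: float = 0.01
    shot_noise_sd: float = 0.02
    vignette_strength: float = 0.15
    kinetics: KineticParams = field(default_factory=KineticParams)
    subject_sd_frac: float = 0.15  # between-subject spread of L and background
    delta: float = 0.0
    timestamp_overlay: bool = False
    eye: str = "OS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < -1:
            raise ValueError("delta must be >= -1")


def _draw_motion(rng: np.random.Generator, cfg: SyntheticStudyConfig,
                 center: float) -> Transform2D:
    tx, ty = rng.uniform(-cfg.motion_px, cfg.motion_px, size=2)
    if cfg.species == "mouse":
        return Transform2D(kind="translation", tx=float(tx), ty=float(ty))
    rot = float(rng.uniform(-cfg.motion_deg, cfg.motion_deg))
    about = SimilarityTransform(translation=(-center, -center))
    spin = SimilarityTransform(rotation=np.deg2rad(rot))
    back = SimilarityTransform(translation=(center + tx, center + ty))
    m = back.params @ spin.params @ about.params
    t = SimilarityTransform(matrix=m)
    return Transform2D(kind="similarity", tx=float(t.translation[0]),
                       ty=float(t.translation[1]),
                       rotation_deg=float(np.rad2deg(t.rotation)),
                       scale=float(t.scale))


def _subject_kinetics(base: KineticParams, rng: np.random.Generator,
                      sd_frac: float) -> tuple[KineticParams, float]:
    """Per-subject kinetic draw; returns (params, background level)."""
    L = float(base.L * rng.lognormal(0.0, sd_frac))
    K = float(base.K * rng.lognormal(0.0, 0.05))
    b0 = float(np.clip(rng.normal(0.08, 0.005), 0.05, 0.12))
    kin = KineticParams(t0=base.t0, alpha=base.alpha, beta=base.beta,
                        K=K, L=L, tau_L=base.tau_L)
    return kin, b0


def analytic_late_delta_pct(
    kin_am: KineticParams, kin_pm: KineticParams, b0: float,
    schedule: tuple[float, ...], late_lo: float = 240.0,
) -> float:
    """Ground-truth late-phase evening percent change for one subject.

    The parenchymal signal at time t is background + leakage term (the
    vignette factor and texture mean cancel in the ratio), so
    delta% = 100 * delta * (leakage share of the late signal).
    """
    late = [t for t in schedule if t > late_lo]
    if not late:
        return float("nan")
    am = float(np.mean([b0 + leakage_term(t, kin_am) for t in late]))
    pm = float(np.mean([b0 + leakage_term(t, kin_pm) for t in late]))
    return 100.0 * (pm - am) / am


def simulate_series(
    cfg: SyntheticStudyConfig, subject_index: int, session: str,
) -> tuple[ImageSeries, SceneModel, dict]:
    """Render one subject-session series in memory with its ground truth."""
    ss = np.random.SeedSequence([cfg.seed, subject_index])
    scene_seed, kin_seed = ss.spawn(2)
    scene_rng = np.random.default_rng(scene_seed)
    kin_rng = np.random.default_rng(kin_seed)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject_index,
                                0 if session == "AM" else 1, 7]))
    kin_am, b0 = _subject_kinetics(cfg.kinetics, kin_rng, cfg.subject_sd_frac)
    kin = kin_am
    if session == "PM":
        kin = KineticParams(t0=kin_am.t0, alpha=kin_am.alpha, beta=kin_am.beta,
                            K=kin_am.K, L=kin_am.L * (1.0 + cfg.delta),
                            tau_L=kin_am.tau_L)
    scene = build_scene(
        int(scene_rng.integers(2 ** 31)), size=cfg.size,
        tree_params=cfg.tree_params, background_level=b0,
        vignette_strength=cfg.vignette_strength,
    )
    key = SeriesKey(subject_id=f"s{subject_index:02d}", eye=cfg.eye,
                    session=session, species=cfg.species)
    frames, truths = [], []
    for t in cfg.schedule:
        motion = _draw_motion(noise_rng, cfg, cfg.size / 2.0)
        frame, truth = render_frame(
            t, scene, kin, motion=motion,
            read_noise_sd=cfg.read_noise_sd, shot_noise_sd=cfg.shot_noise_sd,
            timestamp_overlay=cfg.timestamp_overlay, rng=noise_rng,
        )
        frames.append(frame)
        truths.append(truth)
    kin_pm = kin if session == "PM" else None
    truth = {
        "subject": key.subject_id,
        "session": session,
        "kinetics": asdict(kin),
        "background_level": b0,
        "frames": truths,
    }
    series = ImageSeries(key=key, frames=frames).finalize()
    return series, scene, truth


def generate_study(
    cfg: SyntheticStudyConfig,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Write a study directory consumable by ``ingest_study``.

    Layout: ``out/sNN/{AM,PM}/sNN_OS_{AM,PM}_tTTTT.png`` (16-bit PNG)
    plus per-directory ``timing.csv`` sidecars and a study-level
    ``ground_truth.json`` holding per-subject kinetics, per-frame
    transforms, and the analytic late-phase evening percent change —
    the oracle for end-to-end parameter recovery.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        import shutil
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    truth_all: dict = {"config": _config_dict(cfg), "subjects": {}}
    for si in range(cfg.n_subjects):
        subj_truth: dict = {}
        for session in ("AM", "PM"):
            series, scene, truth = simulate_series(cfg, si, session)
            sdir = out / series.key.subject_id / session
            sdir.mkdir(parents=True, exist_ok=True)
            rows = ["filename,seconds"]
            for frame in series.frames:
                name = (f"{series.key.subject_id}_{cfg.eye}_{session}"
                        f"_t{int(frame.t_acq):04d}.png")
                px16 = np.round(frame.pixels * 65535).astype(np.uint16)
                iio.imwrite(sdir / name, px16)
                rows.append(f"{name},{frame.t_acq:g}")
            (sdir / "timing.csv").write_text("\n".join(rows) + "\n")
            subj_truth[session] = truth
        kin_am = KineticParams(**subj_truth["AM"]["kinetics"])
        kin_pm = KineticParams(**subj_truth["PM"]["kinetics"])
        subj_truth["analytic_late_delta_pct"] = analytic_late_delta_pct(
            kin_am, kin_pm, subj_truth["AM"]["background_level"], cfg.schedule)
        truth_all["subjects"][f"s{si:02d}"] = subj_truth
    deltas = [s["analytic_late_delta_pct"] for s in truth_all["subjects"].values()]
    truth_all["cohort_mean_late_delta_pct"] = float(np.mean(deltas))
    (out / "ground_truth.json").write_text(json.dumps(truth_all, indent=1,
                                                      sort_keys=True))
    return out


def _config_dict(cfg: SyntheticStudyConfig) -> dict:
    d = asdict(cfg)
    d["schedule"] = list(cfg.schedule)
    return d
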