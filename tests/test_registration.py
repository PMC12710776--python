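"""Registration: FAST contract, transform recovery, exclusion gates, MIP."""
import numpy as np
import pytest
from skimage.transform import SimilarityTransform

from ffakit.errors import (
    DegenerateInputError,
    EmptySeriesError,
    InsufficientFeaturesError,
    SizeError,
)
from ffakit.image_io import Frame, ImageSeries, SeriesKey
from ffakit.registration import (
    AlignedFrame,
    KeypointParams,
    Transform2D,
    _CIRCLE,
    detect_fast,
    estimate_similarity_ransac,
    fast_score_map,
    max_intensity_projection,
    register_frequency,
    register_keypoint,
    register_series,
)
from ffakit.synthetic_fundus import render_frame


# ---------------------------------------------------------------------------
# FAST

def fast_brute_force(image, threshold, arc_length):
    """Direct segment-test oracle: per pixel, per start position, check arcs."""
    h, w = image.shape
    corners = {}
    for y in range(3, h - 3):
        for x in range(3, w - 3):
            c = image[y, x]
            ring = [image[y + dr, x + dc] for dr, dc in _CIRCLE]
            best = -np.inf
            for s in range(16):
                window = [ring[(s + k) % 16] for k in range(arc_length)]
                best = max(best,
                           min(v - c for v in window),
                           min(c - v for v in window))
            if best > threshold:
                corners[(x, y)] = best
    return corners


def test_fast_matches_brute_force_oracle():
    """Score map equals the direct segment-test definition pixel for pixel."""
    rng = np.random.default_rng(7)
    img = rng.random((32, 32))
    for arc in (9, 12):
        oracle = fast_brute_force(img, 0.3, arc)
        score = fast_score_map(img, arc_length=arc)
        mine = {(x, y): score[y, x]
                for y, x in zip(*np.nonzero(score > 0.3))}
        assert set(mine) == set(oracle)
        for k in oracle:
            assert mine[k] == pytest.approx(oracle[k], abs=1e-12)


def test_fast_square_corners_detected():
    """A bright 5x5 square yields detections at all four corners (+-1 px)."""
    img = np.zeros((64, 64))
    img[20:25, 30:35] = 1.0
    pts = {(k.x, k.y) for k in detect_fast(img, threshold=0.1)}
    for cx, cy in [(30, 20), (34, 20), (30, 24), (34, 24)]:
        assert any(abs(x - cx) <= 1 and abs(y - cy) <= 1 for x, y in pts)


def test_fast_constant_image_no_corners():
    assert detect_fast(np.full((64, 64), 0.5), threshold=0.1) == []


def test_fast_cap_retains_highest_scores():
    """Dense noise exceeding the cap keeps exactly `cap`, the strongest first."""
    rng = np.random.default_rng(0)
    img = rng.random((256, 256))
    uncapped = detect_fast(img, threshold=0.01, cap=10 ** 7)
    assert len(uncapped) > 500
    capped = detect_fast(img, threshold=0.01, cap=500)
    assert len(capped) == 500
    kept = sorted(k.score for k in capped)
    dropped = [k.score for k in uncapped[500:]]
    assert min(kept) >= max(dropped)


def test_fast_rejects_tiny_images():
    with pytest.raises(SizeError):
        detect_fast(np.zeros((6, 6)), threshold=0.1)


# ---------------------------------------------------------------------------
# pairwise registration

def _centered_similarity(tx, ty, rot_deg, size=256):
    c = size / 2
    m = (SimilarityTransform(translation=(c + tx, c + ty)).params
         @ SimilarityTransform(rotation=np.deg2rad(rot_deg)).params
         @ SimilarityTransform(translation=(-c, -c)).params)
    t = SimilarityTransform(matrix=m)
    return Transform2D(kind="similarity", tx=float(t.translation[0]),
                       ty=float(t.translation[1]),
                       rotation_deg=float(np.rad2deg(t.rotation)),
                       scale=float(t.scale))


def test_keypoint_self_registration_is_identity(peak_frame):
    tform, _ = register_keypoint(peak_frame, peak_frame, KeypointParams(seed=5))
    assert abs(tform.tx) < 0.1 and abs(tform.ty) < 0.1
    assert abs(tform.rotation_deg) < 0.05
    assert tform.scale == pytest.approx(1.0, abs=1e-3)


def test_keypoint_recovers_known_similarity(scene, kinetics):
    """Applied (12, -7) px translation + 3 deg rotation is recovered (inverse map)."""
    ref, _ = render_frame(30.0, scene, kinetics, rng=np.random.default_rng(1))
    motion = _centered_similarity(12, -7, 3.0)
    mov, _ = render_frame(30.0, scene, kinetics, motion=motion,
                          rng=np.random.default_rng(2))
    tform, metrics = register_keypoint(ref, mov, KeypointParams(seed=5))
    expected = motion.inverse()
    assert np.hypot(tform.tx - expected.tx, tform.ty - expected.ty) < 0.5
    assert abs(tform.rotation_deg - expected.rotation_deg) < 0.2
    assert metrics["n_inliers"] >= 10


def test_keypoint_dark_frame_raises(peak_frame):
    dark = Frame(pixels=np.zeros((256, 256)))
    with pytest.raises(InsufficientFeaturesError):
        register_keypoint(peak_frame, dark, KeypointParams(seed=5))


def test_ransac_is_seed_deterministic():
    rng = np.random.default_rng(4)
    src = rng.uniform(0, 200, size=(120, 2))
    true = Transform2D(kind="similarity", tx=5, ty=-2, rotation_deg=2, scale=1.05)
    dst = true.apply(src) + rng.normal(0, 0.3, size=src.shape)
    dst[:20] = rng.uniform(0, 200, size=(20, 2))  # outliers
    a = estimate_similarity_ransac(src, dst, seed=9)
    b = estimate_similarity_ransac(src, dst, seed=9)
    assert a[0] == b[0]
    assert abs(a[0].rotation_deg - 2) < 0.2


def test_frequency_self_and_known_shift(scene, kinetics):
    ref, _ = render_frame(30.0, scene, kinetics, rng=np.random.default_rng(1))
    tform, ratio = register_frequency(ref, ref)
    assert (tform.tx, tform.ty) == (0.0, 0.0)
    assert ratio > 10
    motion = Transform2D(kind="translation", tx=5.0, ty=-3.0)
    mov, _ = render_frame(30.0, scene, kinetics, motion=motion,
                          rng=np.random.default_rng(2))
    tform, _ = register_frequency(ref, mov)
    assert abs(tform.tx - (-5.0)) < 0.25 and abs(tform.ty - 3.0) < 0.25


def test_frequency_noise_pair_flagged_unreliable():
    """Independent noise frames give a weak, non-committal correlation peak."""
    ratios = []
    for s in range(20):
        rng = np.random.default_rng(s)
        a, b = rng.random((128, 128)), rng.random((128, 128))
        ratios.append(register_frequency(a, b)[1])
    assert np.median(ratios) < 1.5


def test_frequency_constant_frame_raises():
    with pytest.raises(DegenerateInputError):
        register_frequency(np.zeros((128, 128)), np.zeros((128, 128)))


# ---------------------------------------------------------------------------
# transforms algebra

def test_transform_compose_invert_roundtrip():
    t = Transform2D(kind="similarity", tx=8.5, ty=-3.25, rotation_deg=4.0, scale=1.1)
    pts = np.array([[10.0, 20.0], [100.0, 50.0], [200.0, 180.0]])
    roundtrip = t.inverse().apply(t.apply(pts))
    assert np.allclose(roundtrip, pts, atol=1e-9)
    ident = t.compose(t.inverse())
    assert abs(ident.tx) < 1e-9 and abs(ident.ty) < 1e-9
    assert abs(ident.rotation_deg) < 1e-9 and ident.scale == pytest.approx(1.0)


def test_registration_composability(scene, kinetics):
    """A->B and B->C composed agrees with direct A->C within 1 px over the FOV."""
    frames = []
    for i, (tx, ty, r) in enumerate([(0, 0, 0), (6, -4, 1.5), (-5, 7, -2.0)]):
        motion = _centered_similarity(tx, ty, r)
        f, _ = render_frame(30.0, scene, kinetics, motion=motion,
                            rng=np.random.default_rng(10 + i))
        frames.append(f)
    params = KeypointParams(seed=5)
    t_ba, _ = register_keypoint(frames[0], frames[1], params)  # B -> A
    t_cb, _ = register_keypoint(frames[1], frames[2], params)  # C -> B
    t_ca, _ = register_keypoint(frames[0], frames[2], params)  # C -> A
    composed = t_ba.compose(t_cb)
    yy, xx = np.mgrid[64:192:16, 64:192:16]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    err = np.linalg.norm(composed.apply(pts) - t_ca.apply(pts), axis=1)
    assert err.max() < 1.0


# ---------------------------------------------------------------------------
# series registration

def _make_series(scene, kinetics, motions, species="mouse", corrupt=None):
    frames = []
    for i, motion in enumerate(motions):
        f, _ = render_frame(30.0 + 30 * i, scene, kinetics, motion=motion,
                            rng=np.random.default_rng(100 + i))
        if corrupt and i in corrupt:
            kind = corrupt[i]
            if kind == "dark":
                f = f.with_pixels(np.clip(f.pixels * 0.01, 0, 1))
            elif kind == "blur":
                from scipy import ndimage
                f = f.with_pixels(ndimage.gaussian_filter(f.pixels, 10.0))
        frames.append(f)
    key = SeriesKey("t01", "OS", "AM", species)
    return ImageSeries(key=key, frames=frames).finalize()


def test_series_no_motion_gives_identity_transforms(scene, kinetics):
    series = _make_series(scene, kinetics, [None] * 5)
    result, aligned = register_series(series)
    assert result.n_registered == 5
    for rec in result.records:
        assert abs(rec.transform.tx) < 0.1 and abs(rec.transform.ty) < 0.1


def test_series_excludes_corrupted_frames_only(scene, kinetics):
    """Programmed dark/blurred frames are excluded; clean frames never are."""
    rng = np.random.default_rng(3)
    motions = [Transform2D(kind="translation",
                           tx=float(rng.uniform(-15, 15)),
                           ty=float(rng.uniform(-15, 15))) for _ in range(10)]
    series = _make_series(scene, kinetics, motions,
                          corrupt={4: "dark", 7: "blur"})
    result, aligned = register_series(series)
    status = {r.index: (r.status, r.reason) for r in result.records}
    assert status[4][0] == "excluded" and "dark" in status[4][1]
    assert status[7] == ("excluded", "blurred")
    for i in set(range(10)) - {4, 7}:
        assert status[i][0] == "registered"


def test_series_alignment_residual_under_jitter(scene, kinetics):
    """Random jitter <= 15 px is corrected to sub-pixel vessel alignment."""
    rng = np.random.default_rng(11)
    motions = [None] + [
        Transform2D(kind="translation", tx=float(rng.uniform(-15, 15)),
                    ty=float(rng.uniform(-15, 15))) for _ in range(7)]
    series = _make_series(scene, kinetics, motions)
    result, aligned = register_series(series)
    assert result.n_registered == 8
    ref_idx = result.reference_index
    # ground truth: recovered transform should equal motion⁻¹ composed with
    # the reference frame's motion (identity here since frame 0 is reference)
    for rec in result.records:
        if rec.index == ref_idx or rec.status != "registered":
            continue
        gt = motions[rec.index].inverse() if motions[rec.index] else Transform2D()
        err = np.hypot(rec.transform.tx - gt.tx, rec.transform.ty - gt.ty)
        assert err < 0.7


# ---------------------------------------------------------------------------
# MIP

def _aligned(pixels, valid=None, index=0):
    valid = np.ones_like(pixels, dtype=bool) if valid is None else valid
    return AlignedFrame(index=index, t_acq=30.0 * (index + 1),
                        pixels=pixels, valid=valid)


def test_mip_semantics_and_permutation_invariance():
    a = _aligned(np.full((64, 64), 0.2), index=0)
    b = _aligned(np.full((64, 64), 0.5), index=1)
    spots = np.zeros((64, 64))
    spots[10, 10] = 0.9
    c = _aligned(spots, index=2)
    mip1, valid1 = max_intensity_projection([a, b, c])
    mip2, _ = max_intensity_projection([c, a, b])
    assert np.array_equal(mip1, mip2)
    assert mip1[10, 10] == 0.9
    assert mip1[0, 0] == 0.5
    assert valid1.all()


def test_mip_invalid_pixels_ignored_and_flagged():
    px = np.full((64, 64), 0.8)
    v = np.ones((64, 64), dtype=bool)
    v[:, :5] = False
    mip, valid = max_intensity_projection([_aligned(px, valid=v)])
    assert not valid[:, :5].any()
    assert (mip[:, :5] == 0).all()
    assert (mip[:, 5:] == 0.8).all()


def test_mip_empty_raises():
    with pytest.raises(EmptySeriesError):
        max_intensity_projection([])
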