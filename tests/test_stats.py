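"""Statistics engine: normality gate, paired tests, dispatch, mixed effects."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ffakit.errors import (
    DegenerateSampleError,
    NoInformationError,
    SampleSizeError,
)
from ffakit.stats_engine import (
    adjust_family,
    anderson_darling,
    compare_paired,
    mixed_effects_compare,
    paired_t,
    session_effect,
    sidak_adjust,
    wilcoxon_signed_rank,
)


class TestAndersonDarling:
    @pytest.mark.filterwarnings("ignore::FutureWarning")
    def test_statistic_matches_scipy(self):
        """Our A2* equals scipy's statistic after the same n-adjustment."""
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=60)
            v = anderson_darling(x)
            ref = sps.anderson(x, "norm").statistic * (1 + 0.75 / 60 + 2.25 / 60 ** 2)
            assert v.A2 == pytest.approx(ref, rel=1e-10)

    def test_type_one_error_near_nominal(self):
        """Gaussian samples rejected ~5% of the time at alpha=0.05."""
        rejections = sum(
            not anderson_darling(
                np.random.default_rng(1000 + i).normal(size=200)).normal
            for i in range(100))
        assert 90 <= 100 - rejections  # normal verdict in >= 90 of 100

    def test_power_against_exponential(self):
        rejections = sum(
            not anderson_darling(
                np.random.default_rng(2000 + i).exponential(size=200)).normal
            for i in range(100))
        assert rejections >= 99

    def test_heavy_skew_reaches_strongest_band(self):
        x = np.random.default_rng(3).lognormal(0.0, 1.2, size=200)
        assert anderson_darling(x).p_band == "<0.0005"

    def test_affine_invariance(self):
        x = np.random.default_rng(4).normal(size=50)
        a = anderson_darling(x)
        b = anderson_darling(3.7 * x - 11.0)
        assert a.A2 == pytest.approx(b.A2, rel=1e-9)
        assert a.p_band == b.p_band

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSampleError):
            anderson_darling(np.full(20, 1.0))
        with pytest.raises(SampleSizeError):
            anderson_darling(np.arange(5.0))


def wilcoxon_enumeration_oracle(d):
    """Brute force: enumerate every sign assignment of |d| ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert w == 6.0 and p == 0.25

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 8), (2, 10), (3, 12), (4, 12)])
    def test_exact_p_equals_enumeration(self, seed, n):
        """Exact p matches the full 2^n sign-enumeration oracle, with ties."""
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # rounding induces ties
        d[d == 0] = 0.1
        w, p = wilcoxon_signed_rank(np.zeros(n), d)
        w_ref, p_ref = wilcoxon_enumeration_oracle(d)
        assert w == w_ref
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact(self):
        d = np.array([0.3, -1.2, 0.5, 2.2, -0.4, 1.1, 0.9, -2.0, 0.2, 1.4,
                      -0.6, 0.8])
        _, p = wilcoxon_signed_rank(np.zeros_like(d), d)
        assert p == pytest.approx(sps.wilcoxon(d, mode="exact").pvalue, abs=1e-12)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.2, 1.0, size=60)
        _, p = wilcoxon_signed_rank(np.zeros_like(d), d)
        ref = sps.wilcoxon(d, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_all_zero_differences(self):
        with pytest.raises(NoInformationError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_hand_computed_example(self):
        """d = 2,4,6,8: mean 5, sd 2.582 -> t = 3.873."""
        t, _ = paired_t([0, 0, 0, 0], [2, 4, 6, 8])
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([0, 0, 0, 0], [1, 1, 1, 1])

    def test_null_p_uniformity(self):
        """Symmetric null differences give approximately uniform p values."""
        ps = []
        for i in range(500):
            rng = np.random.default_rng(3000 + i)
            x = rng.normal(0, 1, 10)
            ps.append(paired_t(np.zeros(10), x)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSidak:
    def test_examples_and_boundaries(self):
        assert sidak_adjust([0.05]) == [pytest.approx(0.05)]
        assert sidak_adjust([0.01] * 6)[0] == pytest.approx(1 - 0.99 ** 6, abs=1e-4)
        assert sidak_adjust([1.0, 0.2])[0] == 1.0

    def test_order_preserving(self):
        p = [0.3, 0.01, 0.7, 0.04]
        adj = sidak_adjust(p)
        assert np.array_equal(np.argsort(p), np.argsort(adj))


class TestDispatch:
    def test_gaussian_differences_use_paired_t(self):
        rng = np.random.default_rng(5)
        am = rng.normal(10, 1, 30)
        pm = am + rng.normal(0.5, 0.5, 30)
        res = compare_paired(am, pm)
        assert res.test_name == "paired_t"
        assert res.am_center == pytest.approx(am.mean())

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(8)
        am = np.full(30, 10.0)
        pm = am + rng.lognormal(0.0, 1.2, 30)  # heavily skewed differences
        res = compare_paired(am, pm)
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.am_center == pytest.approx(np.median(am))

    def test_dispatch_is_deterministic(self):
        rng = np.random.default_rng(6)
        am, pm = rng.normal(1, 0.1, 20), rng.normal(1, 0.1, 20)
        names = {compare_paired(am, pm).test_name for _ in range(3)}
        assert len(names) == 1

    def test_null_rejection_rate_calibrated(self):
        """Dispatched test keeps its size on null paired cohorts (n=15)."""
        rej = 0
        n_rep = 400
        for i in range(n_rep):
            rng = np.random.default_rng(50000 + i)
            am = rng.normal(10, 1, 15)
            pm = am + rng.normal(0, 0.5, 15)
            rej += compare_paired(am, pm).p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_family_adjustment_attached(self):
        rng = np.random.default_rng(7)
        results = [compare_paired(rng.normal(1, .1, 12), rng.normal(1, .1, 12),
                                  region=r) for r in ("fovea", "parafovea")]
        adjust_family(results)
        for r in results:
            assert r.p_adjusted >= r.p


def _nested_cohort(seed, n_subjects=6, effect=0.1, subject_sd=0.05,
                   noise_sd=0.02):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, subject_sd)
        for eye in ("OS", "OD"):
            for sess, eff in (("AM", 0.0), ("PM", effect)):
                rows.append({"subject": f"s{s}", "eye": eye, "session": sess,
                             "value": 0.5 + u + eff + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestMixedEffects:
    def test_session_effect_recovery(self):
        ests = [session_effect(mixed_effects_compare(_nested_cohort(100 + s)))
                for s in range(25)]
        assert 0.07 <= np.median(ests) <= 0.13
        assert all(0.05 <= e <= 0.15 for e in ests)

    def test_null_effect_recovery(self):
        ests = [session_effect(mixed_effects_compare(
            _nested_cohort(200 + s, effect=0.0))) for s in range(25)]
        assert abs(np.median(ests)) < 0.01

    def test_duplicated_eyes_collapse_to_subject_means(self):
        """Identical eyes give the same estimate as a per-subject analysis."""
        df = _nested_cohort(42)
        os_rows = df[df["eye"] == "OS"].copy()
        dup = pd.concat([os_rows, os_rows.assign(eye="OD")], ignore_index=True)
        est = session_effect(mixed_effects_compare(dup))
        per_subject = os_rows.pivot_table(index="subject", columns="session",
                                          values="value")
        expected = (per_subject["PM"] - per_subject["AM"]).mean()
        assert est == pytest.approx(expected, abs=1e-6)

    def test_two_way_interaction_reported(self):
        df = pd.concat([
            _nested_cohort(1, effect=0.1).assign(group="young"),
            _nested_cohort(2, effect=0.0).assign(group="old"),
        ], ignore_index=True)
        df["subject"] = df["subject"] + "_" + df["group"]
        res = mixed_effects_compare(df, group_factor="group")
        names = " ".join(res["effects"]["effect"])
        assert "session" in names and ":" in names  # main + interaction terms
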