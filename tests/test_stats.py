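"""Shared statistics layer: closed-form examples and simulations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nrgeom.stats import (
    anova_tukey,
    bonferroni_adjust,
    coefficient_of_variation,
    cohens_d,
    cv_from_summary,
    hierarchical_cluster,
    kruskal_wallis,
    paired_t,
    regression_slope,
    summarize,
)


class TestCV:
    def test_printed_lbd_summary(self):
        # σ = 0.150, μ = 0.512 Å (all-atom LBD RMSD summary) → 29.3%
        assert cv_from_summary(0.150, 0.512) == pytest.approx(29.3, abs=0.05)

    def test_printed_dbd_summary(self):
        # direct evaluation on the printed (rounded) DBD summary is 17.65%,
        # consistent with the published 17.7% from unrounded inputs
        assert cv_from_summary(0.078, 0.442) == pytest.approx(17.65, abs=0.01)
        assert cv_from_summary(0.078, 0.442) == pytest.approx(17.7, abs=0.1)

    def test_constant_values_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    @given(st.floats(0.1, 100), st.integers(0, 5))
    def test_scale_invariance(self, c, seed):
        x = np.random.default_rng(seed).uniform(1, 10, 8)
        assert coefficient_of_variation(c * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )

    def test_sample_sd_convention(self):
        x = [1.0, 2.0, 3.0]
        assert coefficient_of_variation(x) == pytest.approx(np.std(x, ddof=1) / 2.0 * 100)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 5.0, 2.0) == pytest.approx(0.0)

    def test_unit_case(self):
        assert cohens_d(1.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_domain_rmsd_summary_effect_size(self):
        # direct evaluation on the printed all-atom DBD/LBD summaries
        assert cohens_d(0.442, 0.078, 0.512, 0.150) == pytest.approx(0.586, abs=0.001)

    def test_symmetric_in_group_order(self):
        assert cohens_d(1.0, 0.5, 3.0, 0.7) == pytest.approx(cohens_d(3.0, 0.7, 1.0, 0.5))

    def test_both_sds_zero_errors(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 2.0, 0.0)


class TestPairedT:
    def test_identical_samples_t_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError):  # zero-variance differences
            paired_t(a, a)

    def test_constant_difference_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(size=15)
        t, p, sig = paired_t(a, b)
        ts, ps = sps.ttest_rel(a, b)
        assert t == pytest.approx(float(ts))
        assert p == pytest.approx(float(ps))
        assert sig == (p < 0.05)

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            _, _, sig = paired_t(a, b)
            rejections += sig
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestKruskal:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # ranks 1..6, H = 12/(6·7)·(6²/3 + 15²/3) − 3·7 = 3.857
        h, _ = kruskal_wallis([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-9)
        assert h == pytest.approx(3.857, abs=0.001)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.uniform(0, 1, 8) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(5 * g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestRegression:
    def test_identity_line(self):
        x = np.arange(5.0)
        slope, intercept, r = regression_slope(x, x)
        assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line(self):
        x = np.arange(5.0)
        slope, intercept, r = regression_slope(x, 2 * x + 1)
        assert (slope, intercept) == pytest.approx((2.0, 1.0))

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError):
            regression_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClustering:
    def test_identical_points_merge_at_zero(self):
        res = hierarchical_cluster({"a": (1.0, 1.0), "b": (1.0, 1.0), "c": (9.0, 0.0)})
        first = res["merges"][0]
        assert sorted(first[0] + first[1]) == ["a", "b"]
        assert first[2] == pytest.approx(0.0)

    def test_collinear_points_first_merge_nearest(self):
        res = hierarchical_cluster({"p0": (0.0, 0.0), "p1": (1.0, 0.5), "p10": (10.0, 3.0)})
        first = res["merges"][0]
        assert sorted(first[0] + first[1]) == ["p0", "p1"]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster({"a": (0.0, 0.0)})


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        res = anova_tukey([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_equal_mean_groups_no_significant_pairs(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 12) for _ in range(3)]
        res = anova_tukey(groups)
        assert not any(p["significant"] for p in res["pairwise"])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 1, 10)
        g3 = rng.normal(5, 1, 10)  # 5 SD shift
        res = anova_tukey([g1, g2, g3], group_names=["a", "b", "c"])
        sig = {
            frozenset((p["group1"], p["group2"])): p["significant"] for p in res["pairwise"]
        }
        assert sig[frozenset(("a", "c"))] and sig[frozenset(("b", "c"))]
        assert not sig[frozenset(("a", "b"))]


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps, expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02], [0.02, 0.04]),
            ([0.9, 0.9], [1.0, 1.0]),
        ],
    )
    def test_examples(self, ps, expected):
        assert bonferroni_adjust(ps) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


def test_summarize_quartiles_type7():
    s = summarize([1.0, 2.0, 3.0, 4.0])
    assert s.q1 == pytest.approx(1.75)  # linear-interpolation quartiles
    assert s.q3 == pytest.approx(3.25)
    assert s.iqr == pytest.approx(1.5)
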