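"""Measurement-properties statistics: agreement, validity, accuracy, planning."""

import numpy as np
import pytest
from scipy import stats as sst

from tremorkit.errors import DegenerateSignalError, ParameterError
from tremorkit.stats import (
    bland_altman,
    cohens_d,
    correlate,
    correlation_strength,
    group_compare,
    roc_analysis,
    sample_size,
)


def pairwise_concordance(scores, labels):
    """O(n²) oracle for the AUC: P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (pos.size * neg.size / 1)


class TestBlandAltman:
    def test_identical_series_flagged_degenerate(self, rng):
        a = rng.normal(size=10)
        res = bland_altman(a, a.copy())
        assert res.bias == 0
        assert np.all(res.dif == 0)
        assert res.degenerate
        assert np.isnan(res.t_p)

    def test_constant_offset_recovered_as_bias(self, rng):
        a = rng.normal(10, 2, 20)
        res = bland_altman(a, a - 2.0)
        assert res.bias == pytest.approx(2.0)
        assert res.pb_slope == pytest.approx(0.0, abs=1e-9)
        assert res.pb_p > 0.05
        assert res.loa_low <= res.bias <= res.loa_high

    def test_proportional_pairs_give_closed_form_slope(self):
        # b = a/2: dif = a/2 regressed on mu = 3a/4 has slope exactly 2/3
        a = np.arange(1.0, 21.0)
        res = bland_altman(a, 0.5 * a)
        assert res.pb_slope == pytest.approx(2.0 / 3.0)
        assert res.pb_p < 0.01
        assert res.bias == pytest.approx(np.mean(0.5 * a))

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias)

    def test_limits_use_196_sd(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = bland_altman(a, b)
        sd = np.std(a - b, ddof=1)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * sd)

    def test_one_sided_alternative_supported(self, rng):
        a = rng.normal(size=25)
        res = bland_altman(a + rng.normal(1.0, 0.1, 25), a, alternative="greater")
        assert res.t_p < 0.01

    def test_repetition_symmetry_fixture(self, rng):
        # reliability mode is the same computation on (M1, M2)
        m1 = rng.normal(5, 1, 12)
        m2 = m1 + rng.normal(0, 0.1, 12)
        res = bland_altman(m1, m2)
        assert res.n == 12
        assert res.loa_low <= res.bias <= res.loa_high

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ParameterError):
            bland_altman([1.0, 2, 3], [1.0, 2])


class TestCorrelate:
    def test_perfect_linear_is_one_either_method(self, rng):
        x = rng.normal(size=30)
        for policy in ("pearson", "spearman"):
            assert correlate(x, 2 * x + 1, policy)["r"] == pytest.approx(1.0)

    def test_cubic_monotone_spearman_one_pearson_below(self):
        x = np.arange(-5.0, 6.0)
        sp = correlate(x, x ** 3, "spearman")
        pe = correlate(x, x ** 3, "pearson")
        assert sp["r"] == pytest.approx(1.0)
        assert pe["r"] < 1.0

    def test_strength_labels(self):
        assert correlation_strength(0.55) == "moderate"
        assert correlation_strength(0.39) == "weak"
        assert correlation_strength(-0.85) == "strong"

    def test_auto_policy_gates_on_normality(self, rng):
        x = rng.normal(size=50)
        assert correlate(x, x + rng.normal(size=50), "auto")["method"] == "pearson"
        h = rng.standard_cauchy(500)
        assert correlate(h, h + rng.normal(size=500), "auto")["method"] == "spearman"

    def test_pearson_invariant_to_positive_affine(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r0 = correlate(x, y, "pearson")["r"]
        assert correlate(3 * x + 5, y, "pearson")["r"] == pytest.approx(r0)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(0.1, 5, 40)
        y = rng.normal(size=40)
        r0 = correlate(x, y, "spearman")["r"]
        assert correlate(np.exp(x), y, "spearman")["r"] == pytest.approx(r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            correlate([1.0, 1, 1, 1], [1.0, 2, 3, 4])


class TestGroupCompare:
    def test_identical_groups(self, rng):
        g = rng.normal(size=20)
        res = group_compare(g, g.copy())
        assert res["p"] > 0.9
        assert abs(res["effect_size"]) < 0.05

    def test_known_effect_selects_ttest(self, rng):
        g1 = rng.normal(1.0, 1.0, 200)
        g2 = rng.normal(0.0, 1.0, 200)
        res = group_compare(g1, g2)
        assert res["test"] == "t-test"
        assert res["p"] < 0.01
        assert res["effect_size"] == pytest.approx(1.0, abs=0.3)

    def test_heavy_tails_select_mann_whitney(self, rng):
        g1 = rng.standard_cauchy(200)
        g2 = rng.standard_cauchy(200) + 2
        res = group_compare(g1, g2)
        assert res["test"] == "mann-whitney"
        assert res["effect_type"] == "rank_biserial"
        assert -1 <= res["effect_size"] <= 1

    def test_cohens_d_sign_convention(self):
        assert cohens_d(np.array([2.0, 3, 4]), np.array([0.0, 1, 2])) > 0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ParameterError):
            group_compare([1.0, 2], [3.0, 4, 5])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == res.specificity == 1.0
        assert res.adequate

    def test_four_point_example(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 2 < res.cutoff <= 3
        assert res.sensitivity + res.specificity - 1 == pytest.approx(1.0)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(50):
            scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
            labels = rng.integers(0, 2, 200)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels)
            assert abs(res.auc - pairwise_concordance(scores, labels)) < 1e-12

    def test_inadequate_flag_below_07(self, rng):
        scores = rng.normal(size=400)
        labels = rng.integers(0, 2, 400)
        res = roc_analysis(scores, labels)
        assert not res.adequate

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_analysis([1.0, 2, 3], [1, 1, 1])


class TestSampleSize:
    def test_one_tailed_reference_design(self):
        # d = 0.70, 80% power, alpha 0.05, one-tailed: 26 per group
        assert sample_size(0.70, 0.80, 0.05, tails="one") == 26

    def test_two_tailed_same_design(self):
        assert sample_size(0.70, 0.80, 0.05, tails="two") == 34

    def test_returned_n_is_minimal(self):
        # the next smaller n must fall short of the power
        n = sample_size(0.70, 0.80, 0.05, tails="one")
        df = 2 * (n - 1) - 2
        ncp = 0.70 * np.sqrt((n - 1) / 2)
        tcrit = sst.t.ppf(0.95, df)
        assert sst.nct.sf(tcrit, df, ncp) < 0.80

    def test_doubling_effect_quarters_n(self):
        n1 = sample_size(0.5, 0.80, 0.05, tails="two")
        n2 = sample_size(1.0, 0.80, 0.05, tails="two")
        # normal-approximation check: n ~ 2 (z_a + z_b)^2 / d^2
        assert abs(n1 / 4 - n2) <= max(2.0, 0.15 * n1 / 4)

    def test_monotone_in_effect_and_power(self):
        assert sample_size(0.9) <= sample_size(0.6)
        assert sample_size(0.6, power=0.9) >= sample_size(0.6, power=0.8)

    def test_invalid_parameters_rejected(self):
        for kw in ({"effect_size": 0.0}, {"effect_size": 0.5, "power": 1.5},
                   {"effect_size": 0.5, "alpha": 0.0}):
            with pytest.raises(ParameterError):
                sample_size(**kw)

    def test_agrees_with_statsmodels_solver(self):
        # independent cross-check: ceil of the continuous solution
        from statsmodels.stats.power import TTestIndPower

        for d, alt, tails in ((0.7, "larger", "one"), (0.7, "two-sided", "two"),
                              (0.4, "two-sided", "two")):
            cont = TTestIndPower().solve_power(
                effect_size=d, power=0.8, alpha=0.05, alternative=alt)
            assert sample_size(d, 0.8, 0.05, tails) == int(np.ceil(cont))
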