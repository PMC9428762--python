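"""Routed statistics: diagnostics, two/three-group tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from heelpad.errors import InsufficientDataError, PairingError, ParameterError
from heelpad.stats import (
    Diagnostics,
    assess_distribution,
    compare_three_groups,
    compare_two_groups,
    correlation_matrix,
    route_omnibus,
    route_paired,
    route_unpaired,
    significance_stars,
    summarize_property,
    t_from_summary,
)
from heelpad.stats import _brown_forsythe_means, _posthoc_dunn, _rank_sum

SKEWED = np.array([1, 1, 1, 1, 2, 2, 3, 50, 60, 100] * 2, dtype=float)


def _diag(normal_a, normal_b, homosc):
    return Diagnostics(
        shapiro_ps=(0.5 if normal_a else 0.001, 0.5 if normal_b else 0.001),
        bartlett_p=0.5 if homosc else 0.001,
    )


class TestRouting:
    @pytest.mark.parametrize(
        "normal_a,normal_b,homosc,expected",
        [
            (True, True, True, "student_t"),
            (True, True, False, "welch_t"),
            (True, False, True, "wilcoxon"),
            (True, False, False, "wilcoxon"),
            (False, True, True, "wilcoxon"),
            (False, True, False, "wilcoxon"),
            (False, False, True, "wilcoxon"),
            (False, False, False, "wilcoxon"),
        ],
    )
    def test_unpaired_decision_table(self, normal_a, normal_b, homosc, expected):
        assert route_unpaired(_diag(normal_a, normal_b, homosc)) == expected

    @pytest.mark.parametrize(
        "normal_a,normal_b,homosc,expected",
        [
            (True, True, True, "anova"),
            (True, True, False, "brown_forsythe"),
            (False, True, True, "kruskal_wallis"),
            (True, False, False, "kruskal_wallis"),
        ],
    )
    def test_omnibus_decision_table(self, normal_a, normal_b, homosc, expected):
        assert route_omnibus(_diag(normal_a, normal_b, homosc)) == expected

    def test_paired_routing(self):
        normal = Diagnostics(shapiro_ps=(0.4,), bartlett_p=float("nan"))
        skew = Diagnostics(shapiro_ps=(0.01,), bartlett_p=float("nan"))
        assert route_paired(normal) == "paired_t"
        assert route_paired(skew) == "paired_wilcoxon"


class TestAssessDistribution:
    def test_gaussian_samples_flagged_normal_and_homoscedastic(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            d = assess_distribution(a, b)
            hits += d.all_normal and d.homoscedastic
        assert hits >= 80  # each of 3 tests falsely rejects ~5% of the time

    def test_skewed_sample_flagged_nonnormal(self):
        rng = np.random.default_rng(1)
        sample = SKEWED + rng.normal(0, 0.01, SKEWED.size)
        d = assess_distribution(sample, rng.normal(0, 1, 20))
        assert not d.normal[0]

    def test_variance_ratio_flagged_heteroscedastic(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 5, 20)
            hits += not assess_distribution(a, b).homoscedastic
        assert hits >= 90

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            assess_distribution([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_levene_option(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        d = assess_distribution(a, b, variance_test="levene")
        assert np.isfinite(d.bartlett_p)
        with pytest.raises(ParameterError):
            assess_distribution(a, b, variance_test="nope")


class TestCompareTwoGroups:
    def test_identical_paired_samples_null(self):
        a = np.array([3.0, 4.0, 5.0, 6.0])
        res = compare_two_groups(a, a.copy(), paired=True)
        assert res.test_name == "paired_t"
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_separated_gaussians_route_to_student_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 20), rng.normal(5, 1, 20)
        res = compare_two_groups(a, b)
        assert res.test_name == "student_t"
        assert res.p < 1e-3
        assert res.stars == "***"

    def test_heteroscedastic_normals_route_to_welch(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 6, 30)
        res = compare_two_groups(a, b)
        assert res.test_name == "welch_t"

    def test_skewed_sample_routes_to_rank_sum(self):
        rng = np.random.default_rng(13)
        res = compare_two_groups(SKEWED + rng.normal(0, 0.01, SKEWED.size),
                                 rng.normal(5, 1, 20))
        assert res.test_name == "wilcoxon"

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            if compare_two_groups(rng.normal(0, 1, 20),
                                  rng.normal(0, 1, 20)).significant:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_rank_sum_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(15)
        a = rng.exponential(1.0, 18)
        b = rng.exponential(2.0, 22)
        s1, p1 = _rank_sum(a, b)
        s2, p2 = _rank_sum(np.exp(a), np.exp(b))  # strictly monotone map
        assert s1 == s2
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_unequal_paired_lengths_rejected(self):
        with pytest.raises(PairingError):
            compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0], paired=True)

    def test_paired_differences_route_on_normality(self):
        rng = np.random.default_rng(16)
        base = rng.normal(10, 1, 20)
        res = compare_two_groups(base, base - rng.normal(1, 0.3, 20), paired=True)
        assert res.test_name == "paired_t"
        assert res.p < 1e-6


class TestTFromSummary:
    def test_published_age_comparison(self):
        # printed group summaries 64.4+/-3.4 vs 67.8+/-4.9, n=10 each
        t, df, p = t_from_summary(10, 64.4, 3.4, 10, 67.8, 4.9)
        assert abs(t) == pytest.approx(1.80, abs=0.005)
        assert df == 18
        assert p == pytest.approx(0.088, abs=0.001)

    def test_equal_means_give_null(self):
        t, _, p = t_from_summary(8, 5.0, 1.0, 12, 5.0, 2.0)
        assert t == 0.0
        assert p == 1.0

    def test_matches_raw_sample_t(self):
        # engineer raw samples with exactly the requested summaries
        rng = np.random.default_rng(17)

        def sample(n, mean, sd):
            z = rng.normal(0, 1, n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        n1, m1, s1, n2, m2, s2 = 14, 3.2, 1.1, 9, 4.0, 0.8
        a, b = sample(n1, m1, s1), sample(n2, m2, s2)
        t_raw = sps.ttest_ind(a, b, equal_var=True)
        t_sum, _, p_sum = t_from_summary(n1, m1, s1, n2, m2, s2)
        assert t_sum == pytest.approx(float(t_raw.statistic), rel=1e-9)
        assert p_sum == pytest.approx(float(t_raw.pvalue), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            t_from_summary(1, 0, 1, 10, 0, 1)
        with pytest.raises(ParameterError):
            t_from_summary(10, 0, 0, 10, 0, 1)


class TestThreeGroups:
    def test_null_omnibus_rarely_rejects(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            res = compare_three_groups(*groups)
            hits += not res.significant
            if not res.significant:
                assert res.posthoc is None
        assert hits >= 90

    def test_posthoc_isolates_shifted_group(self):
        rng = np.random.default_rng(22)
        res = compare_three_groups(
            rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(5, 1, 10),
            labels=("a", "b", "c"),
        )
        assert res.significant
        ph = res.posthoc.set_index(["group1", "group2"])
        assert ph.loc[("a", "c"), "significant"].item()
        assert ph.loc[("b", "c"), "significant"].item()
        assert not ph.loc[("a", "b"), "significant"].item()

    def test_brown_forsythe_reduces_to_anova_when_balanced(self):
        # equal n: F* equals the ANOVA F statistic exactly
        rng = np.random.default_rng(23)
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.4, 1.0)]
        fstar, df2, _ = _brown_forsythe_means(groups)
        f_anova = float(sps.f_oneway(*groups).statistic)
        assert fstar == pytest.approx(f_anova, rel=1e-12)
        assert df2 <= 33  # Satterthwaite df never exceeds N - k

    def test_dunn_squares_to_kruskal_for_two_groups(self):
        rng = np.random.default_rng(24)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        ph = _posthoc_dunn([a, b], ["a", "b"])
        h = float(sps.kruskal(a, b).statistic)
        assert ph["statistic"].iloc[0] ** 2 == pytest.approx(h, rel=1e-9)

    def test_snk_reduces_to_student_t_for_two_groups(self):
        from heelpad.stats import _posthoc_snk

        rng = np.random.default_rng(25)
        a, b = rng.normal(0, 1, 10), rng.normal(1.2, 1, 10)
        ph = _posthoc_snk([a, b], ["a", "b"])
        p_t = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        assert ph["p"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_arity_and_size_errors(self):
        with pytest.raises(InsufficientDataError):
            compare_three_groups([1.0, 2.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_self_and_anticorrelation(self):
        x = np.linspace(0, 1, 20)
        table = pd.DataFrame({"x": x, "negx": -x, "x2": x})
        mats = correlation_matrix(table, ["x", "negx", "x2"])
        assert mats["r"].loc["x", "x2"] == pytest.approx(1.0)
        assert mats["r"].loc["x", "negx"] == pytest.approx(-1.0)
        assert np.all(np.diag(mats["r"]) == 1.0)

    def test_sampling_distribution_around_true_rho(self):
        rng = np.random.default_rng(31)
        rho = 0.6
        hits = 0
        for _ in range(100):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 20)
            table = pd.DataFrame(z, columns=["u", "v"])
            r = correlation_matrix(table, ["u", "v"])["r"].loc["u", "v"]
            hits += abs(r - rho) <= 0.25
        assert hits >= 90

    def test_constant_column_flagged_not_crashing(self):
        table = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        mats = correlation_matrix(table, ["x", "c"])
        assert "c" in mats["constant_columns"]
        assert np.isnan(mats["r"].loc["x", "c"])

    def test_star_tiers(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.07) == "."
        assert significance_stars(0.5) == ""


class TestSummaries:
    def test_gaussian_sample_uses_mean_sd_form(self):
        rng = np.random.default_rng(41)
        s = summarize_property(rng.normal(10, 2, 30))
        assert s.normal
        assert "±" in s.text

    def test_skewed_sample_uses_median_range_form(self):
        # heavily skewed data are reported "median (range: min~max)",
        # the style used for disease-course durations
        sample = SKEWED + np.random.default_rng(42).normal(0, 0.01, SKEWED.size)
        s = summarize_property(sample)
        assert not s.normal
        assert "range:" in s.text
        assert s.median == pytest.approx(np.median(sample), abs=1e-9)
        assert s.text.startswith(f"{np.median(sample):.2f} (range: ")

    def test_constant_sample_degenerates_to_median_range(self):
        s = summarize_property([4.0, 4.0, 4.0, 4.0])
        assert not s.normal
        assert s.text == "4.00 (range: 4.00~4.00)"
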