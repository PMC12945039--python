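"""Cohort statistics: exclusion, fold changes, rank tests, Cox, Kaplan-Meier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ki67quant.cohort import (
    benjamini_hochberg,
    compare_groups,
    cox_univariable,
    exclude_inflamed,
    fold_change,
    interlab_intensity_compare,
    km_dichotomize,
    pi_category_summary,
    resolve_events,
    round_half_away,
    spearman_correlation,
    webster_summary,
)
from ki67quant.synthetic import generate_cohort


class TestExcludeInflamed:
    def test_keeps_scores_one_and_two(self):
        df = pd.DataFrame({"q_inflammation": [0, 1, 2, 0, 2], "x": range(5)})
        out = exclude_inflamed(df)
        assert list(out.x) == [1, 2, 4]

    def test_all_clean_is_identity(self):
        df = pd.DataFrame({"q_inflammation": [2, 2], "x": [1, 2]})
        assert len(exclude_inflamed(df)) == 2

    def test_all_marked_empties_cohort(self):
        df = pd.DataFrame({"q_inflammation": [0, 0], "x": [1, 2]})
        assert len(exclude_inflamed(df)) == 0


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (26, 21, -1.24),  # H-score means before/after exclusion
            (14, 11, -1.27),  # PI means before/after exclusion
            (5, 5, 1.0),
            (10, 14, 1.4),
        ],
    )
    def test_signed_ratio_convention(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected)

    def test_antisymmetry(self):
        for a, b in [(26, 21), (3, 7), (1.5, 4.2)]:
            assert fold_change(a, b) == pytest.approx(-fold_change(b, a))

    def test_nonpositive_mean_undefined(self):
        assert np.isnan(fold_change(0.0, 5.0))


class TestSummaries:
    def test_webster_cohort_percentages(self):
        cats = ["low"] * 149 + ["high"] * 93
        out = webster_summary(cats).set_index("category")
        assert out.loc["low", "n"] == 149 and out.loc["low", "percent"] == 62
        assert out.loc["high", "n"] == 93 and out.loc["high", "percent"] == 38

    @pytest.mark.parametrize(
        "lows,highs,p_low,p_high", [(1, 1, 50, 50), (2, 1, 67, 33)]
    )
    def test_rounding_half_away(self, lows, highs, p_low, p_high):
        out = webster_summary(["low"] * lows + ["high"] * highs).set_index("category")
        assert out.loc["low", "percent"] == p_low
        assert out.loc["high", "percent"] == p_high

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            webster_summary([])

    def test_percentages_sum_to_100_within_rounding(self, rng):
        for _ in range(20):
            n_low, n_high = rng.integers(1, 400, size=2)
            out = webster_summary(["low"] * n_low + ["high"] * n_high)
            assert abs(out.percent.sum() - 100) <= 1

    def test_pi_categories_all_and_excluded(self):
        pi = [10.0] * 186 + [20.0] * 81 + [40.0] * 39
        q = [1] * 143 + [0] * 43 + [0] * 54 + [1] * 27 + [1] * 27 + [0] * 12
        df = pd.DataFrame({"pi_percent": pi, "q_inflammation": q})
        out = pi_category_summary(df).set_index(["subset", "category"])
        assert out.loc[("all", "low_pi"), "percent"] == 61  # 186/306
        assert out.loc[("all", "high_pi"), "percent"] == 13  # 39/306
        assert out.loc[("excluded", "low_pi"), "n"] == 143

    def test_all_zero_pi_is_all_low(self):
        df = pd.DataFrame({"pi_percent": [0.0] * 7})
        out = pi_category_summary(df, inflammation_col=None).set_index("category")
        assert out.loc["low_pi", "percent"] == 100

    def test_round_half_away(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(61.4) == 61


class TestCompareGroups:
    def test_exact_p_for_tiny_groups(self):
        res = compare_groups([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.name.endswith("exact")
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_give_p_one(self):
        res = compare_groups([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_agrees_with_scipy_enumeration_for_small_groups(self, rng):
        """All group sizes up to 5, tie-free data: match scipy's exact test."""
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                labels = ["a"] * n1 + ["b"] * n2
                ours = compare_groups(vals, labels)
                ref = sps.mannwhitneyu(
                    vals[:n1], vals[n1:], alternative="two-sided", method="exact"
                )
                assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_groups_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(1, 1, 45)
        res = compare_groups(
            np.concatenate([x, y]), ["a"] * 40 + ["b"] * 45
        )
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_three_identical_groups_kruskal_zero(self):
        res = compare_groups([3.0] * 9, ["a", "b", "c"] * 3)
        assert res.name == "kruskal-wallis"
        assert res.statistic == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestSpearman:
    def test_monotone_limits(self):
        inc = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        dec = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert inc.effect == pytest.approx(1.0)
        assert dec.effect == pytest.approx(-1.0)

    def test_hand_ranked_five_pairs(self):
        # ranks differ by d = (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.effect == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        res = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.statistic) and "constant" in res.note


class TestCox:
    def test_constant_metric_carries_no_information(self):
        df = generate_cohort(50, 0.0, 0.002, 2000, seed=2)
        res = cox_univariable(np.zeros(50), df.survival_days, df.event)
        assert res.effect == 1.0 and res.statistic == 0.0

    def test_negated_metric_inverts_hazard_ratio(self):
        df = generate_cohort(120, np.log(2), 0.002, 2000, seed=3)
        res = cox_univariable(df.metric, df.survival_days, df.event)
        res_neg = cox_univariable(-df.metric, df.survival_days, df.event)
        assert res_neg.effect == pytest.approx(1.0 / res.effect, rel=1e-6)

    def test_null_effect_recovers_unit_hazard_ratio(self):
        df = generate_cohort(400, 0.0, 0.002, 2000, seed=4)
        res = cox_univariable(df.metric, df.survival_days, df.event)
        lo, hi = res.ci
        assert lo <= 1.0 <= hi

    def test_censor_rules(self):
        flags = np.array(["died-MCT", "died-other", "alive", "died-MCT"])
        assert resolve_events(flags, "all-deaths").tolist() == [True, True, False, True]
        assert resolve_events(flags, "mct-only").tolist() == [True, False, False, True]
        with pytest.raises(ValueError):
            resolve_events(flags, "bogus")

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="two events"):
            cox_univariable([1.0, 2.0], [10.0, 20.0], [False, False])


class TestKaplanMeier:
    def _toy(self):
        # 6-record single-group toy joined with a far-away high group
        low = pd.DataFrame({
            "metric": 0.0,
            "survival_days": [1, 2, 3, 4, 5, 6],
            "event": [True, True, False, True, False, True],
        })
        high = pd.DataFrame({
            "metric": 10.0,
            "survival_days": [7, 8, 9, 10, 11, 12],
            "event": [True] * 6,
        })
        return pd.concat([low, high], ignore_index=True)

    def test_median_split_rule(self):
        df = pd.DataFrame({
            "metric": [1.0, 2.0, 3.0, 4.0],
            "survival_days": [5.0, 6.0, 7.0, 8.0],
            "event": [True] * 4,
        })
        res = km_dichotomize(df, "metric")
        # median 2.5: {1,2} low, {3,4} high
        assert res.n_low == 2 and res.n_high == 2
        # ties at an explicit threshold go to the low group
        res2 = km_dichotomize(df, "metric", threshold=3.0)
        assert res2.n_low == 3 and res2.n_high == 1

    def test_product_limit_matches_hand_computation(self):
        res = km_dichotomize(self._toy(), "metric")
        low = res.curve_table[res.curve_table.group == "low"].set_index("time")
        assert low.loc[1, "survival"] == pytest.approx(5 / 6)
        assert low.loc[2, "survival"] == pytest.approx(2 / 3)
        assert low.loc[3, "survival"] == pytest.approx(2 / 3)  # censored
        assert low.loc[4, "survival"] == pytest.approx(4 / 9)
        assert low.loc[6, "survival"] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(100, size=25).round(1)
        df = pd.DataFrame({
            "metric": np.concatenate([np.zeros(25), np.ones(25)]),
            "survival_days": np.concatenate([times, times + 1000]),
            "event": True,
        })
        res = km_dichotomize(df, "metric", threshold=0.5)
        low = res.curve_table[res.curve_table.group == "low"]
        for t, s in zip(low.time, low.survival):
            assert s == pytest.approx((times > t).mean())

    def test_degenerate_split_flagged(self):
        df = pd.DataFrame({
            "metric": [1.0, 1.0], "survival_days": [5.0, 6.0], "event": [True, True]
        })
        res = km_dichotomize(df, "metric")
        assert res.flagged


class TestInterlab:
    def test_identical_distributions_zero_difference(self):
        vals = [100.0, 110.0, 120.0, 100.0, 110.0, 120.0]
        res = interlab_intensity_compare(vals, ["de"] * 3 + ["ch"] * 3)
        assert res.effect == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_shift_detected(self, rng):
        a = rng.normal(100, 5, 400)
        b = a + 2.0  # a 2-unit protocol shift
        res = interlab_intensity_compare(
            np.concatenate([a, b]), ["de"] * 400 + ["ch"] * 400
        )
        assert res.effect == pytest.approx(2.0, abs=0.01)
        assert res.p_value < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            interlab_intensity_compare([1.0, 2.0], ["de", "de"])


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
    assert adj[0] == pytest.approx(0.004)
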