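"""Exact nonparametric tests vs brute-force enumeration and scipy,
screening filters and group summaries."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from arcpk.cohort import (
    GroupSummary,
    ReferenceRanges,
    infection_screen,
    linear_trend_test,
    mann_whitney_u,
    summarize_group,
    urine_completeness_filter,
    wilcoxon_signed_rank,
)
from arcpk.exceptions import DegenerateInputError, DomainError
from arcpk.study_data import AnimalRecord, Hematology, UrineInterval


# -- independent brute-force oracles ----------------------------------------

def brute_wilcoxon_p(d, alternative):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(np.array(signs) * ranks)
          for signs in product([0, 1], repeat=d.size)]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def brute_mwu_p(x, y, alternative):
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = x.size

    def u_of(sel):
        xs = pooled[list(sel)]
        ys = np.delete(pooled, list(sel))
        return np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :])

    u_obs = u_of(range(n))
    us = np.array([u_of(sel) for sel in combinations(range(pooled.size), n)])
    p_ge = np.mean(us >= u_obs - 1e-9)
    p_le = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxonSignedRank:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], "greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 8)

    def test_all_negative_one_sided_greater(self):
        res = wilcoxon_signed_rank([-1.0, -2.0, -3.0], "greater")
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0], "two-sided")

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = np.round(rng.normal(0.3, 1.0, n), 6)  # continuous -> no ties
        res = wilcoxon_signed_rank(d, alternative)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_wilcoxon_p(d, alternative))

    @pytest.mark.parametrize("alternative,scipy_alt", [
        ("greater", "greater"), ("less", "less"), ("two-sided", "two-sided")])
    def test_matches_scipy_exact(self, alternative, scipy_alt):
        rng = np.random.default_rng(42)
        d = rng.normal(0.5, 1.0, 10)
        res = wilcoxon_signed_rank(d, alternative)
        ref = stats.wilcoxon(d, alternative=scipy_alt, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.0, 30)
        res = wilcoxon_signed_rank(d, "greater")
        assert res.method == "approximate"
        ref = stats.wilcoxon(d, alternative="greater", method="approx",
                             correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitneyU:
    def test_complete_separation_small(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0], "less")
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 6)

    def test_single_observations(self):
        res = mann_whitney_u([1.0], [2.0], "less")
        assert res.p_value == pytest.approx(1 / 2)

    def test_identical_singletons_two_sided(self):
        res = mann_whitney_u([5.0], [5.0], "two-sided")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0], "two-sided")

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed, alternative):
        rng = np.random.default_rng(100 + seed)
        n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        x = np.round(rng.normal(0.0, 1.0, n), 6)
        y = np.round(rng.normal(0.5, 1.0, m), 6)
        res = mann_whitney_u(x, y, alternative)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_mwu_p(x, y, alternative))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        res = mann_whitney_u(x, y, "less")
        ref = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        res = mann_whitney_u(x, y, "less")
        assert res.method == "approximate"
        ref = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic",
                                 use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestTypeIError:
    """Exact tests keep their size near the nominal 5 % under H0 at the
    study's sample sizes."""

    def test_wilcoxon_exact_size_at_n11(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            d = rng.normal(0.0, 1.0, 11)
            if wilcoxon_signed_rank(d, "greater").p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_mwu_exact_size_at_7_vs_7(self):
        rng = np.random.default_rng(2025)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(0, 1, 7), rng.normal(0, 1, 7)
            if mann_whitney_u(x, y, "greater").p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestOneVsTwoSidedConvention:
    def test_doubling_convention(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 8)
        p1g = wilcoxon_signed_rank(d, "greater").p_value
        p1l = wilcoxon_signed_rank(d, "less").p_value
        p2 = wilcoxon_signed_rank(d, "two-sided").p_value
        assert p2 == pytest.approx(min(1.0, 2.0 * min(p1g, p1l)))


class TestLinearTrend:
    def test_flat_series(self):
        slope, p = linear_trend_test([0, 12, 24, 36], [30.0, 30.0, 30.0, 30.0])
        assert slope == 0.0
        assert p == pytest.approx(1.0)

    def test_exact_linear_series(self):
        slope, p = linear_trend_test([0, 12, 24, 36], [30.0, 31.0, 32.0, 33.0])
        assert slope == pytest.approx(1 / 12)
        assert p < 1e-6

    def test_identical_times_rejected(self):
        with pytest.raises(DomainError):
            linear_trend_test([1, 1, 1], [1.0, 2.0, 3.0])

    def test_null_p_values_roughly_uniform(self):
        """Under H0 the p-value distribution is approximately uniform."""
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(500):
            t = np.array([0.0, 12.0, 24.0, 36.0])
            ps.append(linear_trend_test(t, rng.normal(30, 2, 4))[1])
        ps = np.asarray(ps)
        # coarse uniformity: mean ~0.5 and tail mass ~10 % below 0.1
        assert abs(ps.mean() - 0.5) < 0.06
        assert 0.05 < np.mean(ps < 0.1) < 0.16


def _animal(leuk_m2=17000.0, neut_m2=6000.0, dt=0.0, lymph_m1=9000.0):
    rec = AnimalRecord(animal_id="X", group="control")
    rec.body_temperature = {"M1": 39.2, "M2": 39.2 + dt}
    rec.hematology = {
        "M1": Hematology(17000.0, 6000.0, lymph_m1, 700.0),
        "M2": Hematology(leuk_m2, neut_m2, 9000.0, 700.0),
    }
    return rec


class TestInfectionScreen:
    def test_leukocytosis_with_fever_excluded(self):
        d = infection_screen(_animal(leuk_m2=32690.0, neut_m2=23341.0, dt=1.2))
        assert not d.include
        assert "leukocytosis" in d.reason and "delta_t:+1.2C" in d.reason

    def test_normal_animal_included(self):
        assert infection_screen(_animal()).include

    def test_lymphocyte_outlier_without_fever_included(self):
        # an isolated lymphocyte elevation with normal temperature stays in
        assert infection_screen(_animal(lymph_m1=20000.0)).include

    def test_counts_without_fever_included(self):
        assert infection_screen(_animal(leuk_m2=32690.0, dt=0.0)).include

    def test_fever_without_counts_included(self):
        assert infection_screen(_animal(dt=1.5)).include


class TestUrineFilter:
    def _intervals(self, leaked=False):
        return [UrineInterval(0, 2, 50, 100, leaked=leaked),
                UrineInterval(2, 4, 50, 80)]

    def test_leak_at_one_occasion_makes_ineligible(self):
        assert not urine_completeness_filter(
            {"M1": self._intervals(leaked=True), "M2": self._intervals()})

    def test_no_leaks_eligible(self):
        assert urine_completeness_filter(
            {"M1": self._intervals(), "M2": self._intervals()})

    def test_leaks_at_both_ineligible(self):
        assert not urine_completeness_filter(
            {"M1": self._intervals(leaked=True),
             "M2": self._intervals(leaked=True)})

    def test_missing_occasion_ineligible(self):
        assert not urine_completeness_filter({"M1": self._intervals()})


class TestSummaries:
    def test_odd_sample(self):
        s = summarize_group([1.0, 2.0, 3.0])
        assert s.median == 2.0

    def test_interpolated_quartiles(self):
        s = summarize_group([1.0, 2.0, 3.0, 4.0])
        assert (s.median, s.p25, s.p75) == (2.5, 1.75, 3.25)

    def test_single_value(self):
        s = summarize_group([7.0])
        assert s.median == s.p25 == s.p75 == 7.0
        assert s.p25 <= s.median <= s.p75
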