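"""Nonparametric group comparisons, trend test, screening filters, summaries.

The study's sample sizes (11-12 animals per arm) put its hypothesis tests in
the regime where exact small-sample null distributions matter, so the
Wilcoxon signed-rank and Mann-Whitney U tests enumerate their exact null
distributions when feasible (signed-rank: n <= 12 after dropping zero
differences and no ties in |d|; Mann-Whitney: n + m <= 14 and no cross-group
ties) and otherwise use the tie-corrected normal approximation with a
continuity correction.  Two-sided exact p-values use the doubling
convention p_two = min(1, 2·min(P(T <= t), P(T >= t))).

Screening mirrors the study's exclusion rules: an animal is excluded from
all calculations when an inflammation signal (leukocyte or neutrophil count
above the upper reference bound) coincides with a body-temperature rise
between occasions; an animal is excluded from renal-clearance calculations
when either occasion's urine collection leaked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DomainError, ValidationError
from .study_data import AnimalRecord, OCCASIONS, UrineInterval

__all__ = [
    "TestResult",
    "GroupSummary",
    "ReferenceRanges",
    "ScreenDecision",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "linear_trend_test",
    "infection_screen",
    "urine_completeness_filter",
    "summarize_group",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str  # "exact" | "approximate"
    n: int
    m: int | None = None


@dataclass(frozen=True)
class GroupSummary:
    parameter: str
    group: str
    occasion: str
    median: float
    p25: float
    p75: float
    n: int


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise DomainError(f"alternative must be one of {_ALTERNATIVES}")


def wilcoxon_signed_rank(diffs, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention).  ``alternative``
    "greater" means the differences tend to be positive.  Statistic is W+,
    the sum of ranks of positive differences.
    """
    _check_alternative(alternative)
    d = np.asarray(list(diffs), dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= 12 and not has_ties:
        r = ranks.astype(int)
        # all 2^n sign patterns, vectorised
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        w_all = signs @ r
        p_ge = float(np.mean(w_all >= w_plus - 1e-9))
        p_le = float(np.mean(w_all <= w_plus + 1e-9))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(absd, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise DegenerateInputError("zero variance in signed-rank null")
        sd = math.sqrt(var)
        p_ge = float(stats.norm.sf((w_plus - mu - 0.5) / sd))
        p_le = float(stats.norm.cdf((w_plus - mu + 0.5) / sd))
        method = "approximate"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(statistic=w_plus, p_value=p, alternative=alternative,
                      method=method, n=n)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test; ``alternative`` refers to *x* relative to *y*.

    Statistic is U_x (number of (x, y) pairs with x > y, ties counted half).
    """
    _check_alternative(alternative)
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise DomainError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    cross_ties = bool(np.intersect1d(x, y).size)

    if n + m <= 14 and not cross_ties:
        pooled = np.concatenate([x, y])
        # value-level comparison matrix; U(sel) = sum over sel x complement
        gt = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(gt, 0.0)
        sel = np.zeros((math.comb(n + m, n), n + m))
        for k, c in enumerate(combinations(range(n + m), n)):
            sel[k, list(c)] = 1.0
        a = sel @ gt  # K x N partial sums
        u_all = a.sum(axis=1) - np.einsum("kn,kn->k", a, sel)
        p_ge = float(np.mean(u_all >= u_obs - 1e-9))
        p_le = float(np.mean(u_all <= u_obs + 1e-9))
        method = "exact"
    else:
        mu = n * m / 2.0
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        nm = n + m
        tie_term = float(np.sum(counts**3 - counts)) / (nm * (nm - 1))
        var = n * m / 12.0 * (nm + 1 - tie_term)
        if var <= 0:
            # all pooled values identical: no evidence either way
            return TestResult(statistic=u_obs, p_value=1.0, alternative=alternative,
                              method="approximate", n=n, m=m)
        sd = math.sqrt(var)
        p_ge = float(stats.norm.sf((u_obs - mu - 0.5) / sd))
        p_le = float(stats.norm.cdf((u_obs - mu + 0.5) / sd))
        method = "approximate"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(statistic=u_obs, p_value=p, alternative=alternative,
                      method=method, n=n, m=m)


def linear_trend_test(times, values) -> tuple[float, float]:
    """OLS slope of value on time with a two-sided t-test on slope = 0."""
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if t.size != v.size or t.size < 3:
        raise DomainError("trend test needs >= 3 paired observations")
    if np.unique(t).size < 2:
        raise DomainError("all times identical; slope undefined")
    if np.unique(t).size < 3:
        raise DomainError("trend test needs >= 3 distinct time points")
    res = stats.linregress(t, v)
    slope, p = float(res.slope), float(res.pvalue)
    if math.isnan(p):
        # perfect fit: residual variance 0 -> p is 1 for a flat series
        # (slope exactly 0) and 0 for any exact non-zero trend
        p = 1.0 if slope == 0.0 else 0.0
    return slope, p


@dataclass(frozen=True)
class ReferenceRanges:
    """Upper reference bounds for the inflammation screen (cells/µL)."""

    leukocytes_upper: float = 22_800.0
    neutrophils_upper: float = 9_600.0


@dataclass(frozen=True)
class ScreenDecision:
    include: bool
    reason: str | None = None  # machine-readable exclusion reason


def infection_screen(animal: AnimalRecord,
                     ref_ranges: ReferenceRanges | None = None,
                     delta_t_threshold: float = 1.0) -> ScreenDecision:
    """Exclude an animal when an out-of-range leukocyte or neutrophil count
    coincides with a body-temperature rise of at least *delta_t_threshold* °C
    between occasions."""
    ref = ref_ranges or ReferenceRanges()
    for occ in OCCASIONS:
        if occ not in animal.hematology or occ not in animal.body_temperature:
            raise ValidationError(
                f"{animal.animal_id}: hematology/temperature missing for {occ}"
            )
    delta_t = animal.body_temperature["M2"] - animal.body_temperature["M1"]
    flags = []
    for occ in OCCASIONS:
        h = animal.hematology[occ]
        if h.leukocytes > ref.leukocytes_upper:
            flags.append(f"leukocytosis@{occ}:{h.leukocytes:.0f}")
        if h.neutrophils > ref.neutrophils_upper:
            flags.append(f"neutrophilia@{occ}:{h.neutrophils:.0f}")
    if flags and delta_t >= delta_t_threshold:
        return ScreenDecision(include=False,
                              reason=";".join(flags) + f";delta_t:{delta_t:+.1f}C")
    return ScreenDecision(include=True)


def urine_completeness_filter(
        urine_by_occasion: Mapping[str, Sequence[UrineInterval]]) -> bool:
    """True (eligible for CL_R) iff both occasions have leak-free collections."""
    for occ in OCCASIONS:
        intervals = urine_by_occasion.get(occ)
        if not intervals or any(iv.leaked for iv in intervals):
            return False
    return True


def summarize_group(values, parameter: str = "", group: str = "",
                    occasion: str = "") -> GroupSummary:
    """Median and quartiles (linear interpolation) for one summary cell."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("empty summary cell")
    p25, med, p75 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(parameter=parameter, group=group, occasion=occasion,
                        median=float(med), p25=float(p25), p75=float(p75),
                        n=int(arr.size))
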