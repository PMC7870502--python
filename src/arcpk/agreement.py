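"""Test-retest reproducibility and between-marker agreement statistics.

Duplicate determinations (a clearance measured twice in the same animal) are
summarised by the per-subject coefficient of variation CV_i = 100·sd/mean
(sd = |x1-x2|/sqrt(2) for a duplicate) and pooled into the reproducibility

    R = sqrt( sum_i CV_i^2 / n )

the quadratic mean of the per-subject CVs, which is never below their
arithmetic mean.  Agreement between two measurements or two markers uses the
Bland-Altman construction with, in percent mode, each pair's difference
expressed relative to the pair mean: d_i = 100·(b_i - a_i)/mean(a_i, b_i),
bias = mean(d) and 95 % limits of agreement bias ± 1.96·sd(d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DomainError, InsufficientDataError

__all__ = [
    "AgreementResult",
    "ReproducibilitySummary",
    "duplicate_cv",
    "reproducibility",
    "bland_altman",
    "pearson_r",
]


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_lower: float
    loa_upper: float
    per_pair_diffs: tuple[float, ...]
    n: int
    mode: str  # "percent" | "absolute"


@dataclass(frozen=True)
class ReproducibilitySummary:
    n: int
    cvs: tuple[float, ...]  # per-subject duplicate CV (%)
    mean_cv: float          # arithmetic mean (%)
    r_pct: float            # quadratic mean (%)


def duplicate_cv(x1: float, x2: float) -> float:
    """Duplicate-determination CV (%): 100·(|x1-x2|/sqrt(2)) / mean(x1,x2)."""
    if not (x1 > 0 and x2 > 0):
        raise DomainError("duplicate CV needs positive measurements")
    sd = abs(x1 - x2) / math.sqrt(2.0)
    return 100.0 * sd / ((x1 + x2) / 2.0)


def reproducibility(cvs) -> float:
    """Quadratic-mean reproducibility R (%) from per-subject CVs (%)."""
    arr = np.asarray(list(cvs), dtype=float)
    if arr.size == 0:
        raise DomainError("reproducibility needs at least one CV")
    if np.any(arr < 0):
        raise DomainError("CVs must be >= 0")
    return float(np.sqrt(np.mean(arr**2)))


def summarize_duplicates(pairs) -> ReproducibilitySummary:
    """Per-subject CVs, their mean and R for a list of duplicate pairs."""
    cvs = tuple(duplicate_cv(a, b) for a, b in pairs)
    return ReproducibilitySummary(
        n=len(cvs), cvs=cvs,
        mean_cv=float(np.mean(cvs)), r_pct=reproducibility(cvs),
    )


def bland_altman(pairs, mode: str = "percent") -> AgreementResult:
    """Bland-Altman bias and 95 % limits of agreement.

    ``mode="percent"``: d_i = 100·(b_i - a_i)/mean(a_i, b_i) (pair-mean
    denominator); ``mode="absolute"``: d_i = b_i - a_i.  Limits use the
    1.96 multiplier with an n-1 standard deviation.
    """
    if mode not in ("percent", "absolute"):
        raise DomainError("mode must be 'percent' or 'absolute'")
    pairs = list(pairs)
    if len(pairs) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    diffs = []
    for a, b in pairs:
        if mode == "percent":
            m = (a + b) / 2.0
            if not m > 0:
                raise DomainError("percent mode needs positive pair means")
            diffs.append(100.0 * (b - a) / m)
        else:
            diffs.append(b - a)
    arr = np.asarray(diffs)
    bias = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return AgreementResult(bias=bias, loa_lower=bias - 1.96 * sd,
                           loa_upper=bias + 1.96 * sd,
                           per_pair_diffs=tuple(diffs), n=len(diffs), mode=mode)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p (t-distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("Pearson correlation needs n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
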