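"""Urinary excretion, renal clearance, urine output and plasma-volume change.

Renal clearance follows the excretion-over-exposure definition
CL_R = Ae / AUC_0->inf, where Ae is the cumulative amount of unchanged
compound recovered in urine and AUC the systemic exposure; with Ae in mg/kg
and AUC in ng·h/mL the result is mL/min/kg.  Plasma-volume change is the
van Beaumont hematocrit transformation, which assumes a constant circulating
red-cell volume so that a hematocrit shift is attributed entirely to plasma
water:

    %dP = [100 / (100 - H1)] · [100 · (H1 - H2) / H2]

H1 being the pre-fluid hematocrit and H2 the value at a later time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import DomainError, IncompleteCollectionError, ValidationError
from .study_data import UrineInterval

__all__ = [
    "ExcretionSummary",
    "PlasmaVolumeChange",
    "cumulative_excretion",
    "renal_clearance",
    "urine_output_rate",
    "plasma_volume_change",
]


@dataclass(frozen=True)
class ExcretionSummary:
    """Cumulative urinary recovery for one animal/occasion."""

    ae: float               # mg per kg body weight
    collection_span: float  # h covered by the intervals
    complete: bool          # False if any interval leaked


@dataclass(frozen=True)
class PlasmaVolumeChange:
    time_h: float
    pct_change: float


def cumulative_excretion(intervals: Sequence[UrineInterval],
                         body_weight: float) -> ExcretionSummary:
    """Sum amount excreted over all collection intervals, per kg body weight.

    Amount per interval is volume (mL) x concentration (µg/mL) = µg; the
    total is converted to mg and indexed to the occasion's body weight.
    """
    if not body_weight > 0:
        raise DomainError("body_weight must be > 0")
    ordered = sorted(intervals, key=lambda iv: iv.start_h)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_h < a.end_h - 1e-12:
            raise ValidationError("urine intervals overlap")
    total_ug = sum(iv.volume_ml * iv.conc_ug_per_ml for iv in ordered)
    span = (ordered[-1].end_h - ordered[0].start_h) if ordered else 0.0
    complete = not any(iv.leaked for iv in ordered)
    return ExcretionSummary(ae=total_ug / 1e3 / body_weight,
                            collection_span=span, complete=complete)


def renal_clearance(ae: float, auc_inf: float) -> float:
    """CL_R (mL/min/kg) from Ae (mg/kg) and AUC_0->inf (ng·h/mL)."""
    if not auc_inf > 0:
        raise DomainError(f"auc_inf must be > 0, got {auc_inf}")
    if ae < 0:
        raise DomainError(f"ae must be >= 0, got {ae}")
    return ae * 1e6 / auc_inf / 60.0


def urine_output_rate(intervals: Sequence[UrineInterval],
                      body_weight: float) -> float:
    """Urine output (mL/kg/h) over a complete (leak-free) collection."""
    if not body_weight > 0:
        raise DomainError("body_weight must be > 0")
    if not intervals:
        raise DomainError("no urine intervals")
    if any(iv.leaked for iv in intervals):
        raise IncompleteCollectionError("leaked interval present; output rate undefined")
    ordered = sorted(intervals, key=lambda iv: iv.start_h)
    span = ordered[-1].end_h - ordered[0].start_h
    if not span > 0:
        raise DomainError("collection span must be > 0")
    total = sum(iv.volume_ml for iv in ordered)
    return total / span / body_weight


def plasma_volume_change(h1: float, h2: float) -> float:
    """van Beaumont percent plasma-volume change from hematocrits H1, H2 (%)."""
    for h in (h1, h2):
        if not 0 < h < 100:
            raise DomainError(f"hematocrit must be in (0, 100), got {h}")
    return (100.0 / (100.0 - h1)) * (100.0 * (h1 - h2) / h2)
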