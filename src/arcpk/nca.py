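"""Non-compartmental AUC cross-check and the extrapolated-area quality gate.

NCA here is deliberately minimal: it exists to verify that the terminal
extrapolation of each profile is small (the study requires the extrapolated
fraction of AUC_0->inf to stay below 10 %), not to replace the compartmental
AUC used elsewhere.  Conventions:

* AUC to the last quantifiable sample by the linear-up/log-down trapezoid,
  with the 0 -> t1 segment closed using C(0) back-extrapolated log-linearly
  from the first two samples (standard IV-bolus NCA practice);
* terminal slope lambda_z from a log-linear regression over the last 3-6
  quantifiable points (never including the observed maximum), choosing the
  window with the best adjusted R^2;
* AUC_0->inf = AUC_last + C_last/lambda_z, in ng·h/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, LambdaZError
from .study_data import PlasmaProfile

__all__ = ["NCAResult", "nca_auc", "check_extrapolation"]


@dataclass(frozen=True)
class NCAResult:
    auc_last: float      # ng·h/mL
    auc_inf_nca: float   # ng·h/mL
    lambda_z: float      # h^-1
    extrap_pct: float    # % of auc_inf_nca from the extrapolated tail
    n_lambda_points: int


def _segment_auc(t1: float, t2: float, c1: float, c2: float) -> float:
    """Linear-up/log-down trapezoid for one segment (µg·h/mL)."""
    dt = t2 - t1
    if c2 < c1 and c1 > 0 and c2 > 0:
        return (c1 - c2) * dt / math.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def _lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float, int]:
    """Best adjusted-R^2 log-linear terminal slope over the last 3-6 points."""
    imax = int(np.argmax(c))
    best = None
    for m in range(3, 7):
        if t.size - m <= imax:  # window would include the observed maximum
            break
        tt, cc = t[-m:], np.log(c[-m:])
        res = stats.linregress(tt, cc)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best[0]:
            best = (adj, -res.slope, m)
    if best is None:
        raise LambdaZError("terminal phase is not decaying; lambda_z undefined")
    return best[1], best[2]


def nca_auc(profile: PlasmaProfile) -> NCAResult:
    """Non-compartmental AUC summary for one plasma profile."""
    recs = [r for r in profile.records if not r.blq and r.time_h > 0]
    if len(recs) < 3:
        raise InsufficientDataError("NCA needs >= 3 quantifiable post-dose records")
    t = np.array([r.time_h for r in recs])
    c = np.array([r.concentration for r in recs])
    if np.any(c <= 0):
        raise InsufficientDataError("NCA needs positive concentrations")

    lam, n_lam = _lambda_z(t, c)

    # back-extrapolated C(0) from the first two samples (log-linear)
    if c[0] > c[1]:
        slope = math.log(c[1] / c[0]) / (t[1] - t[0])
        c0 = c[0] * math.exp(-slope * t[0])
    else:
        c0 = c[0]
    auc = _segment_auc(0.0, t[0], c0, c[0])
    for i in range(t.size - 1):
        auc += _segment_auc(t[i], t[i + 1], c[i], c[i + 1])

    auc_last = auc * 1000.0  # µg·h/mL -> ng·h/mL
    tail = c[-1] / lam * 1000.0
    auc_inf = auc_last + tail
    extrap = 100.0 * tail / auc_inf
    return NCAResult(auc_last=auc_last, auc_inf_nca=auc_inf, lambda_z=lam,
                     extrap_pct=extrap, n_lambda_points=n_lam)


def check_extrapolation(nca: NCAResult, limit: float = 10.0) -> bool:
    """True iff the extrapolated AUC fraction is strictly below *limit* (%)."""
    return nca.extrap_pct < limit
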