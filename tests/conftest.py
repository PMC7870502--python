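import numpy as np
import pytest

from arcpk.pk import PKParameters, predict_concentration
from arcpk.study_data import (
    ConcentrationRecord,
    DoseEvent,
    PlasmaProfile,
    SAMPLING_TIMES_H,
)
from arcpk.synthetic import SimulationConfig, simulate_cohort

SCHEDULE = np.asarray(SAMPLING_TIMES_H)


def make_profile(params: PKParameters, dose: float, analyte: str = "iohexol",
                 occasion: str = "M1", lloq: float = 0.25, noise_sd: float = 0.0,
                 seed: int = 0, animal_id: str = "A01", group: str = "control",
                 body_weight: float = 14.0, times=None) -> PlasmaProfile:
    """Synthetic plasma profile from the closed-form model (+ optional
    proportional noise), censored at the LLOQ."""
    t = SCHEDULE if times is None else np.asarray(times, dtype=float)
    y = predict_concentration(params, dose, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd * rng.standard_normal(t.size))
    records = []
    for ti, yi in zip(t, y):
        if yi < lloq:
            records.append(ConcentrationRecord(float(ti), None, lloq, blq=True))
        else:
            records.append(ConcentrationRecord(float(ti), float(yi), lloq))
    return PlasmaProfile(
        animal_id=animal_id, group=group, occasion=occasion,
        dose=DoseEvent(analyte=analyte, dose_per_bw=dose, occasion=occasion),
        body_weight=body_weight, records=tuple(records),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort, shared across tests (read-only)."""
    return simulate_cohort(SimulationConfig(), seed=7)


@pytest.fixture
def small_noiseless_config():
    """Tiny null cohort: no residual error, no fluid effect, no test-retest
    variation — every fitted M2/M1 ratio must be 1."""
    cfg = SimulationConfig(n_control=3, n_treatment=2)
    for a in cfg.analytes.values():
        a.residual_sigma = 0.0
        a.test_retest_r_pct = 0.0
        a.fluid_cl_mean = 1.0
        a.fluid_vss_mult = 1.0
    cfg.fluid_cl_sd = 0.0
    cfg.urine_conc_cv = 0.0
    return cfg
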