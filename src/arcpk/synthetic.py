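"""Seeded generator of complete synthetic study cohorts.

No raw data accompany the study this package analyses, so every stage is
exercised against simulated cohorts that carry the same statistical
structure the analysis assumes:

* two arms (control / fluid-treated) measured on two occasions (M1, M2);
* per-animal disposition parameters drawn lognormally around the cohort
  geometric means, with a shared latent "renal function" factor inducing
  between-marker clearance correlation;
* occasion-2 parameters equal to occasion-1 times a mean-one lognormal
  test-retest deviate, times a lognormal fluid-effect multiplier in the
  treated arm (applied to clearance, and more weakly to V_ss);
* plasma concentrations from the closed-form compartmental model with
  proportional (or additive) residual error, censored at the assay LLOQ;
* PAH urinary excretion partitioned over a fixed 2-h collection grid in
  proportion to the cumulative plasma AUC, with a configurable fraction of
  the dose excreted unchanged;
* urine volumes from group/occasion urine-output rates; hematocrit series
  consistent with the configured group-wise plasma-volume-change profiles
  (inverted through the van Beaumont formula); hematology panels and body
  temperatures inside their reference ranges.

Everything is driven by :class:`SimulationConfig`; identical config + seed
give identical datasets.
"""

from __future__ import annotations

import copy
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError
from .pk import PKParameters, predict_concentration
from .study_data import (
    ANALYTES,
    AnimalRecord,
    ConcentrationRecord,
    DoseEvent,
    Hematology,
    PlasmaProfile,
    SAMPLING_TIMES_H,
    StudyDataset,
    UrineInterval,
)

__all__ = ["AnalyteSimConfig", "SimulationConfig", "simulate_cohort", "inject_anomalies"]

_ANALYTE_ORDER = ("iohexol", "pah", "amikacin")


@dataclass
class AnalyteSimConfig:
    """Population/simulation knobs for one marker drug."""

    dose_mg_per_kg: float
    lloq_ug_per_ml: float
    cl_gm: float                 # geometric-mean clearance, mL/min/kg
    vss_gm: float                # geometric-mean V_ss, mL/kg
    fluid_cl_mean: float         # arithmetic mean of the CL fluid multiplier
    fluid_vss_mult: float        # deterministic V_ss fluid multiplier
    test_retest_r_pct: float     # target duplicate-CV reproducibility R (%)
    error_model: str = "proportional"
    residual_sigma: float = 0.07  # fraction (proportional) or µg/mL (additive)


@dataclass
class SimulationConfig:
    """Full description of one simulated cohort (all knobs exposed)."""

    n_control: int = 12
    n_treatment: int = 12
    body_weight_mean: float = 14.1     # kg at M1
    body_weight_sd: float = 1.6
    body_weight_gain: float = 2.0      # kg gained by M2
    between_animal_cv: float = 0.12    # lognormal BSV on CL and V_ss
    v1_vss_fraction: float = 0.6
    q_cl_ratio: float = 1.0
    fluid_cl_sd: float = 0.13          # between-animal SD of the CL multiplier
    renal_correlation: float = 0.8     # latent-factor corr. between marker CLs
    pah_fraction_excreted: float = 0.45
    urine_interval_h: float = 2.0
    urine_collection_end_h: float = 10.0
    urine_output_control: float = 1.2      # mL/kg/h, both occasions
    urine_output_treatment_m1: float = 1.45
    urine_output_treatment_m2_mult: float = 2.9
    urine_rate_cv: float = 0.10
    urine_volume_cv: float = 0.20
    urine_conc_cv: float = 0.05
    hct_baseline_mean: float = 30.0
    hct_baseline_sd: float = 2.0
    pvc_times_h: tuple[float, ...] = (12.0, 24.0, 36.0)
    pvc_mean_control: tuple[float, ...] = (-6.7, -4.55, -2.0)    # % per time
    pvc_mean_treatment: tuple[float, ...] = (3.0, 2.5, 1.0)
    pvc_sd: float = 3.0
    temp_mean_c: float = 39.2
    temp_sd_c: float = 0.3
    leukocytes_mean: float = 17_000.0
    leukocytes_sd: float = 2_500.0
    neutrophils_mean: float = 6_000.0
    neutrophils_sd: float = 1_500.0
    lymphocytes_mean: float = 9_000.0
    lymphocytes_sd: float = 2_000.0
    monocytes_mean: float = 700.0
    monocytes_sd: float = 150.0
    sampling_times_h: tuple[float, ...] = SAMPLING_TIMES_H
    analytes: dict[str, AnalyteSimConfig] = field(default_factory=lambda: {
        "iohexol": AnalyteSimConfig(
            dose_mg_per_kg=64.7, lloq_ug_per_ml=0.25, cl_gm=3.7, vss_gm=380.0,
            fluid_cl_mean=1.15, fluid_vss_mult=1.06, test_retest_r_pct=5.8),
        "pah": AnalyteSimConfig(
            dose_mg_per_kg=10.0, lloq_ug_per_ml=0.25, cl_gm=24.3, vss_gm=490.0,
            fluid_cl_mean=1.10, fluid_vss_mult=1.10, test_retest_r_pct=18.0),
        "amikacin": AnalyteSimConfig(
            dose_mg_per_kg=7.5, lloq_ug_per_ml=0.50, cl_gm=3.6, vss_gm=520.0,
            fluid_cl_mean=1.14, fluid_vss_mult=1.0, test_retest_r_pct=5.5),
    })

    def validate(self) -> None:
        if self.n_control < 0 or self.n_treatment < 0:
            raise ConfigError("cohort sizes must be >= 0")
        if not 0 < self.v1_vss_fraction <= 1:
            raise ConfigError("v1_vss_fraction must be in (0, 1]")
        if not -1 <= self.renal_correlation <= 1:
            raise ConfigError("renal_correlation must be in [-1, 1]")
        if not 0 < self.pah_fraction_excreted <= 1:
            raise ConfigError("pah_fraction_excreted must be in (0, 1]")
        for name, a in self.analytes.items():
            if name not in ANALYTES:
                raise ConfigError(f"unknown analyte {name!r}")
            for fieldname in ("dose_mg_per_kg", "lloq_ug_per_ml", "cl_gm", "vss_gm"):
                if not getattr(a, fieldname) > 0:
                    raise ConfigError(f"{name}.{fieldname} must be > 0")
            if a.error_model not in ("proportional", "additive"):
                raise ConfigError(f"{name}.error_model invalid")
        if len(self.pvc_times_h) != len(self.pvc_mean_control) or \
                len(self.pvc_times_h) != len(self.pvc_mean_treatment):
            raise ConfigError("pvc time/mean lengths must match")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("pvc_times_h", "pvc_mean_control", "pvc_mean_treatment",
                    "sampling_times_h"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        analytes = {k: AnalyteSimConfig(**v) for k, v in d.pop("analytes", {}).items()}
        for key in ("pvc_times_h", "pvc_mean_control", "pvc_mean_treatment",
                    "sampling_times_h"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d, analytes=analytes) if analytes else cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _lognormal_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if sd == 0:
        return math.log(mean), 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _auc_fraction(params: PKParameters, t: np.ndarray) -> np.ndarray:
    """Fraction of total plasma AUC accumulated by time t (closed form)."""
    alpha, beta = params.macro_constants()
    c0 = 1.0  # scale cancels
    if params.n_compartments == 1 or alpha == beta:
        return 1.0 - np.exp(-beta * t)
    k21 = 60.0 * params.q / params.v2
    a = c0 * (alpha - k21) / (alpha - beta)
    b = c0 * (k21 - beta) / (alpha - beta)
    total = a / alpha + b / beta
    remaining = (a / alpha) * np.exp(-alpha * t) + (b / beta) * np.exp(-beta * t)
    return 1.0 - remaining / total


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int = 0) -> StudyDataset:
    """Generate one complete study dataset; deterministic given *seed*."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    ds = StudyDataset()

    animals = [("control", f"C{i+1:02d}") for i in range(config.n_control)] + \
              [("treatment", f"T{i+1:02d}") for i in range(config.n_treatment)]
    sigma_bsv = math.sqrt(math.log(1.0 + config.between_animal_cv**2))
    times = np.asarray(config.sampling_times_h, dtype=float)
    urine_edges = np.arange(0.0, config.urine_collection_end_h + 1e-9,
                            config.urine_interval_h)

    for group, aid in animals:
        bw1 = max(float(rng.normal(config.body_weight_mean, config.body_weight_sd)), 5.0)
        bw2 = bw1 + config.body_weight_gain
        bw = {"M1": bw1, "M2": bw2}

        z_renal = rng.standard_normal()
        rho = config.renal_correlation

        rec = AnimalRecord(animal_id=aid, group=group)
        rec.body_weight = dict(bw)
        for occ in ("M1", "M2"):
            rec.body_temperature[occ] = float(rng.normal(config.temp_mean_c, config.temp_sd_c))
            rec.hematology[occ] = Hematology(
                leukocytes=max(float(rng.normal(config.leukocytes_mean, config.leukocytes_sd)), 0.0),
                neutrophils=max(float(rng.normal(config.neutrophils_mean, config.neutrophils_sd)), 0.0),
                lymphocytes=max(float(rng.normal(config.lymphocytes_mean, config.lymphocytes_sd)), 0.0),
                monocytes=max(float(rng.normal(config.monocytes_mean, config.monocytes_sd)), 0.0),
            )

        # hematocrit series via inverted van Beaumont at the configured %dP
        h1 = float(np.clip(rng.normal(config.hct_baseline_mean, config.hct_baseline_sd), 15.0, 60.0))
        rec.hematocrit.append((0.0, h1))
        pvc_means = (config.pvc_mean_control if group == "control"
                     else config.pvc_mean_treatment)
        for t_pvc, mean_pvc in zip(config.pvc_times_h, pvc_means):
            target = float(rng.normal(mean_pvc, config.pvc_sd))
            c = target * (100.0 - h1) / 1e4
            h2 = float(np.clip(h1 / (1.0 + c), 15.0, 60.0))
            rec.hematocrit.append((t_pvc, h2))
        ds.animals[aid] = rec

        occasion_params: dict[tuple[str, str], PKParameters] = {}
        for analyte in _ANALYTE_ORDER:
            a = config.analytes[analyte]
            z = rho * z_renal + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
            cl1 = a.cl_gm * math.exp(sigma_bsv * z)
            vss1 = a.vss_gm * math.exp(sigma_bsv * rng.standard_normal())

            # mean-one test-retest deviates; E[CV_i^2] = R^2 by construction
            s_tr = math.sqrt(2.0) * a.test_retest_r_pct / 100.0
            eps_cl = float(rng.normal(0.0, 1.0)) * s_tr
            s_trv = s_tr / 2.0
            eps_v = float(rng.normal(0.0, 1.0)) * s_trv
            cl2 = cl1 * math.exp(eps_cl - s_tr**2 / 2.0)
            vss2 = vss1 * math.exp(eps_v - s_trv**2 / 2.0)
            if group == "treatment":
                mu_f, s_f = _lognormal_mean_sd(a.fluid_cl_mean, config.fluid_cl_sd)
                cl2 *= math.exp(mu_f + s_f * float(rng.standard_normal()))
                vss2 *= a.fluid_vss_mult

            for occ, cl, vss in (("M1", cl1, vss1), ("M2", cl2, vss2)):
                v1 = config.v1_vss_fraction * vss
                v2 = vss - v1
                if v2 <= 0:
                    params = PKParameters(1, cl, v1)
                else:
                    params = PKParameters(2, cl, v1, config.q_cl_ratio * cl, v2)
                occasion_params[(analyte, occ)] = params

                f = predict_concentration(params, a.dose_mg_per_kg, times)
                noise = rng.standard_normal(times.size)
                if a.error_model == "proportional":
                    y = f * (1.0 + a.residual_sigma * noise)
                else:
                    y = f + a.residual_sigma * noise
                records = [ConcentrationRecord(0.0, None, a.lloq_ug_per_ml, blq=True)]
                for t_i, y_i in zip(times, y):
                    if y_i < a.lloq_ug_per_ml:
                        records.append(ConcentrationRecord(float(t_i), None,
                                                           a.lloq_ug_per_ml, blq=True))
                    else:
                        records.append(ConcentrationRecord(float(t_i), float(y_i),
                                                           a.lloq_ug_per_ml))
                ds.profiles.append(PlasmaProfile(
                    animal_id=aid, group=group, occasion=occ,
                    dose=DoseEvent(analyte=analyte, dose_per_bw=a.dose_mg_per_kg,
                                   occasion=occ),
                    body_weight=bw[occ], records=tuple(records),
                ))

        # PAH urinary excretion over the fixed collection grid
        a = config.analytes["pah"]
        for occ in ("M1", "M2"):
            params = occasion_params[("pah", occ)]
            dose_total_mg = a.dose_mg_per_kg * bw[occ]
            frac = _auc_fraction(params, urine_edges)
            amounts_mg = config.pah_fraction_excreted * dose_total_mg * np.diff(frac)
            if group == "control":
                rate = config.urine_output_control
            else:
                rate = config.urine_output_treatment_m1
                if occ == "M2":
                    rate *= config.urine_output_treatment_m2_mult
            rate *= math.exp(float(rng.normal(0.0, config.urine_rate_cv)))
            intervals = []
            for i in range(urine_edges.size - 1):
                dt = urine_edges[i + 1] - urine_edges[i]
                vol = rate * bw[occ] * dt * math.exp(float(rng.normal(0.0, config.urine_volume_cv)))
                conc = amounts_mg[i] * 1000.0 / vol
                conc *= math.exp(float(rng.normal(0.0, config.urine_conc_cv)))
                intervals.append(UrineInterval(
                    start_h=float(urine_edges[i]), end_h=float(urine_edges[i + 1]),
                    volume_ml=vol, conc_ug_per_ml=conc,
                ))
            ds.urine[(aid, occ)] = intervals

    ds.validate()
    return ds


_ANOMALY_KEYS = {"leukocytosis", "urine_leak"}


def inject_anomalies(dataset: StudyDataset,
                     anomalies: dict | None) -> StudyDataset:
    """Return a copy of *dataset* with controlled anomalies injected.

    ``anomalies`` keys:

    * ``"leukocytosis"``: ``{"animal_id": <id, default first control animal>}``
      — sets an out-of-range M2 leukocyte/neutrophil count and a +1.2 °C
      temperature rise, so the infection screen must exclude the animal;
    * ``"urine_leak"``: list of ``{"animal_id": ..., "occasion": ...,
      "interval": <index, default 0>}`` — flags collections as leaked.

    An empty/None mapping returns an identical copy.  Unknown keys raise
    :class:`ConfigError`.
    """
    out = copy.deepcopy(dataset)
    if not anomalies:
        return out
    unknown = set(anomalies) - _ANOMALY_KEYS
    if unknown:
        raise ConfigError(f"unknown anomaly key(s): {sorted(unknown)}")

    if "leukocytosis" in anomalies:
        entry = anomalies["leukocytosis"] or {}
        aid = entry.get("animal_id")
        if aid is None:
            controls = out.animal_ids("control")
            if not controls:
                raise ConfigError("no control animal to make leukocytotic")
            aid = controls[0]
        if aid not in out.animals:
            raise ConfigError(f"unknown animal {aid!r}")
        rec = out.animals[aid]
        rec.hematology["M2"] = Hematology(
            leukocytes=entry.get("leukocytes", 32_690.0),
            neutrophils=entry.get("neutrophils", 23_341.0),
            lymphocytes=rec.hematology["M2"].lymphocytes,
            monocytes=rec.hematology["M2"].monocytes,
        )
        rec.body_temperature["M2"] = rec.body_temperature["M1"] + entry.get("delta_t", 1.2)

    for entry in anomalies.get("urine_leak", []):
        key = (entry["animal_id"], entry["occasion"])
        if key not in out.urine:
            raise ConfigError(f"no urine collection for {key}")
        idx = entry.get("interval", 0)
        intervals = out.urine[key]
        if not 0 <= idx < len(intervals):
            raise ConfigError(f"interval index {idx} out of range for {key}")
        intervals[idx] = replace(intervals[idx], leaked=True)

    return out
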