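"""End-to-end analysis: screen -> fit -> derive -> compare -> report.

``run_analysis`` reproduces the study's full quantitative workflow on a
validated dataset:

1. inflammation screening (hematology + temperature) excludes animals from
   every calculation; urine leakage excludes animals from renal-clearance
   and urine-output calculations only;
2. every plasma profile is fitted with the per-analyte compartmental policy
   (``select_model``), cross-checked by the NCA extrapolation gate;
3. derived quantities: V_ss, AUC_0->inf, PAH Ae and CL_R, urine output,
   van Beaumont plasma-volume changes;
4. the hypothesis-test battery: one-sided Wilcoxon signed-rank tests on
   within-group clearance changes, one-sided Mann-Whitney U on between-group
   clearance changes, two-sided tests for V_ss / AUC / urine output,
   per-timepoint Mann-Whitney tests on plasma-volume change, hematocrit
   linear trends, and the iohexol-amikacin correlation/agreement analyses;
5. tabular report mirroring the study's summary tables, with an exclusion
   log carrying machine-readable reasons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort
from .exceptions import ArcPKError, DegenerateInputError, DomainError
from .nca import check_extrapolation, nca_auc
from .pk import select_model
from .renal import cumulative_excretion, plasma_volume_change, renal_clearance, urine_output_rate
from .study_data import OCCASIONS, StudyDataset

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis"]

_ANALYTE_ORDER = ("iohexol", "pah", "amikacin")


@dataclass
class AnalysisConfig:
    cv_threshold: float = 50.0          # fallback rule: max acceptable CV%
    extrapolation_limit_pct: float = 10.0
    alpha: float = 0.05
    delta_t_threshold: float = 1.0      # degC rise for the infection screen
    leukocytes_upper: float = 22_800.0
    neutrophils_upper: float = 9_600.0
    clearance_alternative: str = "greater"  # expected direction at M2
    fit_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisReport:
    """All output tables of one analysis run."""

    fits: pd.DataFrame            # per animal x analyte x occasion
    summary_table: pd.DataFrame   # medians (p25-p75) per parameter cell
    reproducibility: pd.DataFrame  # control-arm duplicate-CV table
    agreement: pd.DataFrame       # Bland-Altman comparisons
    correlations: pd.DataFrame    # Pearson tests
    renal: pd.DataFrame           # Ae / CL_R per animal x occasion
    urine_output: pd.DataFrame    # mL/kg/h per animal x occasion
    pvc: pd.DataFrame             # plasma-volume change per animal x time
    tests: pd.DataFrame           # hypothesis-test battery
    exclusions: pd.DataFrame      # machine-readable exclusion log
    errors: pd.DataFrame          # per-profile failures (partial report)
    n_generated: dict[str, int] = field(default_factory=dict)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def ok(self) -> bool:
        return self.errors.empty

    def write(self, directory: str | Path) -> Path:
        """Write all tables as CSVs plus a JSON manifest; returns the dir."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tables = {
            "fits": self.fits, "summary_table": self.summary_table,
            "reproducibility": self.reproducibility, "agreement": self.agreement,
            "correlations": self.correlations, "renal": self.renal,
            "urine_output": self.urine_output, "pvc": self.pvc,
            "tests": self.tests, "exclusions": self.exclusions,
            "errors": self.errors,
        }
        for name, df in tables.items():
            df.to_csv(directory / f"{name}.csv", index=False)
        cfg = self.config.to_dict()
        manifest = {
            "tables": sorted(tables),
            "n_generated": self.n_generated,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "ok": self.ok,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


def _fit_all(dataset: StudyDataset, included: list[str],
             config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, errors = [], []
    profiles = sorted(
        (p for p in dataset.profiles if p.animal_id in included),
        key=lambda p: (p.animal_id, p.analyte, p.occasion),
    )
    for p in profiles:
        row = {
            "animal_id": p.animal_id, "group": p.group, "occasion": p.occasion,
            "analyte": p.analyte, "dose_mg_per_kg": p.dose.dose_per_bw,
            "body_weight_kg": p.body_weight,
        }
        try:
            fit = select_model(p, cv_threshold=config.cv_threshold,
                               seed=config.fit_seed)
        except ArcPKError as exc:
            errors.append({**row, "stage": "fit", "error": str(exc)})
            continue
        cv = fit.cv_pct or {}
        row.update({
            "n_compartments": fit.n_compartments, "error_model": fit.error_model,
            "cl_tot": fit.params.cl_tot, "v1": fit.params.v1,
            "q": fit.params.q, "v2": fit.params.v2,
            "vss": fit.vss, "auc_inf": fit.auc_inf, "sigma": fit.sigma,
            "converged": fit.converged,
            "cv_cl_pct": cv.get("cl_tot", np.nan),
            "cv_v1_pct": cv.get("v1", np.nan),
        })
        try:
            nca = nca_auc(p)
            row.update({
                "auc_inf_nca": nca.auc_inf_nca, "lambda_z": nca.lambda_z,
                "extrap_pct": nca.extrap_pct,
                "extrap_ok": check_extrapolation(nca, config.extrapolation_limit_pct),
            })
        except ArcPKError as exc:
            row.update({"auc_inf_nca": np.nan, "lambda_z": np.nan,
                        "extrap_pct": np.nan, "extrap_ok": False})
            errors.append({**row, "stage": "nca", "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(errors)


def _paired(fits: pd.DataFrame, analyte: str, column: str,
            group: str | None = None) -> pd.DataFrame:
    """Wide M1/M2 table of one fitted quantity, animals with both occasions."""
    sub = fits[fits["analyte"] == analyte]
    if group is not None:
        sub = sub[sub["group"] == group]
    wide = sub.pivot_table(index=["animal_id", "group"], columns="occasion",
                           values=column, aggfunc="first").reset_index()
    if "M1" not in wide.columns or "M2" not in wide.columns:
        return pd.DataFrame(columns=["animal_id", "group", "M1", "M2"])
    return wide.dropna(subset=["M1", "M2"]).sort_values("animal_id")


def _safe_test(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (DegenerateInputError, DomainError):
        return None


def run_analysis(dataset: StudyDataset,
                 config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the complete analysis pipeline on a validated dataset."""
    config = config or AnalysisConfig()
    dataset.validate()
    ref = cohort.ReferenceRanges(leukocytes_upper=config.leukocytes_upper,
                                 neutrophils_upper=config.neutrophils_upper)

    n_generated = {g: len(dataset.animal_ids(g)) for g in ("control", "treatment")}

    # -- screening ----------------------------------------------------------
    exclusion_rows = []
    included: list[str] = []
    for aid in dataset.animal_ids():
        rec = dataset.animals[aid]
        try:
            decision = cohort.infection_screen(rec, ref, config.delta_t_threshold)
        except ArcPKError as exc:
            decision = cohort.ScreenDecision(include=False, reason=f"missing_data:{exc}")
        if decision.include:
            included.append(aid)
        else:
            exclusion_rows.append({"animal_id": aid, "group": rec.group,
                                   "scope": "all", "reason": decision.reason})

    # urine completeness (renal-clearance scope only)
    urine_eligible: list[str] = []
    for aid in included:
        by_occ = {occ: dataset.urine.get((aid, occ), []) for occ in OCCASIONS}
        if not any(by_occ.values()):
            continue  # no urine collected for this animal at all
        if cohort.urine_completeness_filter(by_occ):
            urine_eligible.append(aid)
        else:
            leaks = [occ for occ in OCCASIONS
                     if not by_occ[occ] or any(iv.leaked for iv in by_occ[occ])]
            exclusion_rows.append({
                "animal_id": aid, "group": dataset.animals[aid].group,
                "scope": "renal", "reason": "urine_leak:" + "+".join(leaks),
            })

    # -- fitting ------------------------------------------------------------
    fits, errors = _fit_all(dataset, included, config)

    # -- renal / urine output ----------------------------------------------
    renal_rows, urine_rows = [], []
    for aid in included:
        group = dataset.animals[aid].group
        for occ in OCCASIONS:
            intervals = dataset.urine.get((aid, occ))
            if not intervals:
                continue
            bw = dataset.animals[aid].body_weight.get(occ)
            summary = cumulative_excretion(intervals, bw)
            auc_rows = fits[(fits["animal_id"] == aid) & (fits["analyte"] == "pah")
                            & (fits["occasion"] == occ)]
            cl_r = np.nan
            if not auc_rows.empty and np.isfinite(auc_rows.iloc[0]["auc_inf"]):
                cl_r = renal_clearance(summary.ae, float(auc_rows.iloc[0]["auc_inf"]))
            renal_rows.append({
                "animal_id": aid, "group": group, "occasion": occ,
                "ae_mg_per_kg": summary.ae, "cl_r_ml_min_kg": cl_r,
                "complete": summary.complete, "eligible": aid in urine_eligible,
            })
            if aid in urine_eligible:
                urine_rows.append({
                    "animal_id": aid, "group": group, "occasion": occ,
                    "output_ml_kg_h": urine_output_rate(intervals, bw),
                })
    renal = pd.DataFrame(renal_rows)
    urine_output = pd.DataFrame(urine_rows)

    # -- plasma-volume change ----------------------------------------------
    pvc_rows = []
    for aid in included:
        rec = dataset.animals[aid]
        series = sorted(rec.hematocrit)
        base = [v for t, v in series if t == 0.0]
        if not base:
            continue
        h1 = base[0]
        for t, h2 in series:
            if t == 0.0:
                continue
            pvc_rows.append({"animal_id": aid, "group": rec.group, "time_h": t,
                             "pct_change": plasma_volume_change(h1, h2)})
    pvc = pd.DataFrame(pvc_rows)

    # -- summary tables ------------------------------------------------------
    summary_rows = []
    for analyte in _ANALYTE_ORDER:
        for param in ("cl_tot", "vss", "auc_inf"):
            sub = fits[fits["analyte"] == analyte]
            for group in ("control", "treatment"):
                for occ in OCCASIONS:
                    vals = sub[(sub["group"] == group) & (sub["occasion"] == occ)][param].dropna()
                    if vals.empty:
                        continue
                    s = cohort.summarize_group(vals, parameter=f"{analyte}_{param}",
                                               group=group, occasion=occ)
                    summary_rows.append(asdict(s))
    if not renal.empty:
        elig = renal[renal["eligible"]]
        for group in ("control", "treatment"):
            for occ in OCCASIONS:
                vals = elig[(elig["group"] == group) & (elig["occasion"] == occ)]["cl_r_ml_min_kg"].dropna()
                if vals.empty:
                    continue
                summary_rows.append(asdict(cohort.summarize_group(
                    vals, parameter="pah_cl_r", group=group, occasion=occ)))
    if not urine_output.empty:
        for group in ("control", "treatment"):
            for occ in OCCASIONS:
                vals = urine_output[(urine_output["group"] == group)
                                    & (urine_output["occasion"] == occ)]["output_ml_kg_h"]
                if vals.empty:
                    continue
                summary_rows.append(asdict(cohort.summarize_group(
                    vals, parameter="urine_output", group=group, occasion=occ)))
    summary_table = pd.DataFrame(summary_rows)

    # -- reproducibility (control arm) ---------------------------------------
    repro_rows = []
    for analyte in _ANALYTE_ORDER:
        wide = _paired(fits, analyte, "cl_tot", group="control")
        if len(wide) == 0:
            continue
        summary = agr.summarize_duplicates(zip(wide["M1"], wide["M2"]))
        repro_rows.append({
            "analyte": analyte, "n": summary.n,
            "mean_cv_pct": summary.mean_cv,
            "cv_min_pct": float(np.min(summary.cvs)),
            "cv_max_pct": float(np.max(summary.cvs)),
            "r_pct": summary.r_pct,
        })
    reproducibility = pd.DataFrame(repro_rows)

    # -- agreement / correlation ---------------------------------------------
    agreement_rows, corr_rows = [], []
    for analyte in _ANALYTE_ORDER:
        wide = _paired(fits, analyte, "cl_tot", group="control")
        if len(wide) >= 2:
            res = agr.bland_altman(zip(wide["M1"], wide["M2"]), mode="percent")
            agreement_rows.append({
                "comparison": f"{analyte}_cl_M2_vs_M1_control", "n": res.n,
                "bias_pct": res.bias, "loa_lower_pct": res.loa_lower,
                "loa_upper_pct": res.loa_upper,
            })
    # iohexol vs amikacin: difference convention (CL_ioh - CL_ami)/mean
    for occ, label, groups in (("M1", "baseline", ("control", "treatment")),
                               ("M2", "fluid", ("treatment",))):
        ioh = fits[(fits["analyte"] == "iohexol") & (fits["occasion"] == occ)
                   & fits["group"].isin(groups)][["animal_id", "cl_tot"]]
        ami = fits[(fits["analyte"] == "amikacin") & (fits["occasion"] == occ)
                   & fits["group"].isin(groups)][["animal_id", "cl_tot"]]
        merged = ioh.merge(ami, on="animal_id", suffixes=("_ioh", "_ami")).dropna()
        if len(merged) >= 3:
            r, p = agr.pearson_r(merged["cl_tot_ioh"], merged["cl_tot_ami"])
            corr_rows.append({"comparison": f"iohexol_vs_amikacin_cl_{label}",
                              "n": len(merged), "r": r, "p_value": p})
        if len(merged) >= 2:
            res = agr.bland_altman(
                zip(merged["cl_tot_ami"], merged["cl_tot_ioh"]), mode="percent")
            agreement_rows.append({
                "comparison": f"iohexol_vs_amikacin_cl_{label}", "n": res.n,
                "bias_pct": res.bias, "loa_lower_pct": res.loa_lower,
                "loa_upper_pct": res.loa_upper,
            })
    agreement = pd.DataFrame(agreement_rows)
    correlations = pd.DataFrame(corr_rows)

    # -- hypothesis tests -----------------------------------------------------
    test_rows = []

    def add_test(parameter, comparison, result, note=""):
        if result is None:
            test_rows.append({"parameter": parameter, "comparison": comparison,
                              "alternative": "", "method": "", "statistic": np.nan,
                              "p_value": np.nan, "n": 0, "m": None,
                              "note": note or "degenerate input"})
            return
        test_rows.append({"parameter": parameter, "comparison": comparison,
                          "alternative": result.alternative, "method": result.method,
                          "statistic": result.statistic, "p_value": result.p_value,
                          "n": result.n, "m": result.m, "note": note})

    def battery(parameter, frame_by_group, alternative_within, alternative_between):
        changes = {}
        for group in ("control", "treatment"):
            wide = frame_by_group.get(group)
            if wide is None or len(wide) == 0:
                continue
            d = (wide["M2"] - wide["M1"]).to_numpy()
            changes[group] = d
            add_test(parameter, f"within_{group}_M2_vs_M1",
                     _safe_test(cohort.wilcoxon_signed_rank, d, alternative_within))
        if "control" in changes and "treatment" in changes:
            add_test(parameter, "between_change_treatment_vs_control",
                     _safe_test(cohort.mann_whitney_u, changes["treatment"],
                                changes["control"], alternative_between))

    for analyte in _ANALYTE_ORDER:
        by_group = {g: _paired(fits, analyte, "cl_tot", group=g)
                    for g in ("control", "treatment")}
        battery(f"{analyte}_cl_tot", by_group,
                config.clearance_alternative, config.clearance_alternative)
        for param in ("vss", "auc_inf"):
            by_group = {g: _paired(fits, analyte, param, group=g)
                        for g in ("control", "treatment")}
            battery(f"{analyte}_{param}", by_group, "two-sided", "two-sided")

    # PAH renal clearance (eligible animals only), two-sided small-n tests
    if not renal.empty:
        elig = renal[renal["eligible"]]
        by_group = {}
        for g in ("control", "treatment"):
            wide = elig[elig["group"] == g].pivot_table(
                index="animal_id", columns="occasion",
                values="cl_r_ml_min_kg", aggfunc="first").reset_index()
            if "M1" in wide.columns and "M2" in wide.columns:
                by_group[g] = wide.dropna(subset=["M1", "M2"]).assign(group=g)
        battery("pah_cl_r", by_group, "two-sided", "two-sided")

    if not urine_output.empty:
        by_group = {}
        for g in ("control", "treatment"):
            wide = urine_output[urine_output["group"] == g].pivot_table(
                index="animal_id", columns="occasion",
                values="output_ml_kg_h", aggfunc="first").reset_index()
            if "M1" in wide.columns and "M2" in wide.columns:
                by_group[g] = wide.dropna(subset=["M1", "M2"]).assign(group=g)
        battery("urine_output", by_group, "two-sided", "two-sided")

    # plasma-volume change: per-timepoint between-group Mann-Whitney
    if not pvc.empty:
        for t in sorted(pvc["time_h"].unique()):
            ctrl = pvc[(pvc["group"] == "control") & (pvc["time_h"] == t)]["pct_change"]
            trt = pvc[(pvc["group"] == "treatment") & (pvc["time_h"] == t)]["pct_change"]
            if len(ctrl) and len(trt):
                add_test("plasma_volume_change", f"between_groups_at_{t:g}h",
                         _safe_test(cohort.mann_whitney_u, trt, ctrl, "two-sided"))

    # hematocrit linear trend per group
    for g in ("control", "treatment"):
        pts = [(t, v) for aid in included if dataset.animals[aid].group == g
               for t, v in dataset.animals[aid].hematocrit]
        if len(pts) >= 3:
            try:
                slope, p = cohort.linear_trend_test([t for t, _ in pts],
                                                    [v for _, v in pts])
                test_rows.append({"parameter": "hematocrit", "comparison": f"trend_{g}",
                                  "alternative": "two-sided", "method": "ols",
                                  "statistic": slope, "p_value": p,
                                  "n": len(pts), "m": None, "note": "slope %/h"})
            except DomainError:
                pass

    tests = pd.DataFrame(test_rows)
    exclusions = pd.DataFrame(exclusion_rows,
                              columns=["animal_id", "group", "scope", "reason"])

    return AnalysisReport(
        fits=fits, summary_table=summary_table, reproducibility=reproducibility,
        agreement=agreement, correlations=correlations, renal=renal,
        urine_output=urine_output, pvc=pvc, tests=tests, exclusions=exclusions,
        errors=errors if not errors.empty else pd.DataFrame(columns=["animal_id", "stage", "error"]),
        n_generated=n_generated, config=config,
    )
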