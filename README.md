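# arcpk

Quantitative analysis pipeline for a two-occasion piglet study of
**fluid-therapy-induced augmented renal clearance (ARC)** — the
supraphysiological increase in renal solute elimination seen under
intravenous fluid loading. Two arms of juvenile piglets (control /
fluid-treated with 0.9 % saline at 6 mL/kg/h) each receive consecutive IV
boluses of three renal markers on two occasions (baseline M1 and
re-measurement M2):

* **iohexol** (64.7 mg/kg) — total body clearance measures the glomerular
  filtration rate (GFR);
* **para-aminohippuric acid, PAH** (10 mg/kg) — urinary renal clearance
  evaluates effective renal plasma flow (ERPF);
* **amikacin** (7.5 mg/kg) — a renally excreted antibiotic whose exposure
  (AUC) responds to ARC.

The package is written for PK/renal-physiology analysts: it provides the
compartmental fitting engine, the renal and plasma-volume calculators, the
agreement/reproducibility statistics and the small-sample hypothesis-test
battery, plus a seeded synthetic-cohort generator so the complete pipeline
runs and is testable without any study download.

## The model

Each individual plasma profile after an IV bolus of dose *D* (mg/kg) is a
mono-/biexponential disposition curve

```
C(t) = A·e^(−αt) + B·e^(−βt),       C(0) = D·1000 / V1
```

parameterised by clearance CL (mL/min/kg), central volume V1 (mL/kg) and —
for the two-compartment model — intercompartmental clearance Q and
peripheral volume V2. Profiles are fitted per animal by maximum likelihood
under a proportional, `y = f·(1+ε)`, or additive, `y = f + ε`, residual
model; below-LLOQ samples are excluded. The reported secondary parameters
are `V_ss = V1 + V2` and `AUC_0→∞ = D·10⁶/(60·CL)` (ng·h/mL), so dose
conservation `AUC·CL·60/10⁶ = D` holds exactly for every fit. A fit whose
parameter CVs exceed a threshold (default 50 %) falls back to the
one-compartment model (iohexol: proportional error; PAH: additive;
amikacin is always two-compartment).

Derived physiology:

* renal clearance `CL_R = Ae / AUC_0→∞` from cumulative urinary recovery Ae;
* urine output (mL/kg/h) from leak-free timed collections;
* plasma-volume change from hematocrit via van Beaumont:
  `%ΔP = [100/(100−H1)]·[100·(H1−H2)/H2]`;
* test–retest reproducibility `R = √(Σ CVᵢ²/n)` from duplicate clearance
  CVs, and Bland–Altman bias ± 1.96·SD limits of agreement with
  percent differences relative to the pair mean;
* exact (enumerated) Wilcoxon signed-rank and Mann–Whitney U tests at the
  study's small sample sizes.

## Worked example

```python
from arcpk import SimulationConfig, simulate_cohort, run_analysis

dataset = simulate_cohort(SimulationConfig(), seed=42)   # 12 + 12 piglets
report = run_analysis(dataset)

print(report.reproducibility.to_string(index=False))
tests = report.tests
cl = tests[tests.parameter.str.endswith("cl_tot")
           & (tests.comparison == "within_treatment_M2_vs_M1")]
print(cl[["parameter", "method", "p_value"]].to_string(index=False))
```

prints

```
 analyte  n  mean_cv_pct  cv_min_pct  cv_max_pct     r_pct
 iohexol 12     4.508629    0.027860   12.596434  5.864948
     pah 12    13.029301    1.484129   36.974589 16.566336
amikacin 12     4.310268    0.323912   17.495216  6.162940

      parameter method  p_value
 iohexol_cl_tot  exact 0.008057
     pah_cl_tot  exact 0.765137
amikacin_cl_tot  exact 0.000488
```

The reproducibility table mirrors the study's control-arm duplicate-CV
summary (R ≈ 5.9 % iohexol, 6.2 % amikacin, 16.6 % PAH for this seed); the
one-sided within-treatment signed-rank tests detect the fluid-induced
clearance increase for the two filtration markers (p < 0.01) while the
noisier PAH clearance does not reach significance in this cohort.

A command-line interface wraps the same pipeline:

```bash
arcpk simulate --seed 7 --out data/
arcpk analyze --in data/ --out report/
```

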