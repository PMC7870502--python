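# Methods

## Disposition model and likelihood

Each plasma profile (one animal × marker × occasion) is modelled as an
instantaneous IV bolus into a one- or two-compartment mammillary system with
first-order elimination. The package parameterises the model directly in
(CL, V1, Q, V2) — clearances in mL/min/kg, volumes in mL/kg — rather than
macro-constants, because the study's summary tables report CL and V_ss.
Micro rate constants are k10 = 60·CL/V1, k12 = 60·Q/V1, k21 = 60·Q/V2
(h⁻¹), and the hybrid constants α > β follow from the usual quadratic; the
discriminant (k10+k12−k21)² + 4·k12·k21 is strictly positive, so α > β
always holds for positive parameters.

Fitting is per-individual maximum likelihood with a proportional
(`y = f·(1+ε)`, ε ~ N(0, σ²)) or additive (`y = f + ε`) residual model.
σ is profiled out analytically; the concentrated −2 log L is minimised over
log-parameters. The residual variance inside the concentrated objective is
floored at 1e−20 (relative scale) so noise-free data yield a well-defined
minimum instead of a divergence; the induced bias is O(1e−10) and
irrelevant at any reported precision.

**Initialisation** is curve stripping (method of residuals): a log-linear
fit of the last 3–4 quantifiable points gives (β, B), the positive early
residuals give (α, A), and the macro constants are mapped to (CL, V1, Q,
V2). If stripping fails (non-biexponential shape), the fallback start uses
a trapezoid-AUC clearance and V1 = D·1000/C(first).
**Optimisation** is BFGS (gtol 1e−4 — the resolution attainable with
finite-difference gradients) with a Nelder–Mead polish on stalls and up to
five ±50 % jittered restarts; a fit is flagged unconverged when no start
converges.

**Precision** is the Gauss–Newton (expected-information) covariance
s²(JᵀWJ)⁻¹ on the log scale, with W = 1/f² for proportional error. By the
delta method the log-scale standard error is directly the fractional SE,
so CV% = 100·se(log p). A singular information matrix is reported as
"precision unavailable" and treated as unacceptable by model selection.

**Model selection** follows the study's per-analyte policy: the
two-compartment fit is kept when it converges with all structural CVs at or
below the threshold (default 50 % — the study reports only "unacceptable
precision", so the threshold is exposed as configuration); otherwise the
one-compartment fallback is fitted (iohexol: proportional error, PAH:
additive, amikacin: no fallback — its structural model is fixed at two
compartments).

**Pre-dose samples** (t = 0) are retained by the data model but never
fitted: an IV-bolus model has no pre-dose prediction, and a t = 0 record
would carry a singular weight under proportional error. Below-LLOQ records
are excluded before fitting; a profile must keep ≥ 2n+1 quantifiable
post-dose points for an n-compartment fit.

## Non-compartmental cross-check

NCA exists only as the extrapolation-quality gate (extrapolated fraction of
AUC_0→∞ strictly below 10 %), not as the AUC used downstream. AUC to the
last quantifiable sample uses the linear-up/log-down trapezoid with the
0→t₁ segment closed by log-linear back-extrapolation of C(0) from the first
two samples; λz comes from the best adjusted-R² log-linear window over the
last 3–6 points, never including the observed maximum. Profiles failing the
gate are flagged in the report, not dropped.

## Renal and fluid physiology

* Ae = Σ volumeᵢ·concᵢ per collection, converted to mg and indexed to the
  occasion's body weight (the study's clearances are per kg, so the
  normalisation is made explicit here).
* CL_R = Ae·10⁶/AUC_0→∞/60 uses the compartmental AUC, which satisfies
  CL_R ≤ CL_TOT whenever Ae ≤ dose.
* Urine output = total volume / span / body weight, defined only for
  leak-free collections; a leaked interval raises rather than silently
  underestimating.
* Plasma-volume change uses the van Beaumont hematocrit transform with H1
  the pre-fluid (t = 0) value and each later time its own H2; per-animal
  %ΔP values are computed first and summarised by group medians.

## Statistics

Duplicate determinations use CVᵢ = 100·(|x₁−x₂|/√2)/mean; reproducibility
R = √(Σ CVᵢ²/n) is their quadratic mean and therefore never below the
arithmetic mean CV. Bland–Altman percent differences are taken relative to
the pair mean, with 95 % limits of agreement at bias ± 1.96·SD (n−1
denominator).

Wilcoxon signed-rank (zero differences dropped, Wilcoxon's convention) and
Mann–Whitney U enumerate their exact null distributions when feasible
(n ≤ 12 with untied |d|; n+m ≤ 14 without cross-group ties) and otherwise
use the tie-corrected normal approximation with a 0.5 continuity
correction. Exact two-sided p-values use the doubling convention
min(1, 2·min(P≤, P≥)). Quartiles are linearly interpolated between order
statistics (the study does not state its quartile rule). Hematocrit trends
use OLS with a two-sided t-test on the slope. The significance level is
0.05 throughout with no multiplicity adjustment, and the expected direction
of the clearance tests ("increase at M2") is configuration, defaulting to
one-sided-greater.

Screening: an animal is excluded from all calculations when a leukocyte or
neutrophil count above its upper reference bound (22,800 and 9,600 cells/µL)
coincides with a between-occasion temperature rise ≥ 1 °C; an animal whose
urine collection leaked at either occasion is excluded from renal-clearance
and urine-output calculations only. The repeated-measures general linear
model for plasma volume is out of scope; the per-timepoint Mann–Whitney
comparisons are implemented instead.

## Synthetic cohorts

The generator emulates the study conditions: 12 + 12 animals, body weight
14.1 ± 1.6 kg gaining 2 kg by M2, doses 64.7/10/7.5 mg/kg, the 13-sample
schedule (pre-dose plus 5 min–10 h), LLOQs 0.25/0.25/0.50 µg/mL.
Population geometric means (CL 3.7/24.3/3.6 mL/min/kg, V_ss 380/490/520
mL/kg for iohexol/PAH/amikacin) with 12 % lognormal between-animal spread
were calibrated to the study's median (IQR) summaries; V1/V_ss = 0.6 and
Q/CL = 1 fix the intra-profile shape. Between-marker clearance correlation
is induced by a shared latent "renal function" factor (loading 0.8, chosen
to echo the reported iohexol–amikacin correlation; a modelling choice, not
a measured parameter).

Occasion 2 multiplies occasion-1 parameters by a **mean-one** lognormal
test–retest deviate whose scale is parameterised directly by the target
duplicate-CV reproducibility (R = 5.8/18/5.5 % for iohexol/PAH/amikacin;
σ = √2·R/100, so E[CVᵢ²] = R² and the agreement statistics recover the
configured value). The treated arm additionally applies a lognormal
fluid-effect multiplier to clearance with arithmetic mean 1.15 (iohexol),
1.14 (amikacin), 1.10 (PAH) and between-animal SD 0.13 — spanning roughly
−9 % to +43 %, matching the reported spread — and deterministic V_ss
multipliers 1.06/1.10/1.0. The PAH values are the package's own
calibration: the study reports significant within-treatment PAH clearance
and V_ss increases without printing an effect mean.

Residual error is 7 % proportional (additive 0.15 µg/mL available for
PAH). PAH urinary excretion partitions a fixed fraction (0.45) of the dose
over a 2-h collection grid to 10 h in proportion to the cumulative plasma
AUC — giving CL_R/CL_TOT ratios in the study's range — with lognormal
volume (20 %) and concentration (5 %) measurement noise. Urine-output
rates are 1.2 (control) and 1.45 mL/kg/h (treatment baseline) with a ×2.9
multiplier under fluid loading. Hematocrit series start at 30 ± 2 % and
follow group-wise %ΔP profiles (control −6.7/−4.55/−2 %, treatment
+3/+2.5/+1 % at 12/24/36 h, SD 3) inverted through the van Beaumont
formula. Hematology panels and temperatures are drawn inside their
reference ranges; the anomaly injector creates the out-of-range
leukocytosis (+1.2 °C) and urine-leak cases the screening rules must catch.

What the generator does **not** emulate: physiological (nephron-level)
mechanisms, inflammation, circadian or batch/period effects, assay drift,
or correlated residuals within a profile. Passing tests therefore
demonstrate correctness of the estimators and pipeline logic under the
assumed statistical structure, not the biological claims themselves.

## Problem sizes and numerics

Effect-recovery checks run 200 seeded cohorts (≈ 19,000 individual fits)
— enough for ≈ 0.35 percentage-point Monte-Carlo error on the recovered
mean clearance increases, well inside the ±1-point acceptance band. The
worked-example AUC checks are noise-free single fits and deterministic.
Exact-test enumeration is vectorised (2ⁿ sign patterns; C(n+m, n)
arrangements via a selection-matrix product), keeping the 2000-replicate
type-I-error checks fast. Degenerate inputs (all-zero differences, zero
variance, flat terminal phases, leaked collections) raise typed errors
rather than returning silent defaults.

## Known limitations

* Per-individual ML only — no population (mixed-effects) modelling, no
  covariates, no absorption models.
* BLQ records are excluded, not censored-likelihood-integrated; with the
  study's sampling density the extrapolated AUC stays below the 10 % gate,
  where this simplification is benign.
* The exact Mann–Whitney path is limited to n+m ≤ 14; the study's
  between-group comparisons (11–12 per arm) therefore use the corrected
  normal approximation, as small-sample software commonly does.
* The fallback CV threshold (50 %) is a configurable convention; the study
  states no numeric criterion.
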