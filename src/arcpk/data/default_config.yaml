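n_control: 12
n_treatment: 12
body_weight_mean: 14.1
body_weight_sd: 1.6
body_weight_gain: 2.0
between_animal_cv: 0.12
v1_vss_fraction: 0.6
q_cl_ratio: 1.0
fluid_cl_sd: 0.13
renal_correlation: 0.8
pah_fraction_excreted: 0.45
urine_interval_h: 2.0
urine_collection_end_h: 10.0
urine_output_control: 1.2
urine_output_treatment_m1: 1.45
urine_output_treatment_m2_mult: 2.9
urine_rate_cv: 0.1
urine_volume_cv: 0.2
urine_conc_cv: 0.05
hct_baseline_mean: 30.0
hct_baseline_sd: 2.0
pvc_times_h:
- 12.0
- 24.0
- 36.0
pvc_mean_control:
- -6.7
- -4.55
- -2.0
pvc_mean_treatment:
- 3.0
- 2.5
- 1.0
pvc_sd: 3.0
temp_mean_c: 39.2
temp_sd_c: 0.3
leukocytes_mean: 17000.0
leukocytes_sd: 2500.0
neutrophils_mean: 6000.0
neutrophils_sd: 1500.0
lymphocytes_mean: 9000.0
lymphocytes_sd: 2000.0
monocytes_mean: 700.0
monocytes_sd: 150.0
sampling_times_h:
- 0.08333333333333333
- 0.16666666666666666
- 0.3333333333333333
- 0.5
- 0.75
- 1.0
- 1.5
- 2.0
- 4.0
- 6.0
- 8.0
- 10.0
analytes:
  iohexol:
    dose_mg_per_kg: 64.7
    lloq_ug_per_ml: 0.25
    cl_gm: 3.7
    vss_gm: 380.0
    fluid_cl_mean: 1.15
    fluid_vss_mult: 1.06
    test_retest_r_pct: 5.8
    error_model: proportional
    residual_sigma: 0.07
  pah:
    dose_mg_per_kg: 10.0
    lloq_ug_per_ml: 0.25
    cl_gm: 24.3
    vss_gm: 490.0
    fluid_cl_mean: 1.1
    fluid_vss_mult: 1.1
    test_retest_r_pct: 18.0
    error_model: proportional
    residual_sigma: 0.07
  amikacin:
    dose_mg_per_kg: 7.5
    lloq_ug_per_ml: 0.5
    cl_gm: 3.6
    vss_gm: 520.0
    fluid_cl_mean: 1.14
    fluid_vss_mult: 1.0
    test_retest_r_pct: 5.5
    error_model: proportional
    residual_sigma: 0.07
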