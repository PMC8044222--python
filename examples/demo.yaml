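# Demo pipeline run: 2,000-subject synthetic cohort, LDL-C variability (SD
# metric), 24-month exposure window, five chained-equation imputations.
generator:
  n_subjects: 2000
  missingness:
    dm_duration: 0.051
    bmi: 0.067
    acr_baseline: 0.377
model:
  burn_in: 1000
  draws: 4000
imputation:
  m: 5
  sweeps: 10
analysis:
  exposure_parameter: ldl
  variability_metric: sd
  window_months: 24
output_dir: demo_out
seed: 7
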