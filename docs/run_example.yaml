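# Example configuration for `transrep run --config run_example.yaml`.
# Either simulate the packaged study design (optionally scaled down) or
# point `cohort:` (+ optional `panel:`) at existing TSV files.
seed: 17
simulate: true
simulate_scale: 0.25      # fraction of the published stratum sizes
alpha: 0.05
covariates: [age, bmi, sex]
qc:
  max_missing_snps_per_subject: 5
  min_call_rate: 0.95
  hwe_flag_p: 0.01
score:
  weighting: unweighted   # or log_published_or
  imputation: ethnic_2raf # or complete_case
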