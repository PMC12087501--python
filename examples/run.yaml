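# Full-pipeline run on a synthetic cohort. Exactly one of input_path /
# generator may be set; all flags mirror the sensitivity variants.
generator:
  scenario: mixed       # null | direct_only | smoking_only | obstetric_dependent | mixed
  n: 50000
seed: 1
preterm_cutoff: 37      # 34 for the early-preterm sensitivity variant
include_year: false
include_marital: true
smoking_levels: 2
complete_case: false
imputation:
  m: 5
  iterations: 5
k_expansions: 200       # 0 = exact enumeration
bootstrap:
  b_per_imputation: 0   # set to 1000 for the full percentile-bootstrap interval
subsampling:
  n_subsamples: 0       # set to 10000 for the full subsampling interval
out_dir: results/run
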