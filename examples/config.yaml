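# Full-pipeline configuration for `wcyears all examples/config.yaml`.
# Exactly one of `sim` / `input_paths` may be set.
sim:
  n_participants: 4000
  seed: 42
threshold_label: standard      # standard (102/88 cm) | lower (90/76 cm)
inclusion_min_wc_measures: 2   # sensitivity option: 1
grid_rule: cohort_min_age      # or participant_entry
m_imputations: 10
n_bootstrap: 100
adjustments: [age_only, multivariable]
outcome_defs: [all, obesity_related, non_obesity_related]
exposures: [wc_years, single_wc, single_bmi, cum_degree, cum_duration]
seed: 42
outdir: wcyears_run
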