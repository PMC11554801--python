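# Data dictionary

Column conventions for every CSV the package reads or writes.  All files
are plain UTF-8 CSV with a header row.

## Inputs (analysis-facing cohort tables)

### visits.csv — one row per exam

| column | type | units | description |
| --- | --- | --- | --- |
| participant_id | int/str | — | stable participant key |
| sex | str | — | `male` or `female` |
| visit_index | int ≥ 1 | — | exam number; ages strictly increase with it |
| age_at_exam | float | years | age at the exam |
| wc | float, may be empty | cm | waist circumference; plausibility window 40–200 |
| bmi | float, may be empty | kg/m² | body-mass index |

The landmark (baseline) exam is each participant's highest visit_index.

### covariates.csv — one row per participant

| column | type | units | description |
| --- | --- | --- | --- |
| participant_id | int/str | — | key |
| sex | str | — | `male` / `female` |
| baseline_age | float | years | age at the landmark exam |
| race_black | 0/1 | — | self-reported race (Black = 1, White = 0) |
| smoking_ever | 0/1, may be empty | — | ever vs never smoker |
| alcohol | float ≥ 0, may be empty | units/week | alcohol consumption |
| education | int 0–5, may be empty | — | ordinal education level |
| hrt_ever | 0/1, empty for men | — | ever HRT use; structurally absent in men |

### followup.csv — one row per participant

| column | type | units | description |
| --- | --- | --- | --- |
| participant_id | int/str | — | key |
| time_years | float ≥ 0 | years | time from the landmark exam to the first event |
| event_class | str | — | `cancer`, `death`, or `admin` |
| site | str | — | cancer site label; empty unless event_class = cancer |
| is_obesity_related | bool | — | whether the site is in the obesity-related list |

### truth.json (synthetic cohorts only)

Sidecar with the generating random effects, latent exposures and linear
predictor.  Never read by the analysis pipeline.

## Outputs

### yearly_wc.csv
`participant_id, sex, age` (integer years), `wc_hat` (cm): predicted WC
on the contiguous integer-age grid ending at floor(landmark age).

### exposures.csv
`participant_id, sex, wc_years` (cm·years), `cum_degree` (cm·years),
`cum_duration` (years), `single_wc` (cm), `single_bmi` (kg/m²),
`wc_years_category` (`0` / `1-100` / `>100`), `threshold_label`
(`standard` = 102/88, `lower` = 90/76).

### hazard_ratios.csv
One row per sex × outcome × exposure × adjustment: `hr_per_sd`,
`ci_low`, `ci_high` (Wald 95%, pooled over imputations on the log scale),
`n_events`, `epp_eligible` (≥10 events per candidate parameter),
`ph_violations` (semicolon-joined covariates that failed the Schoenfeld
test on the first imputed dataset).

### incidence_rates.csv
`sex, wc_years_category, events, person_years, rate_per_1000py`.

### cstatistics.csv / cstatistic_differences.csv
Optimism-corrected Harrell C per metric (`c_apparent, optimism,
c_corrected, ci_low, ci_high`) and paired deltas between wc-years and
each comparator (`delta_c`, percentile CI, `direction`).

### manifest.json
Package version, seed, config hash, inclusion/threshold settings,
analysis row counts per sex, and the list of output files — everything
needed to attribute a results file to a run.
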