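# wcyears

Cumulative central-adiposity exposure and cancer incidence.

Single measurements of waist circumference (WC) or body-mass index ignore
how long a person has carried excess adiposity.  `wcyears` builds
**waist circumference-years** — the abdominal-obesity analogue of smoking
pack-years — from sparse longitudinal exam data and asks two questions a
cancer epidemiologist would put to a prospective cohort:

1. Is cumulative exposure to excess WC associated with cancer incidence,
   per standard deviation, beyond a single WC or BMI measurement?
2. Does the cumulative metric *discriminate* future cancer cases better
   than the single measurements?

It is written for biostatisticians and epidemiologists who have a visit
table (id, exam age, WC, BMI), a baseline covariate table, and a
time-to-event follow-up table — or who want a fully synthetic cohort with
known ground truth to validate the analysis machinery.

## The model

**Yearly WC prediction.**  With only ~4 exams per person, yearly WC is
predicted from a linear mixed-effects model

    WC_ij = β' x(age_ij, sex_i) + b_0i + b_1i (age_ij − c) + ε_ij,
    (b_0i, b_1i) ~ N(0, Ψ),   ε_ij ~ N(0, σ²),

where the fixed effects hold a sex-specific intercept, a sex × age
interaction, and a natural cubic spline on age (linear beyond its
boundary knots, so backward extrapolation to the cohort minimum entry age
is a straight line).  Each participant's BLUPs (b̂_0i, b̂_1i)
individualise the curve, giving predicted WC on an integer-age grid up to
the landmark exam.

**Exposure metrics.**  With sex-specific thresholds τ (102 cm men, 88 cm
women; 90/76 as a sensitivity preset), over the yearly grid:

    wc-years      = Σ_t max(0, WC_t − τ) × 1 yr        [cm·years]
    cum. degree   = Σ_t max(0, WC_t − τ)               [cm·years]
    cum. duration = #{t : WC_t ≥ τ}                    [years]

plus the single WC and single BMI measured at the landmark exam.
Accumulation pauses in years below the threshold and resumes when WC
exceeds it again.

**Survival analysis.**  Follow-up is landmarked at the last pre-baseline
exam; the first of {outcome cancer, other-class cancer, death,
administrative end} determines each participant's record, with the
non-outcome classes treated as censoring.  Cox proportional-hazards
models (Efron ties) report hazard ratios per within-sex SD of each
metric, age-adjusted and multivariable-adjusted (age, race, smoking,
alcohol, HRT in women; degree/duration models additionally adjust for
baseline WC).  Schoenfeld-residual violations are remediated by
stratification (categorical) or coefficient × log(t) terms (continuous).
Missing covariates are completed by chained-equation multiple imputation
and estimates pooled with Rubin's rules on the log-HR scale.

**Discrimination.**  Harrell's C of each metric's model linear predictor,
corrected for in-sample optimism with the Harrell bootstrap (default 100
resamples), and compared between metrics with a *paired* bootstrap that
reuses identical resamples for both models.

## Worked example

```python
import numpy as np, wcyears as w
from wcyears.discrimination import ModelSpec, compare_c

cfg = w.SimConfig(n_participants=4000, seed=42)
cohort = w.inject_missingness(w.generate_cohort(cfg), cfg)

fit = w.WCTrajectoryModel(cohort.visits).fit()
print(fit.summary())
```

```
WC trajectory model (linear mixed effects, REML)
  participants: 4000   observations: 16000
  spline knots: (50.94, 58.56, 66.43) boundary (44.02, 75.00)
  ...
  random intercept SD:   11.283 cm
  random slope SD:        0.283 cm/yr
  residual SD:            3.032 cm
  converged: True
```

The generating cohort used intercept/slope/residual SDs of 11.0 / 0.30 /
3.0 cm, so the variance components are recovered from four exams per
person.  Yearly predictions then feed the exposure metrics:

```python
yearly = fit.predict_yearly_all()
baseline = cohort.visits[cohort.visits["visit_index"] == 4]
exposures = w.exposure_table(yearly, baseline)
```

```
 participant_id   wc_years  cum_duration  single_wc
              0   0.000000             0  98.925632
              1  87.274355            18  91.419776
              2 145.273387            25 115.070069
```

Participant 1 shows why the cumulative metric differs from a snapshot: a
below-threshold WC at the landmark exam (91.4 cm) but 18 prior years above
the threshold, totalling 87 cm·years.  Landmarked Cox models with multiple
imputation and Rubin pooling:

```python
rows  = w.assemble_landmark_dataset(cohort, exposures, "obesity_related")
women = rows[rows["sex"] == "female"].reset_index(drop=True)
tab = women[["baseline_age","race_black","smoking_ever","alcohol","hrt_ever"]].copy()
tab["event"], tab["log_time"] = women["event"], np.log(women["time"])
imps = w.impute_chained(tab, m=5, seed=7)
pooled, fits = w.fit_cox_pooled(women, imps, "wc_years", "multivariable",
                                "obesity_related")
print(w.check_ph_and_remediate(fits[0]).summary())
```

```
pooled HR per SD: 1.337 (95% CI 1.147, 1.558), 137 events
Cox PH per SD of wc_years [obesity_related, multivariable]
  HR 1.335 (95% CI 1.146, 1.556)   events: 137
  per-SD scale: 1 SD = 189.31   AIC: 2027.0
  covariates: baseline_age, race_black, smoking_ever, alcohol, hrt_ever
  PH violations: none
```

One SD here is 189 cm·years of exposure; each SD multiplies the
obesity-related-cancer hazard by ~1.34 in this cohort (generated with a
true per-SD effect on the all-cancer hazard).  Discrimination comparison:

```python
comp = women.dropna(subset=["hrt_ever","smoking_ever","alcohol"]).reset_index(drop=True)
cmp = compare_c(comp, ModelSpec("wc_years","age_only"),
                ModelSpec("single_wc","age_only"), n_bootstrap=40, seed=1)
print(cmp.summary())
```

```
ΔC (single_wc − wc_years) = -0.0024 (95% CI -0.0172, +0.0076) — no clear difference
```

— the marginal-difference regime: when single WC carries almost the same
ranking information, the paired corrected-C comparison correctly finds no
winner.

A `wcyears` console script wraps the stages (`simulate`, `trajectories`,
`metrics`, `survival`, `rates`, `all`); `wcyears all config.yaml` runs the
whole pipeline from one YAML config and writes the report CSVs plus a run
manifest.  Column conventions are in `docs/data_dictionary.md`.

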