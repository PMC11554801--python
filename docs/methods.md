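# Methods

This note records the statistical model, the defaults and the design
choices behind `wcyears`, in the order the pipeline runs them.

## Study design emulated

A prospective cohort observed at four exams ~3 years apart, landmarked at
the fourth exam: all exposure metrics are frozen there, follow-up for
cancer starts there, and only pre-baseline information enters the
exposures.  Inclusion requires an observed WC and BMI at the landmark
exam and at least 2 non-missing pre-baseline WC measurements (the
sensitivity option relaxes this to 1).  Men and women are analysed
separately throughout — thresholds, SD scaling and covariate sets are
sex-specific — except the trajectory model, which pools sexes through
interaction terms to share the age-curvature estimate.

## WC trajectory model

`WCTrajectoryModel` fits, by REML via statsmodels `MixedLM`,

    WC_ij = β0 + β_m 1[male] + β_ma 1[male](age_ij − c)
            + f(age_ij) + b_0i + b_1i (age_ij − c) + ε_ij

* `f` is a natural cubic spline on age: 3 interior knots at the 10/50/90%
  age quantiles, boundary knots at the observed age range (configurable
  via `SplineSpec`).  The basis is the truncated-power construction,
  exactly linear outside the boundary knots; its span equals R's
  `splines::ns` (checked against an R oracle in the tests).  Linearity in
  the tails is what makes backward extrapolation to the cohort minimum
  entry age defensible: below the first knot the individual prediction is
  the participant's own BLUP line.
* Sex enters as an intercept and a sex × linear-age term; the spline
  curvature is shared across sexes.  This is the smallest structure that
  allows sex-specific levels and trends plus a smooth common shape;
  single-sex data must be fitted with `sex_interaction=False`, otherwise
  the rank-deficient design raises immediately.
* The random slope is internally rescaled to decades: per-year slope
  variance (~0.1 cm²/yr²) sits three orders of magnitude below the
  intercept variance (~120 cm²), which stalls the profiled-REML
  optimiser; on the decade scale the components are commensurate and
  L-BFGS converges reliably.  Estimates are transformed back before being
  reported.
* Degenerate noise-free inputs (data exactly on the population curve) are
  detected by an exact least-squares fit up front and returned with zero
  variance components — the REML criterion is unbounded there and no
  optimiser should be asked to find that corner.
* Non-convergence raises `ConvergenceError` carrying the optimiser state;
  there is no silent fallback.
* WC readings outside a plausibility window (default 40–200 cm) are
  treated as implausible and dropped, like missing values.

Yearly predictions are the conditional mean `Xβ + Zb` on a contiguous
integer-age grid, closed at both ends, ending at floor(landmark age).
The default grid starts at floor(cohort minimum exam age)
(`grid_rule="cohort_min_age"`); `"participant_entry"` starts at each
participant's own first exam for users who consider backward
extrapolation too aggressive.  Integer ages make the cm·year arithmetic
exact; a fractional-age convention would only rescale every metric by a
constant near 1.

## Exposure metrics

Definitions as in the README.  Three conventions worth stating:

* A year exactly at the threshold counts toward **duration** (the
  definition is "≥") but contributes zero **degree**.
* On the yearly grid, wc-years and cumulative degree are numerically
  identical (each year's excess × 1 year, summed).  They are kept as
  separate columns because they are modelled differently downstream:
  degree/duration Cox models additionally adjust for baseline WC, which
  changes the interpretation from "total exposure" to "exposure history
  beyond the current level".  A `component_grid="visits"` mode computes
  degree/duration over the observed exams only.
* The incidence-rate categories are 0, (0, 100] and (100, ∞) cm·years;
  the value 100 falls in the middle bin (the labels "1-100" and ">100"
  imply a closed upper bound).

Per-SD standardisation uses the sample SD (ddof=1) within the
sex-specific analysis sample, and the SD used is recorded so hazard
ratios can be back-converted to natural units.

## Synthetic cohort generator

`generate_cohort` draws from the exact model family the analysis assumes,
which is deliberate: recovery tests then isolate estimation error from
model misspecification.  Defaults and their provenance:

| parameter | default | rationale |
| --- | --- | --- |
| entry age | truncated N(54, 5.7²) on [44, 66] | landmark age ≈ 63 (SD ≈ 5), minimum exam age 44 |
| visits | 4, 3-year gaps, optional jitter | quadrennial cohort cadence |
| WC intercepts (age 60) | 101.9 (m) / 99.4 (f) cm | calibrated so landmark means ≈ 103 / 101 cm |
| WC slopes | 0.35 / 0.45 cm/yr | mid-life WC drift, faster in women |
| random intercept / slope SD | 11.0 cm / 0.30 cm/yr, corr 0.3 | landmark WC SD ≈ 12 cm |
| residual SD | 3.0 cm | exam-to-exam measurement + short-term variation |
| BMI link | 0.30 kg/m² per cm WC + N(0, 1.8²) | landmark BMI means 28.5 / 29.2, WC–BMI corr ≈ 0.85 |
| covariates | Black 19%/27%, ever-smoker 72%/47%, HRT 50% (women), alcohol N⁺(3.9, 7.8²)/N⁺(1.2, 3.2²) u/wk | cohort prevalences (men/women) |
| cancer hazard | exponential, 0.005/yr; per-SD log-HR 0.15 | obesity-related-cancer incidence; HR ≈ 1.16 per SD |
| covariate log-HRs | age 0.06/yr, smoking 0.30, race 0.10, alcohol 0.005/u, HRT −0.10 | plausible cancer-risk gradients |
| competing death | exponential, 0.020/yr | other-cause mortality at these ages |
| admin horizon | 17 years | registry follow-up window |
| missingness | smoking/alcohol 0.7%, education 0.2%, HRT 27% (women only); logistic in standardised age and baseline WC | MAR with observed drivers |

The single female WC SD (≈12 cm here vs ≈16 cm in the emulated
population) is a known compromise: variance components are shared across
sexes, as in the analysis model itself.

Event times use inverse-transform sampling on the cumulative hazard
(exponential or Weibull baseline — both have closed forms used as test
oracles); the earliest of cancer, other-cause death and administrative
censoring defines the record, and cancer events receive a site label
from sex-specific multinomials whose obesity-related shares mirror
registry-style site mixes.  The exposure that drives the hazard is
configurable (`true_metric`), so discrimination tests can construct a
known winner.

What the generator does **not** emulate: secular calendar-time trends in
WC, informative (MNAR) missingness, visit non-attendance/dropout before
the landmark, measurement-protocol drift, and non-proportional hazards.
Passing tests therefore demonstrate that the *machinery* is correct and
calibrated under its stated assumptions — not that those assumptions hold
in any particular real cohort.

## Multiple imputation and pooling

Chained equations via statsmodels `MICEData`: every incomplete variable
is imputed by predictive mean matching against a Gaussian working model,
so binary/ordinal variables keep their support (donors are observed
values).  One chain per imputation set, 10 burn cycles between saved
datasets (conventional thinning); the event indicator and log follow-up
time are included as predictors.  HRT is imputed for women only — for men
the variable is structurally absent, not missing.  Rubin's rules pool on
the log-HR scale (C statistics pool on the raw scale: bounded and
approximately Gaussian at these event counts), with the small-sample
degrees of freedom `(m−1)(1 + W/((1+1/m)B))²` and a t-based Wald CI.

## Survival models

Efron tie handling (lifelines' default and that of mainstream survival
software).  PH diagnostics use the Schoenfeld-residual score test with a
log-time transform at α = 0.05.  Remediation: categorical violators
(race, smoking, HRT) become strata; continuous violators (age, alcohol,
baseline WC) receive a coefficient × log(t) interaction, implemented by
episode-splitting at ~40 event-time quantiles — a step approximation to
the exact every-event-time split, chosen to keep the long-format fit
linear in the sample size.  The
model is refitted once and re-tested; a persistent violation on the
exposure itself sets `ph_flag_exposure` rather than being absorbed
silently.  The events-per-parameter screen (≥10 events per candidate
parameter) is reported per outcome; the pipeline flags ineligible
outcomes but does not hard-block them, since borderline site analyses are
a judgment call for the analyst.

## Discrimination

Harrell's C uses the standard conventions: pairs with tied times and two
events are not comparable; a tied time with exactly one event compares
the event member as earlier; tied scores count 1/2.  The concordance
engine is lifelines' `concordance_index`; the test suite holds an
independent exhaustive-pair oracle.  Optimism correction follows the
Harrell bootstrap (refit on resample; optimism = C on resample − C of the
refit on the original data; corrected = apparent − mean optimism), with
non-convergent resamples redrawn (capped at 10× the bootstrap count).
CIs on C and on C differences are percentile intervals of the
per-resample corrected values; comparisons are paired — both models are
refitted on identical resamples — so the delta CI reflects the strong
correlation between two metrics fitted to the same cohort.  C is
evaluated on the model linear predictor, not the raw exposure, matching
how the metrics are used in adjusted models.

## Problem sizes in the test suite

Simulation tests run at the sizes where their Monte-Carlo bands are
meaningful on a single CPU in minutes: per-SD HR recovery at n = 10,000
over 20 seeds (m = 3 imputations — between-imputation variance is
negligible at 0.7% missingness); trajectory recovery at n = 5,000 over 20
seeds; null calibration at n = 3,000 over 40 seeds; discrimination
scenarios at n = 10,000/4,000 with 25 bootstrap resamples.  Pass bounds
are binomial 3-sigma bands at those counts, fixed before the tests were
first run.

## Known limitations

* BLUP-based exposures are shrunken versions of the latent truth; per-SD
  hazard ratios estimated through the full trajectory pipeline are mildly
  attenuated relative to fits on the latent exposures (regression
  dilution).  The recovery tests quantify the machinery on the latent
  scale; the pipeline reports what an analyst would actually obtain.
* Competing events are censored, not modelled (no subdistribution
  hazards); estimands are cause-specific.
* The chained-equation engine uses PMM throughout rather than
  per-variable-type models (logistic/multinomial); at the default
  missingness rates the practical difference is nil, but users with
  heavily missing categorical data should treat `impute_chained` as a
  default, not a recommendation.
* `MICEData` draws from NumPy's global RNG; `impute_chained` scopes and
  restores that state around a seeded block, so runs are reproducible but
  concurrent imputations in one process are not supported.
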