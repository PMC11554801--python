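"""Synthetic cohort generator with known ground truth.

Emulates the longitudinal, covariate, missingness and time-to-event
structure that the waist circumference-years analysis assumes: ~10,000
participants examined at four visits at three-year intervals, entering in
mid-life (entry age truncated-normal on [44, 66] so that the landmark
Visit-4 age averages ≈63), WC following a linear mixed-effects model
(sex-specific fixed intercept and slope, shared smooth age curvature,
participant random intercept + slope, iid residual), baseline covariates
drawn from configured prevalences, and proportional-hazards cancer
outcomes with competing other-cause death and administrative censoring
over a ~17-year horizon.

Every cohort carries a ``truth`` block: the generating parameters, each
participant's latent random effects, the noise-free yearly WC series on
the integer-age grid and the exposure metrics computed from it, and the
linear predictor that drove the hazard.  The truth block exists only for
synthetic cohorts and is never written to the analysis-facing CSVs, so
pipeline code cannot leak it.

The exposure metric that actually drives the hazard is configurable
(``wc_years``, ``degree``, ``duration`` or ``single_wc``), which gives
discrimination comparisons a known winner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ThresholdSpec
from .splines import SplineSpec, natural_cubic_basis

# Cancer-site labels used by the simulator.  "or" = obesity-related
# (colorectal, kidney, pancreas and the residual obesity-related group,
# which in women includes post-menopausal breast, endometrial and ovarian
# sites broken out separately); everything else is non-obesity-related.
OBESITY_RELATED_SITES = frozenset(
    {
        "colorectal",
        "kidney",
        "pancreas",
        "breast",
        "endometrial",
        "ovarian",
        "other_or",
    }
)

_SITE_PROBS_MALE = {
    "colorectal": 0.083,
    "kidney": 0.036,
    "pancreas": 0.030,
    "other_or": 0.053,
    "lung": 0.139,
    "prostate": 0.377,
    "bladder": 0.035,
    "other_nor": 0.247,
}
_SITE_PROBS_FEMALE = {
    "colorectal": 0.107,
    "kidney": 0.033,
    "pancreas": 0.035,
    "breast": 0.288,
    "endometrial": 0.061,
    "ovarian": 0.032,
    "other_or": 0.050,
    "lung": 0.123,
    "other_nor": 0.271,
}

_EDU_PROBS_MALE = (0.137, 0.295, 0.097, 0.277, 0.109, 0.085)
_EDU_PROBS_FEMALE = (0.089, 0.256, 0.080, 0.381, 0.133, 0.061)


@dataclass(frozen=True)
class VisitSchedule:
    """Exam schedule: entry age distribution plus fixed inter-visit gap."""

    entry_age_mean: float = 54.0
    entry_age_sd: float = 5.7
    entry_age_range: tuple[float, float] = (44.0, 66.0)
    gap_years: float = 3.0
    n_visits: int = 4
    jitter_sd: float = 0.0  # optional gaussian jitter on exam timing

    def __post_init__(self) -> None:
        if self.gap_years <= 0:
            raise ValueError("inter-visit gap must be positive")
        if self.n_visits < 2:
            raise ValueError("need at least 2 visits per participant")
        if self.entry_age_sd <= 0 or self.jitter_sd < 0:
            raise ValueError("entry_age_sd must be > 0 and jitter_sd >= 0")


@dataclass(frozen=True)
class WCModelParams:
    """Generating linear-mixed-effects model for WC (cm scale).

    The population curve at age ``a`` for sex ``s`` is
    ``intercept_s + slope_s (a − age_center) + curvature(a)``, where the
    curvature is a natural cubic spline shared across sexes.  Participant
    deviations are a bivariate-normal random intercept and slope plus an
    iid residual.  Defaults put the male Visit-4 mean/SD near 103/12 cm
    and the female mean near 101 cm.
    """

    intercept_male: float = 101.9
    intercept_female: float = 99.4
    slope_male: float = 0.35
    slope_female: float = 0.45
    age_center: float = 60.0
    spline_spec: SplineSpec = field(
        default_factory=lambda: SplineSpec(knots=(50.0, 57.0, 64.0), boundary=(44.0, 70.0))
    )
    spline_coefs: tuple[float, ...] = (0.0, 0.0, 0.0)
    random_intercept_sd: float = 11.0
    random_slope_sd: float = 0.30
    intercept_slope_corr: float = 0.30
    residual_sd: float = 3.0
    # baseline-BMI link: bmi = bmi_intercept_s + bmi_per_cm * (wc_true - intercept_s) + noise
    bmi_intercept_male: float = 28.5
    bmi_intercept_female: float = 29.2
    bmi_per_cm: float = 0.30
    bmi_resid_sd: float = 1.8

    def __post_init__(self) -> None:
        if min(self.random_intercept_sd, self.random_slope_sd) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.residual_sd < 0 or self.bmi_resid_sd < 0:
            raise ValueError("residual SDs must be >= 0")
        if not -1.0 < self.intercept_slope_corr < 1.0:
            raise ValueError("intercept-slope correlation must be in (-1, 1)")
        if len(self.spline_coefs) != self.spline_spec.n_basis - 1:
            raise ValueError(
                "spline_coefs must have one value per curvature column "
                f"({self.spline_spec.n_basis - 1})"
            )

    def population_curve(self, ages: np.ndarray, sex: str) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        icpt = self.intercept_male if sex == "male" else self.intercept_female
        slope = self.slope_male if sex == "male" else self.slope_female
        mu = icpt + slope * (ages - self.age_center)
        if any(c != 0 for c in self.spline_coefs):
            basis = natural_cubic_basis(ages, self.spline_spec)[:, 1:]
            mu = mu + basis @ np.asarray(self.spline_coefs)
        return mu


@dataclass(frozen=True)
class CovariatePrevalences:
    """Baseline covariate distribution, by sex where prevalences differ."""

    female_frac: float = 0.554
    race_black: tuple[float, float] = (0.188, 0.269)  # (male, female)
    smoking_ever: tuple[float, float] = (0.72, 0.47)
    hrt_ever_female: float = 0.497
    alcohol_mean: tuple[float, float] = (3.9, 1.2)  # units/week
    alcohol_sd: tuple[float, float] = (7.8, 3.2)
    education_probs_male: tuple[float, ...] = _EDU_PROBS_MALE
    education_probs_female: tuple[float, ...] = _EDU_PROBS_FEMALE

    def __post_init__(self) -> None:
        for p in (
            self.female_frac,
            *self.race_black,
            *self.smoking_ever,
            self.hrt_ever_female,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class OutcomeParams:
    """Proportional-hazards outcome model with competing events.

    Cancer hazard: ``h0(t) · exp(lp)`` with ``h0`` exponential (rate) or
    Weibull (rate, shape; cumulative hazard ``(rate·t)^shape``), where the
    linear predictor carries the designated true exposure per within-sex
    SD plus covariate effects.  Other-cause death is an independent
    exponential competing event; administrative censoring applies at the
    horizon.  Defaults mirror obesity-related-cancer incidence (~0.005/yr)
    and a per-SD hazard ratio of exp(0.15) ≈ 1.16.
    """

    baseline: str = "exponential"  # or "weibull"
    rate: float = 0.005
    shape: float = 1.0
    log_hr_per_sd: float = 0.15
    true_metric: str = "wc_years"  # wc_years | degree | duration | single_wc
    covariate_log_hrs: dict[str, float] = field(
        default_factory=lambda: {
            "baseline_age": 0.06,  # per year above age 60
            "race_black": 0.10,
            "smoking_ever": 0.30,
            "alcohol": 0.005,  # per unit/week
            "hrt_ever": -0.10,  # women only
        }
    )
    death_rate: float = 0.020
    admin_horizon_years: float = 17.0

    def __post_init__(self) -> None:
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.rate <= 0 or self.shape <= 0 or self.death_rate < 0:
            raise ValueError("hazard rates and shape must be positive")
        if self.admin_horizon_years < 0:
            raise ValueError("admin horizon must be >= 0")
        if self.true_metric not in ("wc_years", "degree", "duration", "single_wc"):
            raise ValueError(f"unknown true_metric {self.true_metric!r}")


@dataclass(frozen=True)
class MissingnessParams:
    """MAR missingness for baseline covariates.

    Each covariate cell is set missing with probability logistic in fully
    observed variables (age and baseline WC, both standardised), anchored
    so the marginal rate approximates the configured rate.  WC and BMI
    are never made missing — they define study inclusion.  HRT
    missingness applies to women only.  Default rates mirror ~0.7% for
    smoking/alcohol and ~27% for HRT.
    """

    rates: dict[str, float] = field(
        default_factory=lambda: {
            "smoking_ever": 0.007,
            "alcohol": 0.007,
            "education": 0.002,
            "hrt_ever": 0.27,
        }
    )
    mar_coef_age: float = 0.3  # per SD of baseline age
    mar_coef_wc: float = 0.15  # per SD of baseline WC

    def __post_init__(self) -> None:
        for name, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 10_000
    seed: int = 0
    schedule: VisitSchedule = field(default_factory=VisitSchedule)
    wc_model: WCModelParams = field(default_factory=WCModelParams)
    covariates: CovariatePrevalences = field(default_factory=CovariatePrevalences)
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    site_probs_male: dict[str, float] = field(default_factory=lambda: dict(_SITE_PROBS_MALE))
    site_probs_female: dict[str, float] = field(default_factory=lambda: dict(_SITE_PROBS_FEMALE))
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")


@dataclass
class Cohort:
    """Synthetic (or loaded) cohort in long/tidy tables.

    ``visits``: participant_id, sex, visit_index, age_at_exam, wc, bmi.
    ``covariates``: participant_id, sex, baseline_age, race_black,
    smoking_ever, alcohol, education, hrt_ever (NaN for men —
    structurally absent, not missing).
    ``followup``: participant_id, time_years (from the landmark exam),
    event_class ∈ {cancer, death, admin}, site ("" unless cancer),
    is_obesity_related.
    ``truth``: generating parameters + latents; only for synthetic data.
    """

    visits: pd.DataFrame
    covariates: pd.DataFrame
    followup: pd.DataFrame
    truth: dict | None = None

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three analysis-facing CSVs plus a truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("visits", "covariates", "followup"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        if self.truth is not None:
            p = outdir / "truth.json"
            serializable = {
                k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame) else v)
                for k, v in self.truth.items()
                if k != "config"
            }
            p.write_text(json.dumps(serializable))
            paths["truth"] = p
        return paths


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_event_times(
    linear_predictors: np.ndarray,
    outcome: OutcomeParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate first-event records under a proportional-hazards model.

    Cancer times come from inverse-transform sampling on the cumulative
    hazard ``H(t) = H0(t)·exp(lp)``; other-cause death is exponential;
    administrative censoring applies at the horizon.  The earliest of the
    three defines the record.  Deterministic given (seed, inputs).
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictors")
    if outcome.admin_horizon_years < 0:
        raise ValueError("negative admin horizon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = lp.size
    e_unit = rng.exponential(1.0, size=n)
    # H0(t) = rate*t (exponential) or (rate*t)^shape (Weibull); solve H0(t)*exp(lp) = E
    h_target = e_unit / np.exp(lp)
    if outcome.baseline == "exponential":
        t_cancer = h_target / outcome.rate
    else:
        t_cancer = np.power(h_target, 1.0 / outcome.shape) / outcome.rate
    if outcome.death_rate > 0:
        t_death = rng.exponential(1.0 / outcome.death_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    t_admin = np.full(n, float(outcome.admin_horizon_years))
    times = np.column_stack([t_cancer, t_death, t_admin])
    which = times.argmin(axis=1)
    classes = np.array(["cancer", "death", "admin"])[which]
    return pd.DataFrame(
        {"time_years": times[np.arange(n), which], "event_class": classes}
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a complete synthetic cohort (no missingness yet).

    Deterministic under ``(config.seed, config)``.  Use
    :func:`inject_missingness` afterwards for MAR covariate holes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    sch, wcm, cov, out = config.schedule, config.wc_model, config.covariates, config.outcome

    female = rng.random(n) < cov.female_frac
    sex = np.where(female, "female", "male")
    entry_age = _truncnorm(
        rng, sch.entry_age_mean, sch.entry_age_sd, *sch.entry_age_range, size=n
    )
    offsets = np.arange(sch.n_visits) * sch.gap_years
    ages = entry_age[:, None] + offsets[None, :]
    if sch.jitter_sd > 0:
        jit = rng.normal(0.0, sch.jitter_sd, size=(n, sch.n_visits))
        jit[:, 0] = 0.0
        ages = np.sort(ages + jit, axis=1)

    # random effects
    cov_re = np.array(
        [
            [wcm.random_intercept_sd**2,
             wcm.intercept_slope_corr * wcm.random_intercept_sd * wcm.random_slope_sd],
            [wcm.intercept_slope_corr * wcm.random_intercept_sd * wcm.random_slope_sd,
             wcm.random_slope_sd**2],
        ]
    )
    # "eigh" factorisation handles the degenerate zero-variance limits
    re = rng.multivariate_normal(np.zeros(2), cov_re, size=n, method="eigh")
    b0, b1 = re[:, 0], re[:, 1]

    mu = np.empty_like(ages)
    for s in ("male", "female"):
        m = sex == s
        mu[m] = wcm.population_curve(ages[m].ravel(), s).reshape(-1, sch.n_visits)
    agec = ages - wcm.age_center
    wc_true = mu + b0[:, None] + b1[:, None] * agec
    wc_obs = wc_true + rng.normal(0.0, wcm.residual_sd, size=ages.shape)

    # baseline BMI linked to true baseline WC
    icpt = np.where(female, wcm.intercept_female, wcm.intercept_male)
    bmi_icpt = np.where(female, wcm.bmi_intercept_female, wcm.bmi_intercept_male)
    bmi = (
        bmi_icpt[:, None]
        + wcm.bmi_per_cm * (wc_true - icpt[:, None])
        + rng.normal(0.0, wcm.bmi_resid_sd, size=ages.shape)
    )

    pid = np.arange(n)
    visits = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, sch.n_visits),
            "sex": np.repeat(sex, sch.n_visits),
            "visit_index": np.tile(np.arange(1, sch.n_visits + 1), n),
            "age_at_exam": ages.ravel(),
            "wc": wc_obs.ravel(),
            "bmi": bmi.ravel(),
        }
    )

    # covariates
    race_black = rng.random(n) < np.where(female, cov.race_black[1], cov.race_black[0])
    smoking = rng.random(n) < np.where(female, cov.smoking_ever[1], cov.smoking_ever[0])
    alcohol = np.maximum(
        0.0,
        rng.normal(
            np.where(female, cov.alcohol_mean[1], cov.alcohol_mean[0]),
            np.where(female, cov.alcohol_sd[1], cov.alcohol_sd[0]),
        ),
    )
    edu = np.empty(n, dtype=int)
    for s, probs in (("male", cov.education_probs_male), ("female", cov.education_probs_female)):
        m = sex == s
        p = np.asarray(probs) / np.sum(probs)
        edu[m] = rng.choice(len(p), size=int(m.sum()), p=p)
    hrt = np.where(female, (rng.random(n) < cov.hrt_ever_female).astype(float), np.nan)
    baseline_age = ages[:, -1]
    covariates = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "baseline_age": baseline_age,
            "race_black": race_black.astype(int),
            "smoking_ever": smoking.astype(int),
            "alcohol": alcohol,
            "education": edu,
            "hrt_ever": hrt,
        }
    )

    # noise-free yearly truth series and true exposure metrics (vectorised:
    # common integer grid, per-participant mask up to floor(baseline age))
    grid_start = int(np.floor(ages[:, 0].min()))
    grid_full = np.arange(grid_start, int(np.floor(baseline_age.max())) + 1, dtype=float)
    curve_m = wcm.population_curve(grid_full, "male")
    curve_f = wcm.population_curve(grid_full, "female")
    curve = np.where(female[:, None], curve_f[None, :], curve_m[None, :])
    series = curve + b0[:, None] + b1[:, None] * (grid_full[None, :] - wcm.age_center)
    in_grid = grid_full[None, :] <= np.floor(baseline_age)[:, None]
    thr = np.where(
        female, config.thresholds.female_cm, config.thresholds.male_cm
    )[:, None]
    excess = np.maximum(series - thr, 0.0) * in_grid
    metric_vals = {
        "wc_years": excess.sum(axis=1),
        "degree": excess.sum(axis=1),
        "duration": ((series >= thr) & in_grid).sum(axis=1).astype(float),
    }
    single_wc_true = wc_true[:, -1]
    metric_vals["single_wc"] = single_wc_true

    # hazard linear predictor: true metric per within-sex SD + covariates
    driver = metric_vals[out.true_metric]
    z = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        sd = driver[m].std(ddof=1)
        z[m] = (driver[m] - driver[m].mean()) / sd if sd > 0 else 0.0
    clh = out.covariate_log_hrs
    lp = (
        out.log_hr_per_sd * z
        + clh.get("baseline_age", 0.0) * (baseline_age - 60.0)
        + clh.get("race_black", 0.0) * race_black
        + clh.get("smoking_ever", 0.0) * smoking
        + clh.get("alcohol", 0.0) * alcohol
        + clh.get("hrt_ever", 0.0) * np.nan_to_num(hrt)
    )

    followup = generate_event_times(lp, out, rng)
    followup.insert(0, "participant_id", pid)
    # site labels for cancer events
    site = np.array([""] * n, dtype=object)
    is_cancer = (followup["event_class"] == "cancer").to_numpy()
    for s, probs in (("male", config.site_probs_male), ("female", config.site_probs_female)):
        m = (sex == s) & is_cancer
        if m.any():
            names = list(probs)
            p = np.asarray([probs[k] for k in names])
            p = p / p.sum()
            site[m] = rng.choice(names, size=int(m.sum()), p=p)
    followup["site"] = site
    followup["is_obesity_related"] = [
        s in OBESITY_RELATED_SITES if s else False for s in site
    ]

    truth = {
        "config": config,
        "random_effects": pd.DataFrame(
            {"participant_id": pid, "b0": b0, "b1": b1}
        ),
        "true_exposures": pd.DataFrame(
            {
                "participant_id": pid,
                "sex": sex,
                "wc_years": metric_vals["wc_years"],
                "cum_degree": metric_vals["degree"],
                "cum_duration": metric_vals["duration"],
                "single_wc": single_wc_true,
                "single_bmi": bmi[:, -1],
            }
        ),
        "linear_predictor": lp.tolist(),
        "grid_start": grid_start,
        "true_metric": out.true_metric,
        "log_hr_per_sd": out.log_hr_per_sd,
    }
    return Cohort(visits=visits, covariates=covariates, followup=followup, truth=truth)


def inject_missingness(cohort: Cohort, config: SimConfig, seed: int | None = None) -> Cohort:
    """Punch MAR holes into baseline covariates (never WC/BMI).

    Missingness probability is logistic in standardised baseline age and
    WC (both fully observed), anchored at the configured marginal rate.
    HRT missingness applies to women only.  Returns a new cohort; the
    input is not modified.
    """
    mp = config.missingness
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    covs = cohort.covariates.copy()
    base_wc = (
        cohort.visits.sort_values("visit_index")
        .groupby("participant_id")["wc"]
        .last()
        .reindex(covs["participant_id"])
        .to_numpy()
    )
    age_z = (covs["baseline_age"] - covs["baseline_age"].mean()) / covs["baseline_age"].std()
    wc_z = (base_wc - np.nanmean(base_wc)) / np.nanstd(base_wc)
    eta_common = mp.mar_coef_age * age_z.to_numpy() + mp.mar_coef_wc * np.nan_to_num(wc_z)
    for var, rate in mp.rates.items():
        if var not in covs.columns:
            continue
        if rate == 0:
            continue
        anchor = np.log(rate / (1 - rate)) if rate < 1 else np.inf
        p = 1.0 / (1.0 + np.exp(-(anchor + eta_common)))
        holes = rng.random(len(covs)) < p
        if var == "hrt_ever":
            holes &= (covs["sex"] == "female").to_numpy()
        covs.loc[holes, var] = np.nan
    return Cohort(
        visits=cohort.visits.copy(),
        covariates=covs,
        followup=cohort.followup.copy(),
        truth=cohort.truth,
    )
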