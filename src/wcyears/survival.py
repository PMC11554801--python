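"""Landmarked Cox analysis of cumulative adiposity exposures.

Follow-up starts at the landmark exam (the last pre-baseline visit, at
which every exposure metric is frozen).  For a chosen outcome definition
(all cancers, obesity-related, non-obesity-related, the latter excluding
lung/prostate, or a single site) the first event of any *other* class —
another cancer group, other-cause death, administrative end of study —
censors follow-up at its date; competing events are censored, not
modelled.

Hazard ratios are reported per within-sex standard deviation of each
exposure metric, age-adjusted or multivariable-adjusted (baseline age,
race, smoking, alcohol, HRT in women; degree/duration models additionally
adjust for baseline WC).  Ties use the Efron approximation.  Covariates
that violate proportional hazards are stratified (categorical) or given a
coefficient × log(time) interaction (continuous), mirroring standard
remediation practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.statistics import proportional_hazard_test

from .impute import ImputationSet, PooledEstimate, pool_rubin
from .metrics import standardize_per_sd
from .simulate import Cohort

OUTCOME_DEFS = ("all", "obesity_related", "non_obesity_related", "nor_excl_lung_prostate")
EXPOSURES = ("wc_years", "cum_degree", "cum_duration", "single_wc", "single_bmi")
_CATEGORICAL_COVS = {"race_black", "smoking_ever", "hrt_ever"}
_MULTIVARIABLE_SET = ("baseline_age", "race_black", "smoking_ever", "alcohol")


def _event_predicate(outcome_def):
    """Map an outcome definition to a predicate on (site, is_obesity_related)."""
    if isinstance(outcome_def, tuple) and outcome_def[0] == "site":
        target = outcome_def[1]
        return lambda site, is_or: site == target
    if outcome_def == "all":
        return lambda site, is_or: True
    if outcome_def == "obesity_related":
        return lambda site, is_or: bool(is_or)
    if outcome_def == "non_obesity_related":
        return lambda site, is_or: not is_or
    if outcome_def == "nor_excl_lung_prostate":
        return lambda site, is_or: (not is_or) and site not in ("lung", "prostate")
    raise ValueError(f"unknown outcome definition {outcome_def!r}")


def assemble_landmark_dataset(
    cohort: Cohort,
    exposures: pd.DataFrame,
    outcome_def="all",
    min_wc_measures: int = 2,
) -> pd.DataFrame:
    """One analysis row per eligible participant for one outcome definition.

    Inclusion: observed WC and BMI at the landmark exam and at least
    ``min_wc_measures`` non-missing pre-baseline WC measurements (2 in the
    main analysis; 1 in the sensitivity analysis).  ``event`` is 1 iff the
    first event is a cancer inside the outcome definition; a first event
    of any other class censors at its date with ``censor_reason`` in
    {other-cancer, death, admin}; event-free rows carry reason ``admin``.
    """
    pred = _event_predicate(outcome_def)
    visits = cohort.visits
    base_ix = visits.groupby("participant_id")["visit_index"].transform("max")
    at_base = visits[visits["visit_index"] == base_ix].set_index("participant_id")
    pre = visits[visits["visit_index"] < base_ix]
    n_pre_wc = pre.groupby("participant_id")["wc"].apply(lambda s: int(s.notna().sum()))

    eligible = at_base.index[
        at_base["wc"].notna()
        & at_base["bmi"].notna()
        & (n_pre_wc.reindex(at_base.index).fillna(0) >= min_wc_measures)
    ]
    fu = cohort.followup.set_index("participant_id").loc[eligible]
    if (fu["time_years"] < 0).any():
        raise ValueError("negative follow-up time: events before baseline must be excluded upstream")

    is_cancer = fu["event_class"] == "cancer"
    in_def = np.array(
        [pred(s, o) for s, o in zip(fu["site"], fu["is_obesity_related"])]
    )
    event = (is_cancer & in_def).astype(int)
    reason = np.where(
        event == 1,
        "none",
        np.where(
            is_cancer,
            "other-cancer",
            np.where(fu["event_class"] == "death", "death", "admin"),
        ),
    )
    rows = pd.DataFrame(
        {
            "participant_id": eligible,
            "time": fu["time_years"].to_numpy(),
            "event": event.to_numpy(),
            "censor_reason": reason,
        }
    )
    if (rows["time"] <= 0).any():
        # landmarking requires strictly positive follow-up; drop t == 0 admin rows
        rows = rows[rows["time"] > 0]
    covs = cohort.covariates.set_index("participant_id")
    expo = exposures.set_index("participant_id")
    out = (
        rows.set_index("participant_id")
        .join(covs.drop(columns=["sex"], errors="ignore"))
        .join(expo.drop(columns=["sex"], errors="ignore"))
        .reset_index()
    )
    out["sex"] = covs["sex"].reindex(out["participant_id"]).to_numpy()
    if "wc_years_category" not in out.columns and "wc_years" in out.columns:
        from .metrics import categorize_wc_years

        out["wc_years_category"] = [
            categorize_wc_years(v) for v in out["wc_years"]
        ]
    return out


@dataclass
class ExposureCoxResults:
    """Per-SD Cox fit for one exposure × outcome × adjustment tier."""

    exposure: str
    adjustment: str
    outcome_label: str
    log_hr_per_sd: float
    se: float
    n_events: int
    sd_used: float
    aic: float
    covariates: tuple[str, ...]
    strata: tuple[str, ...] = ()
    time_varying_terms: tuple[str, ...] = ()
    ph_diagnostics: pd.DataFrame | None = None
    ph_flag_exposure: bool = False
    _fitter: object = None
    _df: pd.DataFrame | None = None
    _model: "ExposureCoxModel | None" = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr_per_sd))

    @property
    def ci(self) -> tuple[float, float]:
        lo = self.log_hr_per_sd - 1.959963984540054 * self.se
        hi = self.log_hr_per_sd + 1.959963984540054 * self.se
        return float(np.exp(lo)), float(np.exp(hi))

    def linear_predictor(self, rows: pd.DataFrame) -> np.ndarray:
        """Model risk score for arbitrary rows (used by discrimination)."""
        df = self._model.design_frame(rows)
        cols = [c for c in df.columns if c not in ("time", "event", *self.strata)]
        params = self._fitter.params_
        return df[params.index].to_numpy() @ params.to_numpy()

    def summary(self) -> str:
        lo, hi = self.ci
        lines = [
            f"Cox PH per SD of {self.exposure} [{self.outcome_label}, {self.adjustment}]",
            f"  HR {self.hr:.3f} (95% CI {lo:.3f}, {hi:.3f})   events: {self.n_events}",
            f"  per-SD scale: 1 SD = {self.sd_used:.2f}   AIC: {self.aic:.1f}",
            f"  covariates: {', '.join(self.covariates) or '(none)'}",
        ]
        if self.strata:
            lines.append(f"  stratified by: {', '.join(self.strata)}")
        if self.time_varying_terms:
            lines.append(
                f"  time-varying (x log t): {', '.join(self.time_varying_terms)}"
            )
        if self.ph_diagnostics is not None:
            flagged = self.ph_diagnostics.query("violates")["variable"].tolist()
            lines.append(f"  PH violations: {flagged or 'none'}")
        return "\n".join(lines)


class ExposureCoxModel:
    """Cox proportional-hazards model of one exposure metric per SD.

    Rows must be single-sex (men and women are analysed separately; WC
    thresholds and SDs are sex-specific).  The exposure is z-scored within
    the supplied rows; covariates follow the adjustment tier.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        exposure: str = "wc_years",
        adjustment: str = "multivariable",
        outcome_label: str = "all",
        extra_covariates: tuple[str, ...] = (),
        adjust_baseline_wc: bool | None = None,
        strata: tuple[str, ...] = (),
        time_varying: tuple[str, ...] = (),
        allow_mixed_sex: bool = False,
    ):
        if exposure not in rows.columns:
            raise ValueError(f"exposure {exposure!r} not in rows")
        if adjustment not in ("age_only", "multivariable", "unadjusted"):
            raise ValueError("adjustment must be age_only, multivariable or unadjusted")
        sexes = rows["sex"].unique() if "sex" in rows.columns else ["?"]
        if len(sexes) > 1 and not allow_mixed_sex:
            raise ValueError(
                "rows contain both sexes; per-SD models are sex-stratified by "
                "design (pass allow_mixed_sex=True to override)"
            )
        if int(rows["event"].sum()) < 2:
            raise ValueError("need at least 2 events to fit a Cox model")
        self.rows = rows.reset_index(drop=True)
        self.exposure = exposure
        self.adjustment = adjustment
        self.outcome_label = outcome_label
        if adjust_baseline_wc is None:
            adjust_baseline_wc = (
                exposure in ("cum_degree", "cum_duration")
                and adjustment == "multivariable"
            )
        self.adjust_baseline_wc = adjust_baseline_wc
        self.extra_covariates = tuple(extra_covariates)
        self.strata = tuple(strata)
        self.time_varying = tuple(time_varying)
        covs: list[str] = []
        if adjustment in ("age_only", "multivariable"):
            covs.append("baseline_age")
        if adjustment == "multivariable":
            covs += [c for c in _MULTIVARIABLE_SET if c != "baseline_age"]
            if (self.rows.get("sex") == "female").all() and "hrt_ever" in self.rows:
                covs.append("hrt_ever")
            if self.adjust_baseline_wc:
                covs.append("baseline_wc")
        covs += [c for c in self.extra_covariates if c not in covs]
        self.covariates = tuple(covs)
        missing_cells = (
            self.design_frame(self.rows).drop(columns=["time", "event"]).isna()
        )
        if missing_cells.any().any():
            bad = missing_cells.any()
            raise ValueError(
                f"missing covariate cells in {list(bad[bad].index)}; impute first"
            )

    def design_frame(self, rows: pd.DataFrame) -> pd.DataFrame:
        """time, event, z-scored exposure and covariates for given rows."""
        z, sd = standardize_per_sd(rows[self.exposure].to_numpy())
        df = pd.DataFrame(
            {"time": rows["time"].to_numpy(), "event": rows["event"].to_numpy()}
        )
        df[f"{self.exposure}_z"] = z
        for c in self.covariates:
            if c == "baseline_wc":
                df[c] = rows["single_wc"].to_numpy()
            else:
                df[c] = rows[c].to_numpy()
        for s in self.strata:
            df[s] = rows[s].to_numpy()
        self._last_sd = sd
        return df

    def fit(self) -> ExposureCoxResults:
        df = self.design_frame(self.rows)
        term = f"{self.exposure}_z"
        if self.time_varying:
            fitter, params, se_map = self._fit_time_varying(df)
        else:
            fitter = CoxPHFitter()
            fitter.fit(
                df,
                duration_col="time",
                event_col="event",
                strata=list(self.strata) or None,
            )
            params = fitter.params_
            se_map = fitter.standard_errors_
        return ExposureCoxResults(
            exposure=self.exposure,
            adjustment=self.adjustment,
            outcome_label=self.outcome_label,
            log_hr_per_sd=float(params[term]),
            se=float(se_map[term]),
            n_events=int(df["event"].sum()),
            sd_used=float(self._last_sd),
            aic=float(getattr(fitter, "AIC_partial_", np.nan)),
            covariates=self.covariates,
            strata=self.strata,
            time_varying_terms=self.time_varying,
            _fitter=fitter,
            _df=df,
            _model=self,
        )

    def _fit_time_varying(self, df: pd.DataFrame, n_cuts: int = 40):
        """Episode-split fit with coefficient × log(time) interactions.

        Continuous PH violators get an extra covariate x·log(t) evaluated
        at the start of each split interval (step approximation on ~40
        event-time quantile cuts).
        """
        event_times = np.sort(df.loc[df["event"] == 1, "time"].unique())
        if event_times.size > n_cuts:
            cuts = np.unique(np.quantile(event_times, np.linspace(0, 1, n_cuts + 1)[1:-1]))
        else:
            cuts = event_times[:-1]
        base = df.reset_index().rename(columns={"index": "id"})
        frames = []
        starts = np.concatenate([[0.0], cuts])
        stops = np.concatenate([cuts, [np.inf]])
        for lo, hi in zip(starts, stops):
            seg = base[base["time"] > lo].copy()
            seg["start"] = lo
            seg["stop"] = np.minimum(seg["time"], hi)
            seg["ev"] = ((seg["time"] <= hi) & (seg["event"] == 1)).astype(int)
            logt = np.log(np.maximum(lo, 1e-8)) if lo > 0 else np.log(
                np.maximum(seg["stop"].to_numpy() / 2.0, 1e-8)
            )
            for v in self.time_varying:
                seg[f"{v}_xlogt"] = seg[v] * logt
            frames.append(seg)
        long = pd.concat(frames, ignore_index=True).drop(columns=["time", "event"])
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            long,
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="ev",
            strata=list(self.strata) or None,
        )
        return ctv, ctv.params_, ctv.standard_errors_


def fit_cox_per_sd(
    rows: pd.DataFrame,
    exposure: str = "wc_years",
    adjustment: str = "multivariable",
    outcome_label: str = "all",
    **kwargs,
) -> ExposureCoxResults:
    """Convenience wrapper: build an :class:`ExposureCoxModel` and fit it."""
    return ExposureCoxModel(
        rows, exposure=exposure, adjustment=adjustment, outcome_label=outcome_label, **kwargs
    ).fit()


def fit_cox_pooled(
    rows: pd.DataFrame,
    imputations: ImputationSet,
    exposure: str = "wc_years",
    adjustment: str = "multivariable",
    outcome_label: str = "all",
    **kwargs,
) -> tuple[PooledEstimate, list[ExposureCoxResults]]:
    """Fit the per-SD Cox model on each completed dataset and pool.

    ``imputations`` carries completed covariate tables indexed like
    ``rows``; covariate columns in ``rows`` are replaced per dataset.
    Pooling is on the log-HR scale (Rubin's rules); exponentiate the
    pooled estimate and CI bounds for reporting.
    """
    fits = []
    for completed in imputations.datasets:
        r = rows.copy()
        for c in completed.columns:
            if c in r.columns and c in imputations.imputed_columns:
                r[c] = completed[c].to_numpy()
        fits.append(
            fit_cox_per_sd(
                r, exposure=exposure, adjustment=adjustment,
                outcome_label=outcome_label, **kwargs,
            )
        )
    pooled = pool_rubin(
        np.array([f.log_hr_per_sd for f in fits]),
        np.array([f.se**2 for f in fits]),
    )
    return pooled, fits


def check_ph_and_remediate(
    results: ExposureCoxResults, alpha: float = 0.05
) -> ExposureCoxResults:
    """Schoenfeld-residual PH test per covariate, with remediation refit.

    Categorical violators move to strata; continuous violators get a
    coefficient × log(time) interaction; the model is refitted once and
    re-tested.  A persistent violation on the exposure itself is flagged
    (``ph_flag_exposure``), never silently accepted.
    """
    if results.time_varying_terms:
        raise ValueError("results already contain time-varying terms")
    fitter, df = results._fitter, results._df
    test = proportional_hazard_test(fitter, df, time_transform="log")
    diag = test.summary.reset_index().rename(columns={"index": "variable"})
    diag["violates"] = diag["p"] < alpha
    term = f"{results.exposure}_z"
    new_strata = list(results.strata)
    new_tv = []
    for _, r in diag.iterrows():
        var = r["variable"]
        if not r["violates"] or var == term:
            continue
        if var in _CATEGORICAL_COVS:
            new_strata.append(var)
        else:
            new_tv.append(var)
    diag["action"] = [
        ("stratify" if v in new_strata else "x_logt" if v in new_tv else "none")
        for v in diag["variable"]
    ]
    if not (new_strata != list(results.strata) or new_tv):
        out = replace(results)
        out.ph_diagnostics = diag
        out.ph_flag_exposure = bool(
            diag.loc[diag["variable"] == term, "violates"].any()
        )
        return out
    model = results._model
    refit_model = ExposureCoxModel(
        model.rows,
        exposure=model.exposure,
        adjustment=model.adjustment,
        outcome_label=model.outcome_label,
        extra_covariates=tuple(
            c for c in model.extra_covariates if c not in new_strata
        ),
        adjust_baseline_wc=model.adjust_baseline_wc,
        strata=tuple(new_strata),
        time_varying=tuple(new_tv),
        allow_mixed_sex=True,
    )
    # stratification removes the variable from the regression covariates
    refit_model.covariates = tuple(
        c for c in refit_model.covariates if c not in new_strata
    )
    out = refit_model.fit()
    if not new_tv:
        test2 = proportional_hazard_test(out._fitter, out._df, time_transform="log")
        out.ph_flag_exposure = bool(test2.summary.loc[term, "p"] < alpha)
    out.ph_diagnostics = diag
    return out


def incidence_rates(
    rows: pd.DataFrame,
    category_col: str = "wc_years_category",
    by: str | None = None,
) -> pd.DataFrame:
    """Events per 1000 person-years by wc-years category (0 / 1-100 / >100).

    Optionally stratified by a covariate (race, smoking, HRT).  An empty
    category is reported with 0 person-years and an undefined (NaN) rate.
    """
    from .metrics import WC_YEARS_CATEGORIES

    keys = [category_col] + ([by] if by else [])
    grouped = rows.groupby(keys, dropna=False)
    tab = grouped.agg(events=("event", "sum"), person_years=("time", "sum")).reset_index()
    if by is None:
        full = pd.DataFrame({category_col: list(WC_YEARS_CATEGORIES)})
        tab = full.merge(tab, on=category_col, how="left").fillna(
            {"events": 0, "person_years": 0.0}
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["rate_per_1000py"] = np.where(
            tab["person_years"] > 0,
            1000.0 * tab["events"] / tab["person_years"],
            np.nan,
        )
    tab["events"] = tab["events"].astype(int)
    return tab


def site_eligibility(n_events: int, n_candidate_params: int) -> bool:
    """Events-per-parameter screen: at least 10 events per candidate
    predictor parameter."""
    if n_events < 0 or n_candidate_params < 0:
        raise ValueError("counts must be non-negative")
    return n_events >= 10 * n_candidate_params
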