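"""End-to-end analysis pipeline.

simulate (or load) → fit WC trajectories → predict yearly WC → compute
exposure metrics → multiply impute missing covariates → landmarked per-SD
Cox models with PH remediation and Rubin pooling → incidence rates →
optimism-corrected discrimination comparison → report CSVs + manifest.

Men and women are analysed separately throughout (thresholds and SDs are
sex-specific); only the trajectory model pools sexes, by design, via its
sex-interaction terms.  Every random draw is attributable to the single
config seed recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrimination import ModelSpec, compare_c, optimism_corrected_c
from .impute import impute_chained
from .metrics import ThresholdSpec, exposure_table
from .simulate import Cohort, SimConfig, generate_cohort, inject_missingness
from .survival import (
    assemble_landmark_dataset,
    check_ph_and_remediate,
    fit_cox_per_sd,
    fit_cox_pooled,
    incidence_rates,
    site_eligibility,
)
from .trajectory import WCTrajectoryModel

log = logging.getLogger("wcyears")

_IMPUTABLE = ("smoking_ever", "alcohol", "education", "hrt_ever")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """One config object drives a full reproducible run."""

    sim: SimConfig | None = None
    input_paths: dict[str, str] | None = None  # visits/covariates/followup CSVs
    threshold_label: str = "standard"
    inclusion_min_wc_measures: int = 2
    grid_rule: str = "cohort_min_age"
    m_imputations: int = 10
    mice_cycles: int = 10
    n_bootstrap: int = 100
    adjustments: tuple[str, ...] = ("age_only", "multivariable")
    outcome_defs: tuple = ("all", "obesity_related", "non_obesity_related")
    exposures: tuple[str, ...] = ("wc_years", "single_wc", "single_bmi",
                                  "cum_degree", "cum_duration")
    discrimination_outcome: str = "all"
    seed: int = 0
    outdir: str = "wcyears_run"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("exactly one of sim / input_paths must be given")
        for name in ("inclusion_min_wc_measures", "m_imputations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.threshold_label not in ("standard", "lower"):
            raise ValueError("threshold_label must be 'standard' or 'lower'")

    @property
    def thresholds(self) -> ThresholdSpec:
        return ThresholdSpec() if self.threshold_label == "standard" else ThresholdSpec.lower()


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_cohort(paths: dict[str, str]) -> Cohort:
    """Load the three analysis-facing CSVs (no truth block)."""
    need = {"visits", "covariates", "followup"}
    if set(paths) < need:
        raise ValueError(f"input_paths must contain {sorted(need)}")
    return Cohort(
        visits=pd.read_csv(paths["visits"]),
        covariates=pd.read_csv(paths["covariates"]),
        followup=pd.read_csv(paths["followup"]),
        truth=None,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report bundle and writes CSVs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "simulate"
    try:
        if config.sim is not None:
            cohort = generate_cohort(config.sim)
            cohort = inject_missingness(cohort, config.sim)
            cohort.write_csvs(outdir / "cohort")
        else:
            cohort = load_cohort(config.input_paths)
        bundle["cohort"] = cohort

        stage = "trajectories"
        model = WCTrajectoryModel(cohort.visits)
        fit = model.fit()
        yearly = fit.predict_yearly_all(grid_rule=config.grid_rule)
        yearly.to_csv(outdir / "yearly_wc.csv", index=False)
        bundle["trajectory_fit"] = fit
        bundle["yearly"] = yearly

        stage = "metrics"
        base_ix = cohort.visits.groupby("participant_id")["visit_index"].transform("max")
        baseline = cohort.visits[cohort.visits["visit_index"] == base_ix]
        exposures = exposure_table(yearly, baseline, config.thresholds)
        exposures.to_csv(outdir / "exposures.csv", index=False)
        bundle["exposures"] = exposures

        stage = "impute"
        imputations = {}
        rows_by = {}
        first_def = config.outcome_defs[0]
        for sex in ("male", "female"):
            rows = assemble_landmark_dataset(
                cohort, exposures, first_def,
                min_wc_measures=config.inclusion_min_wc_measures,
            )
            rows = rows[rows["sex"] == sex].reset_index(drop=True)
            rows_by[sex] = rows
            imp_cols = [
                c for c in _IMPUTABLE
                if c in rows.columns and not (sex == "male" and c == "hrt_ever")
            ]
            tab = rows[["baseline_age", "race_black", *imp_cols]].copy()
            tab["event"] = rows["event"]
            tab["log_time"] = np.log(rows["time"])
            needs = tab[imp_cols].isna().any().any()
            m = config.m_imputations if needs else 2
            imputations[sex] = impute_chained(
                tab, m=m, cycles=config.mice_cycles,
                seed=config.seed + (11 if sex == "male" else 23),
            )

        stage = "survival"
        hr_rows = []
        for sex in ("male", "female"):
            for outcome_def in config.outcome_defs:
                rows = assemble_landmark_dataset(
                    cohort, exposures, outcome_def,
                    min_wc_measures=config.inclusion_min_wc_measures,
                )
                rows = rows[rows["sex"] == sex].reset_index(drop=True)
                label = outcome_def if isinstance(outcome_def, str) else outcome_def[1]
                n_events = int(rows["event"].sum())
                eligible = site_eligibility(n_events, 6)
                for exposure in config.exposures:
                    for adjustment in config.adjustments:
                        if n_events < 2:
                            continue
                        pooled, fits = fit_cox_pooled(
                            rows, imputations[sex], exposure=exposure,
                            adjustment=adjustment, outcome_label=label,
                        )
                        first = check_ph_and_remediate(fits[0])
                        hr_rows.append(
                            {
                                "sex": sex,
                                "outcome": label,
                                "exposure": exposure,
                                "adjustment": adjustment,
                                "hr_per_sd": float(np.exp(pooled.estimate)),
                                "ci_low": float(np.exp(pooled.ci[0])),
                                "ci_high": float(np.exp(pooled.ci[1])),
                                "n_events": n_events,
                                "epp_eligible": eligible,
                                "ph_violations": ";".join(
                                    first.ph_diagnostics.query("violates")["variable"]
                                )
                                if first.ph_diagnostics is not None
                                else "",
                            }
                        )
        hr_table = pd.DataFrame(hr_rows)
        hr_table.to_csv(outdir / "hazard_ratios.csv", index=False)
        bundle["hazard_ratios"] = hr_table

        stage = "incidence"
        rate_tabs = []
        for sex in ("male", "female"):
            rows = assemble_landmark_dataset(
                cohort, exposures, "all",
                min_wc_measures=config.inclusion_min_wc_measures,
            )
            rows = rows[rows["sex"] == sex]
            tab = incidence_rates(rows)
            tab.insert(0, "sex", sex)
            rate_tabs.append(tab)
        rates = pd.concat(rate_tabs, ignore_index=True)
        rates.to_csv(outdir / "incidence_rates.csv", index=False)
        bundle["incidence_rates"] = rates

        stage = "discriminate"
        cstat_rows = []
        delta_rows = []
        for sex in ("male", "female"):
            rows = assemble_landmark_dataset(
                cohort, exposures, config.discrimination_outcome,
                min_wc_measures=config.inclusion_min_wc_measures,
            )
            rows = rows[rows["sex"] == sex].reset_index(drop=True)
            # complete-case covariates for discrimination (or first imputation)
            comp = imputations[sex].datasets[0]
            for c in imputations[sex].imputed_columns:
                if c in rows.columns:
                    rows[c] = comp[c].to_numpy()
            spec_ref = ModelSpec("wc_years")
            res_ref = optimism_corrected_c(
                rows, spec_ref, config.n_bootstrap, seed=config.seed
            )
            cstat_rows.append(
                {"sex": sex, "metric": "wc_years", **_cstat_dict(res_ref)}
            )
            for other in config.exposures:
                if other == "wc_years":
                    continue
                cmp = compare_c(
                    rows, spec_ref, ModelSpec(other),
                    n_bootstrap=config.n_bootstrap, seed=config.seed,
                )
                cstat_rows.append(
                    {"sex": sex, "metric": other, **_cstat_dict(cmp.result_b)}
                )
                delta_rows.append(
                    {
                        "sex": sex,
                        "metric_a": "wc_years",
                        "metric_b": other,
                        "delta_c": cmp.delta_c,
                        "ci_low": cmp.ci[0],
                        "ci_high": cmp.ci[1],
                        "direction": cmp.direction,
                    }
                )
        cstats = pd.DataFrame(cstat_rows)
        deltas = pd.DataFrame(delta_rows)
        cstats.to_csv(outdir / "cstatistics.csv", index=False)
        deltas.to_csv(outdir / "cstatistic_differences.csv", index=False)
        bundle["cstatistics"] = cstats
        bundle["cstatistic_differences"] = deltas

        stage = "report"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "threshold_label": config.threshold_label,
            "inclusion_min_wc_measures": config.inclusion_min_wc_measures,
            "grid_rule": config.grid_rule,
            "m_imputations": config.m_imputations,
            "n_bootstrap": config.n_bootstrap,
            "n_rows": {s: int(len(rows_by[s])) for s in rows_by},
            "outputs": [
                "yearly_wc.csv", "exposures.csv", "hazard_ratios.csv",
                "incidence_rates.csv", "cstatistics.csv",
                "cstatistic_differences.csv",
            ],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle["manifest"] = manifest
        return bundle
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _cstat_dict(res) -> dict:
    return {
        "c_apparent": res.c_apparent,
        "optimism": res.optimism,
        "c_corrected": res.c_corrected,
        "ci_low": res.ci[0],
        "ci_high": res.ci[1],
    }
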