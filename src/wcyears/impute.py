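"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing baseline covariates (assumed missing at random) are completed m
times (default 10) with chained equations; downstream estimates fitted on
each completed dataset are pooled with Rubin's rules on a scale where
Gaussian pooling is defensible — log hazard ratios, never hazard ratios;
C-statistics on the raw scale.

The chained-equation engine is statsmodels' ``MICEData``, which imputes
every variable by predictive mean matching (PMM) against a Gaussian
working model: imputed values are drawn from observed donors, so binary
and ordinal variables keep their support without separate logistic
sub-models.  One chain is run per imputation set with a fixed number of
burn cycles between saved datasets (thinning), which is the conventional
single-chain practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData


@dataclass
class ImputationSet:
    """m completed covariate tables plus the provenance needed to rerun."""

    m: int
    datasets: list[pd.DataFrame]
    seed: int
    imputed_columns: tuple[str, ...]
    cycles: int = 10

    def __post_init__(self) -> None:
        if self.m != len(self.datasets):
            raise ValueError("m must equal the number of completed datasets")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled point estimate with its variance partition."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]
    m: int


def impute_chained(
    covariates: pd.DataFrame,
    m: int = 10,
    cycles: int = 10,
    seed: int = 0,
    predictors: dict[str, list[str]] | None = None,
) -> ImputationSet:
    """Complete a covariate table m times by chained equations (PMM).

    Parameters
    ----------
    covariates : DataFrame
        Numeric table; NaN cells are imputed.  Include the outcome
        indicator and (transformed) follow-up time as columns so the
        imputation model conditions on them, per standard MI practice for
        survival outcomes.  Columns that should not be touched (ids)
        must be excluded by the caller.
    predictors : dict, optional
        Optional predictor matrix: maps an imputed variable to the list
        of columns allowed to predict it.  Default: all other columns.

    Raises on a variable that is 100% missing (no observed anchor).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df = covariates.copy()
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(
            f"impute_chained requires numeric columns; encode {non_numeric}"
        )
    has_missing = [c for c in df.columns if df[c].isna().any()]
    for c in has_missing:
        if df[c].isna().all():
            raise ValueError(f"variable {c!r} is 100% missing; nothing to anchor on")
    if not has_missing:
        return ImputationSet(
            m=m,
            datasets=[df.copy() for _ in range(m)],
            seed=seed,
            imputed_columns=(),
            cycles=cycles,
        )
    # MICEData draws from the numpy global state; scope a seeded state
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31 - 1))
        md = MICEData(df.astype(float))
        if predictors:
            for var, preds in predictors.items():
                unknown = set(preds) - set(df.columns)
                if unknown:
                    raise ValueError(f"unknown predictors for {var!r}: {unknown}")
                md.set_imputer(var, formula=" + ".join(preds))
        datasets = []
        for _ in range(m):
            md.update_all(cycles)
            snap = md.data.copy()
            snap.index = df.index
            datasets.append(snap)
    finally:
        np.random.set_state(state)
    # imputation must not disturb observed cells
    for snap in datasets:
        obs = ~df.isna()
        if not snap.where(obs).equals(df.astype(float).where(obs)):
            raise AssertionError("observed cells changed during imputation")
    return ImputationSet(
        m=m,
        datasets=datasets,
        seed=seed,
        imputed_columns=tuple(has_missing),
        cycles=cycles,
    )


def pool_rubin(
    estimates: np.ndarray, variances: np.ndarray, alpha: float = 0.05
) -> PooledEstimate:
    """Pool per-dataset estimates and squared SEs by Rubin's rules.

    pooled   = mean(estimates)
    within   = mean(variances)
    between  = sample variance of estimates (ddof=1)
    total    = within + (1 + 1/m) · between
    df       = (m − 1) · (1 + within / ((1 + 1/m) · between))²
    CI       = pooled ± t_{df, 1−α/2} · √total   (Wald on the pooling scale)
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape:
        raise ValueError("estimates and variances must be 1-d and equal length")
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 estimates")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    pooled = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    else:
        df = np.inf
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    half = float(tcrit) * np.sqrt(total)
    return PooledEstimate(
        estimate=pooled,
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        ci=(pooled - half, pooled + half),
        m=m,
    )
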