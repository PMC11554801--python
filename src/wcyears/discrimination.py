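"""Discrimination of exposure metrics: Harrell's C with optimism correction.

For each metric's Cox model the concordance (Harrell's C) of the model
linear predictor is computed, then corrected for in-sample optimism with
the Harrell bootstrap: refit on each resample, take (C on the resample −
C of that refit evaluated on the original data), average, and subtract
from the apparent C.  Metrics are compared with a *paired* bootstrap —
both models are refitted on the same resamples — so the confidence
interval on the C difference reflects the correlation between the two
models' performance.

Tie conventions (the standard Harrell rules): a pair is usable when the
member with the shorter time has the event; tied times with both events
are not comparable; tied times with exactly one event compare the event
member as the earlier; tied risk scores count 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.exceptions import ConvergenceError as _LLConvergence
from lifelines.utils import concordance_index

from .survival import ExposureCoxModel, ExposureCoxResults


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance for right-censored data.

    Proportion of usable pairs in which the member with the earlier event
    carries the higher risk score; tied scores count 1/2.  0.5 means no
    discrimination.  Raises if there are no usable pairs.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    s = np.asarray(risk_scores, dtype=float)
    if not (t.shape == e.shape == s.shape) or t.ndim != 1:
        raise ValueError("times, events and risk_scores must be equal-length 1-d")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be binary 0/1")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite times or risk scores")
    if e.sum() == 0:
        raise ValueError("no events: no usable pairs")
    # higher risk => shorter survival, so concordance uses the negated score
    try:
        return float(concordance_index(t, -s, e.astype(int)))
    except ZeroDivisionError as exc:  # pragma: no cover - tiny degenerate inputs
        raise ValueError("no usable pairs") from exc


@dataclass(frozen=True)
class ModelSpec:
    """What to fit on each (re)sample: an exposure and its adjustment."""

    exposure: str
    adjustment: str = "multivariable"
    extra_covariates: tuple[str, ...] = ()
    adjust_baseline_wc: bool | None = None

    def fit(self, rows: pd.DataFrame, outcome_label: str = "c-stat") -> ExposureCoxResults:
        return ExposureCoxModel(
            rows,
            exposure=self.exposure,
            adjustment=self.adjustment,
            outcome_label=outcome_label,
            extra_covariates=self.extra_covariates,
            adjust_baseline_wc=self.adjust_baseline_wc,
        ).fit()


@dataclass
class CStatResult:
    metric_label: str
    c_apparent: float
    optimism: float
    c_corrected: float
    ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    n_redraws: int = 0
    corrected_draws: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"Harrell C [{self.metric_label}]: corrected {self.c_corrected:.3f} "
            f"(95% CI {lo:.3f}, {hi:.3f}); apparent {self.c_apparent:.3f}, "
            f"optimism {self.optimism:.4f} from {self.n_bootstrap} bootstraps"
        )


@dataclass
class CComparison:
    metric_a: str
    metric_b: str
    delta_c: float
    ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    result_a: CStatResult | None = None
    result_b: CStatResult | None = None

    @property
    def direction(self) -> str:
        lo, hi = self.ci
        if lo > 0:
            return f"{self.metric_b} > {self.metric_a}"
        if hi < 0:
            return f"{self.metric_a} > {self.metric_b}"
        return "no clear difference"

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"ΔC ({self.metric_b} − {self.metric_a}) = {self.delta_c:+.4f} "
            f"(95% CI {lo:+.4f}, {hi:+.4f}) — {self.direction}"
        )


def _bootstrap_indices(rng: np.random.Generator, n: int, n_bootstrap: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_bootstrap, n))


def _optimism_draws(
    rows: pd.DataFrame,
    spec: ModelSpec,
    indices: np.ndarray,
    rng: np.random.Generator,
    max_redraw_factor: int = 10,
):
    """Per-resample (c_boot, c_orig) pairs; redraw on refit failure."""
    t = rows["time"].to_numpy()
    e = rows["event"].to_numpy()
    n = len(rows)
    c_boot = np.empty(len(indices))
    c_orig = np.empty(len(indices))
    redraws = 0
    cap = max_redraw_factor * len(indices)
    for b in range(len(indices)):
        idx = indices[b]
        while True:
            sub = rows.iloc[idx].reset_index(drop=True)
            try:
                fit_b = spec.fit(sub)
                c_boot[b] = harrell_c(
                    sub["time"], sub["event"], fit_b.linear_predictor(sub)
                )
                c_orig[b] = harrell_c(t, e, fit_b.linear_predictor(rows))
                break
            except (_LLConvergence, ValueError, np.linalg.LinAlgError):
                redraws += 1
                if redraws > cap:
                    raise RuntimeError(
                        "bootstrap refits failed more than "
                        f"{max_redraw_factor}x the bootstrap count"
                    )
                idx = rng.integers(0, n, size=n)
    return c_boot, c_orig, redraws


def optimism_corrected_c(
    rows: pd.DataFrame,
    spec: ModelSpec,
    n_bootstrap: int = 100,
    seed: int = 0,
    _indices: np.ndarray | None = None,
    _rng: np.random.Generator | None = None,
) -> CStatResult:
    """Harrell optimism-bootstrap-corrected C for one model spec.

    optimism_b = C(refit_b on resample_b) − C(refit_b on original data);
    corrected = apparent − mean(optimism).  The CI is the percentile
    interval of the per-resample corrected values (apparent − optimism_b).
    Deterministic under ``seed``.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    full = spec.fit(rows)
    c_apparent = harrell_c(rows["time"], rows["event"], full.linear_predictor(rows))
    indices = (
        _indices
        if _indices is not None
        else _bootstrap_indices(rng, len(rows), n_bootstrap)
    )
    c_boot, c_orig, redraws = _optimism_draws(rows, spec, indices, rng)
    optimism = float(np.mean(c_boot - c_orig))
    corrected_draws = c_apparent - (c_boot - c_orig)
    ci = tuple(np.percentile(corrected_draws, [2.5, 97.5]))
    return CStatResult(
        metric_label=spec.exposure,
        c_apparent=float(c_apparent),
        optimism=optimism,
        c_corrected=float(c_apparent - optimism),
        ci=(float(ci[0]), float(ci[1])),
        n_bootstrap=len(indices),
        seed=seed,
        n_redraws=redraws,
        corrected_draws=corrected_draws,
    )


def compare_c(
    rows: pd.DataFrame,
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> CComparison:
    """Paired-bootstrap comparison of two metrics' corrected C.

    Both models are refitted on the *same* resamples (paired design);
    delta_b is the per-resample difference of corrected C draws, the CI
    its percentile interval, and the point estimate the difference of the
    full-data corrected C values.  Antisymmetric under swapping a and b.
    """
    rng = np.random.default_rng(seed)
    indices = _bootstrap_indices(rng, len(rows), n_bootstrap)
    res_a = optimism_corrected_c(
        rows, spec_a, n_bootstrap, seed, _indices=indices, _rng=rng
    )
    res_b = optimism_corrected_c(
        rows, spec_b, n_bootstrap, seed, _indices=indices, _rng=rng
    )
    # per-resample corrected draws come from identical resamples, so the
    # paired delta distribution reflects the models' correlation
    delta_draws = res_b.corrected_draws - res_a.corrected_draws
    ci = np.percentile(delta_draws, [2.5, 97.5])
    return CComparison(
        metric_a=spec_a.exposure,
        metric_b=spec_b.exposure,
        delta_c=float(res_b.c_corrected - res_a.c_corrected),
        ci=(float(ci[0]), float(ci[1])),
        n_bootstrap=n_bootstrap,
        seed=seed,
        result_a=res_a,
        result_b=res_b,
    )
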