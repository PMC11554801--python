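"""Mixed-effects waist-circumference trajectory model.

Sparse exam data (typically four visits per participant at three-year
intervals) are fitted with a linear mixed-effects model:

    WC_ij = beta' x(age_ij, sex_i) + b0_i + b1_i (age_ij − c) + e_ij

with fixed effects comprising a sex-specific intercept, a sex × linear-age
interaction and a natural cubic spline on age whose curvature is shared
across sexes (the smallest structure consistent with sex-specific WC
levels and trends plus a smooth common age shape); random intercept and
slope per participant (unstructured 2×2 covariance); iid residual.
Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Per-participant BLUPs individualise the population curve, and
:meth:`WCTrajectoryResults.predict_yearly` evaluates the conditional mean
on an integer-age grid from the cohort minimum entry age (or the
participant's own entry age) up to the landmark exam — the yearly WC
series from which the cumulative exposure metrics are built.  Backward
extrapolation below a participant's first exam rides on the BLUP line,
which is why the spline is constrained to be linear outside its boundary
knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import SplineSpec, natural_cubic_basis

REQUIRED_COLUMNS = ("participant_id", "sex", "visit_index", "age_at_exam", "wc")


class ConvergenceError(RuntimeError):
    """Mixed-model optimisation failed; carries the optimiser state."""

    def __init__(self, message: str, state: object = None):
        super().__init__(message)
        self.state = state


class SingularDesignError(ValueError):
    """Fixed-effect design is rank-deficient (e.g. single-sex data with a
    sex interaction requested)."""


class WCTrajectoryModel:
    """Linear mixed-effects model for WC as a function of age and sex.

    Parameters
    ----------
    visits : DataFrame
        Long-format exam table with columns ``participant_id, sex,
        visit_index, age_at_exam, wc`` (``bmi`` optional).  Rows with
        missing WC are dropped; WC outside ``wc_window`` is treated as an
        implausible reading and also dropped.
    spline_spec : SplineSpec, optional
        Knot layout for the age spline.  Default: three interior knots at
        the 10/50/90% age quantiles, boundary knots at the observed range.
    sex_interaction : bool
        Include sex-specific intercept and sex × linear-age term.  Must be
        disabled for single-sex data.
    age_center : float
        Centring constant for the random-slope covariate (years).
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        spline_spec: SplineSpec | None = None,
        sex_interaction: bool = True,
        age_center: float = 60.0,
        wc_window: tuple[float, float] = (40.0, 200.0),
    ):
        missing = [c for c in REQUIRED_COLUMNS if c not in visits.columns]
        if missing:
            raise ValueError(f"visits table missing columns: {missing}")
        df = visits.copy()
        df = df[np.isfinite(df["wc"].astype(float))]
        lo, hi = wc_window
        df = df[(df["wc"] >= lo) & (df["wc"] <= hi)]
        if df["participant_id"].nunique() < 2:
            raise ValueError("need at least 2 participants with observed WC")
        # ages must strictly increase with visit index within participant
        chk = df.sort_values(["participant_id", "visit_index"])
        diffs = chk.groupby("participant_id")["age_at_exam"].diff().dropna()
        if (diffs <= 0).any():
            bad = chk.loc[diffs.index[diffs <= 0], "participant_id"].unique()
            raise ValueError(
                f"age must strictly increase with visit_index; offending "
                f"participants: {list(bad[:5])}"
            )
        sexes = set(df["sex"].unique())
        if not sexes <= {"male", "female"}:
            raise ValueError(f"unknown sex values {sexes - {'male', 'female'}}")
        if sex_interaction and len(sexes) < 2:
            raise SingularDesignError(
                "sex interaction requested but the data contain a single sex; "
                "refit with sex_interaction=False"
            )
        self.data = df.reset_index(drop=True)
        self.sex_interaction = sex_interaction
        self.age_center = float(age_center)
        self.spline_spec = spline_spec or SplineSpec.from_quantiles(
            self.data["age_at_exam"].to_numpy()
        )
        self._exog, self._names = self._design(
            self.data["age_at_exam"].to_numpy(), self.data["sex"].to_numpy()
        )
        rank = np.linalg.matrix_rank(self._exog)
        if rank < self._exog.shape[1]:
            raise SingularDesignError(
                f"fixed-effect design is rank deficient (rank {rank} < "
                f"{self._exog.shape[1]} columns)"
            )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "WCTrajectoryModel":
        return cls(pd.read_csv(path), **kwargs)

    def _design(self, ages: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, list[str]]:
        ages = np.asarray(ages, dtype=float)
        basis = natural_cubic_basis(ages, self.spline_spec)
        cols = [np.ones_like(ages)]
        names = ["intercept"]
        if self.sex_interaction:
            male = (np.asarray(sex) == "male").astype(float)
            cols += [male, male * (ages - self.age_center)]
            names += ["male", "male:age"]
        cols += [basis[:, j] for j in range(basis.shape[1])]
        names += [f"ns_age{j}" for j in range(basis.shape[1])]
        return np.column_stack(cols), names

    def fit(
        self,
        method: str = "lbfgs",
        maxiter: int = 500,
        reml: bool = True,
        start_params: np.ndarray | None = None,
    ) -> "WCTrajectoryResults":
        """REML fit; returns a results object with BLUPs.

        Degenerate noise-free data (exact fit on the population curve) are
        detected up front and returned as an exact generalised-least-squares
        solution with zero variance components, since the REML criterion is
        unbounded there.  Non-convergence raises :class:`ConvergenceError`
        carrying the optimiser state — never a silent result.
        """
        y = self.data["wc"].to_numpy(dtype=float)
        X = self._exog
        beta_ols, ssr, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(np.sum((y - X @ beta_ols) ** 2))
        if ssr <= max(1e-16, 1e-12 * float(np.sum(y**2))):
            blups = (
                self.data[["participant_id"]]
                .drop_duplicates()
                .assign(b0=0.0, b1=0.0)
                .reset_index(drop=True)
            )
            return WCTrajectoryResults(
                model=self,
                params=pd.Series(beta_ols, index=self._names),
                cov_re=pd.DataFrame(np.zeros((2, 2)), index=["b0", "b1"], columns=["b0", "b1"]),
                resid_var=0.0,
                blups=blups,
                converged=True,
                _sm_results=None,
            )

        groups = self.data["participant_id"].to_numpy()
        agec = self.data["age_at_exam"].to_numpy(dtype=float) - self.age_center
        # random slope on a decade scale: per-year slope variance is ~3
        # orders of magnitude below the intercept variance, which defeats
        # the optimiser; rescaling makes the components commensurate
        exog_re = np.column_stack([np.ones_like(agec), agec / 10.0])
        mod = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(
                method=method,
                maxiter=maxiter,
                reml=reml,
                start_params=start_params,
            )
        if not res.converged:
            raise ConvergenceError(
                "mixed-model optimisation did not converge", state=res
            )
        re = res.random_effects
        order = list(dict.fromkeys(groups))
        blups = pd.DataFrame(
            {
                "participant_id": order,
                "b0": [float(re[g].iloc[0]) for g in order],
                "b1": [float(re[g].iloc[1]) / 10.0 for g in order],
            }
        )
        scale_back = np.array([[1.0, 0.1], [0.1, 0.01]])
        cov_re = pd.DataFrame(
            np.asarray(res.cov_re) * scale_back, index=["b0", "b1"], columns=["b0", "b1"]
        )
        return WCTrajectoryResults(
            model=self,
            params=pd.Series(np.asarray(res.fe_params), index=self._names),
            cov_re=cov_re,
            resid_var=float(res.scale),
            blups=blups,
            converged=bool(res.converged),
            _sm_results=res,
        )


@dataclass
class WCTrajectoryResults:
    """Fitted trajectory model: fixed effects, variance components, BLUPs."""

    model: WCTrajectoryModel
    params: pd.Series
    cov_re: pd.DataFrame
    resid_var: float
    blups: pd.DataFrame
    converged: bool
    _sm_results: object = None

    def __post_init__(self) -> None:
        self._blup_ix = self.blups.set_index("participant_id")
        v = self.cov_re.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("random-effect covariance must be symmetric")
        if np.linalg.eigvalsh(v).min() < -1e-8:
            raise ValueError("random-effect covariance must be PSD")

    @property
    def random_intercept_sd(self) -> float:
        return float(np.sqrt(self.cov_re.iloc[0, 0]))

    @property
    def random_slope_sd(self) -> float:
        return float(np.sqrt(self.cov_re.iloc[1, 1]))

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.resid_var))

    def population_curve(self, ages: np.ndarray, sex: str) -> np.ndarray:
        """Fixed-effect WC curve for one sex, valid for any real age."""
        ages = np.asarray(ages, dtype=float)
        X, _ = self.model._design(ages, np.full(ages.shape, sex, dtype=object))
        return X @ self.params.to_numpy()

    def conditional_mean(self, participant_id, ages: np.ndarray) -> np.ndarray:
        """X beta + Z b for one participant at arbitrary (fractional) ages."""
        if participant_id not in self._blup_ix.index:
            raise KeyError(f"participant {participant_id!r} has no BLUPs")
        row = self._blup_ix.loc[participant_id]
        sex = self._participant_sex(participant_id)
        ages = np.asarray(ages, dtype=float)
        return (
            self.population_curve(ages, sex)
            + float(row["b0"])
            + float(row["b1"]) * (ages - self.model.age_center)
        )

    def _participant_sex(self, participant_id) -> str:
        sub = self.model.data.loc[
            self.model.data["participant_id"] == participant_id, "sex"
        ]
        if sub.empty:
            raise KeyError(f"participant {participant_id!r} not in fitting data")
        return str(sub.iloc[0])

    def predict_yearly(
        self,
        participant_id,
        baseline_age: float | None = None,
        grid_rule: str = "cohort_min_age",
    ) -> pd.DataFrame:
        """Predicted WC on an integer-age grid up to the landmark exam.

        ``grid_rule='cohort_min_age'`` starts the grid at the floor of the
        youngest exam age in the fitting data (matching yearly prediction
        "from the minimum age at Visit 1"); ``'participant_entry'`` starts
        at the participant's own first exam, avoiding backward
        extrapolation.  The grid is contiguous integers, closed at both
        ends, ending at floor(baseline age).
        """
        if grid_rule not in ("cohort_min_age", "participant_entry"):
            raise ValueError("grid_rule must be 'cohort_min_age' or 'participant_entry'")
        own_ages = self.model.data.loc[
            self.model.data["participant_id"] == participant_id, "age_at_exam"
        ]
        if own_ages.empty:
            raise KeyError(f"participant {participant_id!r} not in fitting data")
        if baseline_age is None:
            baseline_age = float(own_ages.max())
        if grid_rule == "cohort_min_age":
            start = int(np.floor(self.model.data["age_at_exam"].min()))
        else:
            start = int(np.floor(own_ages.min()))
        stop = int(np.floor(baseline_age))
        if stop < start:
            raise ValueError(
                f"baseline age {baseline_age} is below the grid start {start}"
            )
        grid = np.arange(start, stop + 1, dtype=float)
        wc_hat = self.conditional_mean(participant_id, grid)
        if not np.all(np.isfinite(wc_hat)):
            raise FloatingPointError("non-finite yearly predictions")
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "sex": self._participant_sex(participant_id),
                "age": grid.astype(int),
                "wc_hat": wc_hat,
            }
        )

    def predict_yearly_all(self, grid_rule: str = "cohort_min_age") -> pd.DataFrame:
        """Yearly predictions for every participant, as one tidy frame.

        Vectorised over the common integer grid: evaluates the two
        sex-specific fixed curves once and adds each participant's BLUP
        line, then truncates at floor(baseline age).
        """
        if grid_rule not in ("cohort_min_age", "participant_entry"):
            raise ValueError("grid_rule must be 'cohort_min_age' or 'participant_entry'")
        data = self.model.data
        per = data.groupby("participant_id").agg(
            sex=("sex", "first"),
            entry_age=("age_at_exam", "min"),
            baseline_age=("age_at_exam", "max"),
        )
        per = per.loc[self._blup_ix.index.intersection(per.index)]
        start_all = int(np.floor(data["age_at_exam"].min()))
        grid = np.arange(
            start_all, int(np.floor(per["baseline_age"].max())) + 1, dtype=float
        )
        curves = {
            s: self.population_curve(grid, s) for s in data["sex"].unique()
        }
        frames = []
        b0 = self._blup_ix["b0"].reindex(per.index).to_numpy()
        b1 = self._blup_ix["b1"].reindex(per.index).to_numpy()
        sexes = per["sex"].to_numpy()
        curve_mat = np.vstack([curves[s] for s in sexes])
        wc_mat = curve_mat + b0[:, None] + b1[:, None] * (grid[None, :] - self.model.age_center)
        lo = (
            np.floor(per["entry_age"]).to_numpy().astype(int)
            if grid_rule == "participant_entry"
            else np.full(len(per), start_all)
        )
        hi = np.floor(per["baseline_age"]).to_numpy().astype(int)
        keep = (grid[None, :] >= lo[:, None]) & (grid[None, :] <= hi[:, None])
        ii, jj = np.nonzero(keep)
        frames = pd.DataFrame(
            {
                "participant_id": per.index.to_numpy()[ii],
                "sex": sexes[ii],
                "age": grid[jj].astype(int),
                "wc_hat": wc_mat[ii, jj],
            }
        )
        if not np.all(np.isfinite(frames["wc_hat"])):
            raise FloatingPointError("non-finite yearly predictions")
        return frames

    def plot_participant(self, participant_id, ax=None):
        """Observed WC, fitted conditional mean and the yearly prediction
        grid for one participant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        sub = self.model.data[self.model.data["participant_id"] == participant_id]
        series = self.predict_yearly(participant_id)
        dense = np.linspace(series["age"].min(), sub["age_at_exam"].max(), 120)
        sex = self._participant_sex(participant_id)
        ax.plot(dense, self.population_curve(dense, sex), "--", color="0.6",
                label=f"population curve ({sex})")
        ax.plot(dense, self.conditional_mean(participant_id, dense),
                color="C0", label="individual trajectory")
        ax.plot(series["age"], series["wc_hat"], "s", ms=3, color="C0",
                alpha=0.6, label="yearly grid")
        ax.plot(sub["age_at_exam"], sub["wc"], "o", color="C3",
                label="observed exams")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("waist circumference (cm)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "WC trajectory model (linear mixed effects, REML)",
            f"  participants: {self.blups.shape[0]}   observations: {len(self.model.data)}",
            f"  spline knots: {self.model.spline_spec.knots} "
            f"boundary {self.model.spline_spec.boundary}",
            "  fixed effects:",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:>12s}  {val:10.4f}")
        lines += [
            f"  random intercept SD: {self.random_intercept_sd:8.3f} cm",
            f"  random slope SD:     {self.random_slope_sd:8.3f} cm/yr",
            f"  residual SD:         {self.residual_sd:8.3f} cm",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)
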