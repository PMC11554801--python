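import numpy as np
import pandas as pd
import pytest

import wcyears as w
from wcyears.splines import SplineSpec
from wcyears.trajectory import SingularDesignError, WCTrajectoryModel


def _toy_visits(n=80, seed=0, resid=2.0, ri=6.0, rs=0.2):
    cfg = w.SimConfig(
        n_participants=n, seed=seed,
        wc_model=w.WCModelParams(
            random_intercept_sd=ri, random_slope_sd=rs, residual_sd=resid
        ),
    )
    return w.generate_cohort(cfg).visits


class TestFit:
    def test_noise_free_fixed_effects_exact(self):
        """Data generated exactly on the population curve (all variance
        components zero) must be reproduced to machine precision."""
        wcm = w.WCModelParams(
            random_intercept_sd=0.0, random_slope_sd=0.0, residual_sd=0.0,
            intercept_slope_corr=0.0,
        )
        cfg = w.SimConfig(n_participants=60, seed=3, wc_model=wcm)
        visits = w.generate_cohort(cfg).visits
        fit = WCTrajectoryModel(
            visits, spline_spec=wcm.spline_spec
        ).fit()
        assert fit.converged
        assert fit.resid_var == 0.0
        # reconstruct the population curve from the fit at arbitrary ages
        ages = np.linspace(50, 66, 30)
        for sex in ("male", "female"):
            np.testing.assert_allclose(
                fit.population_curve(ages, sex),
                wcm.population_curve(ages, sex),
                rtol=1e-6,
            )

    def test_single_sex_with_interaction_is_singular(self):
        visits = _toy_visits(40)
        men = visits[visits["sex"] == "male"]
        with pytest.raises(SingularDesignError):
            WCTrajectoryModel(men)
        # but fits fine without the interaction
        fit = WCTrajectoryModel(men, sex_interaction=False).fit()
        assert fit.converged

    def test_requires_two_participants(self):
        visits = _toy_visits(40)
        one = visits[visits["participant_id"] == 0]
        with pytest.raises(ValueError):
            WCTrajectoryModel(one)

    def test_nonmonotone_ages_rejected(self):
        visits = _toy_visits(10).copy()
        visits.loc[visits.index[1], "age_at_exam"] = 20.0
        with pytest.raises(ValueError, match="strictly increase"):
            WCTrajectoryModel(visits)

    def test_implausible_wc_dropped(self):
        visits = _toy_visits(30).copy()
        visits.loc[visits.index[0], "wc"] = 250.0  # outside [40, 200]
        model = WCTrajectoryModel(visits)
        assert len(model.data) == len(visits) - 1

    def test_blups_present_for_every_participant(self):
        visits = _toy_visits(50)
        fit = WCTrajectoryModel(visits).fit()
        assert set(fit.blups["participant_id"]) == set(visits["participant_id"])
        v = fit.cov_re.to_numpy()
        assert np.all(np.linalg.eigvalsh(v) >= -1e-10)
        assert fit.resid_var > 0


@pytest.fixture(scope="module")
def fitted():
    visits = _toy_visits(300, seed=7)
    return visits, WCTrajectoryModel(visits).fit()


class TestPrediction:
    def test_conditional_mean_matches_matrix_oracle(self, fitted):
        """Prediction at observed ages equals X beta + Z b computed by an
        independent matrix formula."""
        visits, fit = fitted
        from wcyears.splines import natural_cubic_basis

        pid = visits["participant_id"].iloc[0]
        sub = visits[visits["participant_id"] == pid]
        ages = sub["age_at_exam"].to_numpy()
        sex = sub["sex"].iloc[0]
        male = 1.0 if sex == "male" else 0.0
        B = natural_cubic_basis(ages, fit.model.spline_spec)
        X = np.column_stack(
            [np.ones_like(ages), np.full_like(ages, male),
             male * (ages - fit.model.age_center), B]
        )
        b = fit.blups.set_index("participant_id").loc[pid]
        oracle = (
            X @ fit.params.to_numpy()
            + b["b0"]
            + b["b1"] * (ages - fit.model.age_center)
        )
        np.testing.assert_allclose(
            fit.conditional_mean(pid, ages), oracle, rtol=1e-12
        )

    def test_yearly_grid_contract(self, fitted):
        visits, fit = fitted
        pid = visits["participant_id"].iloc[0]
        base_age = visits[visits["participant_id"] == pid]["age_at_exam"].max()
        series = fit.predict_yearly(pid)
        assert series["age"].iloc[-1] == int(np.floor(base_age))
        assert (np.diff(series["age"]) == 1).all()
        assert series["age"].iloc[0] == int(
            np.floor(visits["age_at_exam"].min())
        )
        assert np.isfinite(series["wc_hat"]).all()
        entry = fit.predict_yearly(pid, grid_rule="participant_entry")
        own_min = visits[visits["participant_id"] == pid]["age_at_exam"].min()
        assert entry["age"].iloc[0] == int(np.floor(own_min))

    def test_predict_yearly_all_agrees_with_per_participant(self, fitted):
        visits, fit = fitted
        allp = fit.predict_yearly_all()
        for pid in visits["participant_id"].unique()[:5]:
            one = fit.predict_yearly(pid)
            sub = allp[allp["participant_id"] == pid]
            np.testing.assert_allclose(
                sub["wc_hat"].to_numpy(), one["wc_hat"].to_numpy(), rtol=1e-10
            )

    def test_predictions_linear_in_blups(self, fitted):
        """Doubling the BLUP intercept shifts every wc_hat by it."""
        visits, fit = fitted
        pid = visits["participant_id"].iloc[0]
        before = fit.predict_yearly(pid)["wc_hat"].to_numpy()
        b0 = float(fit._blup_ix.loc[pid, "b0"])
        fit.blups.loc[fit.blups["participant_id"] == pid, "b0"] = 2 * b0
        fit.__post_init__()  # refresh index
        after = fit.predict_yearly(pid)["wc_hat"].to_numpy()
        np.testing.assert_allclose(after - before, b0, rtol=1e-9, atol=1e-9)
        fit.blups.loc[fit.blups["participant_id"] == pid, "b0"] = b0
        fit.__post_init__()

    def test_unknown_participant_rejected(self, fitted):
        _, fit = fitted
        with pytest.raises(KeyError):
            fit.predict_yearly("nope")

    def test_baseline_below_grid_start_rejected(self, fitted):
        visits, fit = fitted
        pid = visits["participant_id"].iloc[0]
        with pytest.raises(ValueError):
            fit.predict_yearly(pid, baseline_age=10.0)


class TestShrinkage:
    def test_raising_observed_wc_never_decreases_blup_intercept(self):
        visits = _toy_visits(60, seed=11)
        fit0 = WCTrajectoryModel(visits).fit()
        pid = visits["participant_id"].iloc[0]
        bumped = visits.copy()
        sel = bumped["participant_id"] == pid
        bumped.loc[sel, "wc"] += 5.0
        fit1 = WCTrajectoryModel(bumped).fit()
        b0_before = float(fit0._blup_ix.loc[pid, "b0"])
        b0_after = float(fit1._blup_ix.loc[pid, "b0"])
        assert b0_after >= b0_before

    def test_zero_true_slope_variance_not_significant_by_lrt(self):
        """Data generated with no random-slope variance: a likelihood-ratio
        test of random intercept+slope vs intercept-only must not reject
        (critical value 5.14 for the 50:50 chi2_1/chi2_2 boundary mixture
        at the 5% level)."""
        import warnings

        import statsmodels.api as sm

        cfg = w.SimConfig(
            n_participants=400, seed=803,
            wc_model=w.WCModelParams(
                random_intercept_sd=6.0, random_slope_sd=0.0,
                intercept_slope_corr=0.0, residual_sd=2.5,
            ),
        )
        model = WCTrajectoryModel(w.generate_cohort(cfg).visits)
        y = model.data["wc"].to_numpy()
        X = model._exog
        g = model.data["participant_id"].to_numpy()
        aged = (model.data["age_at_exam"].to_numpy() - 60) / 10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM(
                y, X, groups=g,
                exog_re=np.column_stack([np.ones_like(aged), aged]),
            ).fit(reml=False, method="lbfgs")
            null = sm.MixedLM(
                y, X, groups=g, exog_re=np.ones((len(y), 1))
            ).fit(reml=False, method="lbfgs")
        lrt = 2 * (full.llf - null.llf)
        assert lrt < 5.14

    def test_small_random_effect_variance_shrinks_to_population_curve(self):
        # tiny generating RE variance -> BLUPs near zero, predictions near
        # the fixed curve
        visits = _toy_visits(200, seed=13, ri=0.05, rs=0.001, resid=3.0)
        fit = WCTrajectoryModel(visits).fit()
        assert np.abs(fit.blups["b0"]).mean() < 0.5
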