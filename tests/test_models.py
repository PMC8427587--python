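import numpy as np
import pandas as pd
import pytest

from stepflow.models import (fit_angle_model, fit_speed_model,
                             lag1_autocorrelation, predict_effects)
from stepflow.synthetic import simulate_regression_table


@pytest.fixture(scope="module")
def reg_table():
    return simulate_regression_table(2500, rng=np.random.default_rng(10))


@pytest.fixture(scope="module")
def speed_fit(reg_table):
    return fit_speed_model(reg_table, check_lag_baseline=False)


class TestSpeedModel:
    def test_open_bog_contrast_within_two_se(self, speed_fit):
        tab = speed_fit.coef_table.set_index("term")
        est = tab.loc["land_cover[open-bog]", "estimate"]
        se = tab.loc["land_cover[open-bog]", "se"]
        assert abs(est - 0.380) < 2 * se

    def test_lag_coefficient_recovered(self, speed_fit):
        tab = speed_fit.coef_table.set_index("term")
        assert tab.loc["S_prev", "estimate"] == pytest.approx(0.026, abs=0.01)

    def test_null_covariate_smooths_shrink(self, speed_fit):
        """GCV shrinks effect-free covariates to ~0 df (most of them on any
        one realisation; occasional spurious structure is expected noise)."""
        smooths = speed_fit.smooth_table.set_index("term")
        nulls = ["s(dbh)", "s(tree_height)", "s(n_visible_turbines)",
                 "s(shadow_hours)", "s(dist_access_road)"]
        edf = smooths.loc[nulls, "edf"]
        assert (edf < 0.5).sum() >= 4
        assert edf.max() < 1.5

    def test_lag_covariate_removes_residual_autocorrelation(self):
        """Sequentially generated steps carry lag-1 autocorrelation that the
        previous-step covariate absorbs."""
        rng = np.random.default_rng(11)
        df = simulate_regression_table(2500, rng=rng, s_prev_coef=0.06,
                                       lagged_response=True)
        fit = fit_speed_model(df, check_lag_baseline=True)
        assert fit.acf1_before > 0.05
        assert abs(fit.acf1_after) < 0.05
        assert abs(fit.acf1_after) < fit.acf1_before

    def test_diel_effect_curve_tracks_truth(self):
        rng = np.random.default_rng(12)
        df = simulate_regression_table(3000, rng=rng, diel_amplitude=0.5,
                                       gamma_shape=2.0)
        fit = fit_speed_model(df, check_lag_baseline=False)
        grid = np.linspace(0.2, 23.8, 48)
        jday = 120.0                       # early season: large diel amplitude
        rows = []
        for h in grid:
            r = {c: df[c].mean() for c in
                 ("S_prev", "dbh", "tree_height", "n_visible_turbines",
                  "shadow_hours", "dist_access_road")}
            r.update({"daytime": h, "julian_day": jday,
                      "land_cover": fit.model.terms[0].levels_[0],
                      "individual_id": "__population__"})
            rows.append(r)
        pred = fit.model.predict(pd.DataFrame(rows), include_random=False,
                                 response_scale=False)
        truth = 0.5 * ((jday - 172) / 59.0) ** 2 * np.cos(
            2 * np.pi * (grid - 5) / 24)
        assert np.corrcoef(pred, truth)[0, 1] > 0.95


class TestAngleModel:
    def test_open_bog_directionality_sign(self, reg_table):
        fit = fit_angle_model(reg_table)
        tab = fit.coef_table.set_index("term")
        est = tab.loc["land_cover[open-bog]", "estimate"]
        se = tab.loc["land_cover[open-bog]", "se"]
        assert est < 0 and abs(est) > se     # more directional on open bogs

    def test_missing_angles_dropped_and_counted(self, reg_table):
        df = reg_table.copy()
        df.loc[df.index[:100], "alpha_abs"] = np.nan
        fit = fit_angle_model(df)
        assert fit.notes["n_angle_missing_dropped"] == 100
        assert fit.n_obs == len(df) - 100


class TestResidualAcf:
    def steps_frame(self, n):
        t0 = pd.Timestamp("2017-05-01T00:00:00Z")
        return pd.DataFrame({
            "burst_id": np.arange(n) // 500,
            "t_start": t0 + pd.to_timedelta(np.arange(n) * 300, unit="s"),
            "t_end": t0 + pd.to_timedelta((np.arange(n) + 1) * 300, unit="s"),
        })

    def test_white_noise_residuals_uncorrelated(self):
        rng = np.random.default_rng(13)
        n = 10_000
        acf = lag1_autocorrelation(rng.normal(size=n), self.steps_frame(n))
        assert abs(acf) < 0.03

    def test_ar1_residuals_recovered(self):
        rng = np.random.default_rng(14)
        n = 10_000
        e = np.empty(n)
        e[0] = rng.normal()
        for i in range(1, n):
            e[i] = 0.5 * e[i - 1] + np.sqrt(1 - 0.25) * rng.normal()
        acf = lag1_autocorrelation(e, self.steps_frame(n))
        assert acf == pytest.approx(0.5, abs=0.03)

    def test_pairs_only_across_adjacent_steps(self):
        # two steps separated by a gap: no pair, so the ACF is undefined
        t0 = pd.Timestamp("2017-05-01T00:00:00Z")
        steps = pd.DataFrame({
            "burst_id": [0, 0],
            "t_start": [t0, t0 + pd.Timedelta(seconds=900)],
            "t_end": [t0 + pd.Timedelta(seconds=300),
                      t0 + pd.Timedelta(seconds=1200)],
        })
        assert lag1_autocorrelation(np.array([1.0, -1.0]), steps) is None


class TestEffectPrediction:
    def test_null_covariate_curve_is_flat(self, speed_fit, reg_table):
        eff = predict_effects(speed_fit, "dbh", training_data=reg_table)
        spread = eff["estimate"].max() - eff["estimate"].min()
        assert spread < 0.02 * eff["estimate"].mean()

    def test_prediction_at_means_matches_intercept_level(self, speed_fit,
                                                         reg_table):
        from stepflow.models import _analysis_rows
        df = _analysis_rows(reg_table)
        base = {c: [df[c].mean()] for c in
                ("S_prev", "dbh", "tree_height", "n_visible_turbines",
                 "shadow_hours", "dist_access_road", "daytime", "julian_day")}
        base["land_cover"] = [speed_fit.model.terms[0].levels_[0]]
        base["individual_id"] = ["__population__"]
        pred = speed_fit.model.predict(pd.DataFrame(base), include_random=False,
                                       response_scale=False)
        eff = predict_effects(speed_fit, "land_cover", training_data=reg_table)
        ref_row = eff[eff["value"] == speed_fit.model.terms[0].levels_[0]]
        assert np.log(ref_row["estimate"].iloc[0]) == pytest.approx(pred[0],
                                                                    abs=1e-9)

    def test_flat_diel_pattern_at_solstice(self):
        """The seasonally fading diel effect vanishes on the longest day."""
        rng = np.random.default_rng(15)
        df = simulate_regression_table(6000, rng=rng, diel_amplitude=0.5,
                                       gamma_shape=3.0)
        fit = fit_speed_model(df, check_lag_baseline=False)
        grid = np.linspace(0, 24, 25)
        rows = []
        for h in grid:
            r = {c: df[c].mean() for c in
                 ("S_prev", "dbh", "tree_height", "n_visible_turbines",
                  "shadow_hours", "dist_access_road")}
            r.update({"daytime": h, "julian_day": 172.0,
                      "land_cover": fit.model.terms[0].levels_[0],
                      "individual_id": "__population__"})
            rows.append(r)
        pred = fit.model.predict(pd.DataFrame(rows), include_random=False)
        assert (pred.max() - pred.min()) < 0.10 * pred.mean()
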