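"""Mixed-model fits: REML equivalence, parameter recovery, GLMM, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from shortstop import models
from shortstop.synthetic_data import (
    simulate_experience_records,
    simulate_shortstop_records,
    simulate_site_rows,
)


class TestRemlBackend:
    def test_matches_statsmodels_mixedlm(self, rng):
        """Dual route: the profiled-REML fitter must agree with
        statsmodels MixedLM on a healthy dataset."""
        n, p = 120, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        groups = rng.integers(0, 10, n)
        u = rng.normal(0, 2.0, 10)
        y = X @ np.array([5.0, 2.0, -1.5]) + u[groups] + rng.normal(0, 1.0, n)
        fit = models.reml_random_intercept(y, X, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        np.testing.assert_allclose(fit["beta"], ref.fe_params, rtol=1e-5)
        np.testing.assert_allclose(fit["se"], ref.bse_fe, rtol=1e-4)
        np.testing.assert_allclose(fit["sigma2_e"], ref.scale, rtol=1e-4)
        np.testing.assert_allclose(fit["sigma2_u"],
                                   float(np.asarray(ref.cov_re)[0, 0]), rtol=1e-3)


class TestDistanceLmm:
    def test_parameter_recovery_within_two_se(self):
        rows, truth = simulate_site_rows(seed=5)
        fit = models.fit_distance_lmm(rows)
        for term in ("max_age", "grain_cover"):
            assert abs(fit.coef(term) - truth[term]) < 2 * fit.se(term)

    def test_noiseless_data_recovered_exactly(self):
        rows, truth = simulate_site_rows(noise_sd=0.0, year_sd=0.0,
                                         autocov_effect=30.0, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_distance_lmm(rows)
        for term in ("max_age", "temp_anomaly", "grain_cover", "autocov",
                     "intercept"):
            assert fit.coef(term) == pytest.approx(truth[term], abs=1e-6)

    def test_row_order_invariance(self, rng):
        rows, _ = simulate_site_rows(seed=7)
        fit1 = models.fit_distance_lmm(rows)
        fit2 = models.fit_distance_lmm(
            rows.iloc[rng.permutation(len(rows))].reset_index(drop=True))
        np.testing.assert_allclose(fit1.fe_table["estimate"],
                                   fit2.fe_table["estimate"], atol=1e-10)

    def test_response_shift_moves_only_intercept(self):
        rows, _ = simulate_site_rows(seed=11)
        fit1 = models.fit_distance_lmm(rows)
        shifted = rows.copy()
        shifted["distance_km"] += 500.0
        fit2 = models.fit_distance_lmm(shifted)
        slopes1 = fit1.fe_table.set_index("term")["estimate"].drop("intercept")
        slopes2 = fit2.fe_table.set_index("term")["estimate"].drop("intercept")
        np.testing.assert_allclose(slopes1, slopes2, atol=1e-8)
        assert fit2.coef("intercept") - fit1.coef("intercept") == pytest.approx(
            500.0, abs=1e-6)

    def test_ci_coverage_at_study_scale(self):
        """Nominal 95% CIs for the age effect cover the truth between
        90% and 99% of the time over 100 direct simulations."""
        hits = 0
        for s in range(100):
            rows, truth = simulate_site_rows(seed=1000 + s)
            fit = models.fit_distance_lmm(rows)
            half = 1.959963984540054 * fit.se("max_age")
            hits += abs(fit.coef("max_age") - truth["max_age"]) < half
        assert 0.90 <= hits / 100 <= 0.99


class TestPartialResiduals:
    def test_gls_slope_identity(self):
        """The V^-1-weighted simple regression of partial residuals on
        the predictor recovers the fitted coefficient exactly (the GLS
        analogue of the classic partial-residual slope identity)."""
        rows, _ = simulate_site_rows(seed=3)
        fit = models.fit_distance_lmm(rows)
        pr = models.partial_residuals(fit, "max_age")
        x = pr["max_age"].to_numpy()
        z = pr["partial_residual"].to_numpy()
        theta = fit.random_components["first_use_year"] / fit.extra["scale"]
        groups = fit.extra["groups"]

        def vinv(v):
            out = v.astype(float).copy()
            for g in np.unique(groups):
                idx = groups == g
                c = theta / (1.0 + idx.sum() * theta)
                out[idx] -= c * v[idx].sum()
            return out

        W = np.column_stack([np.ones_like(x), x])
        VW = np.column_stack([vinv(W[:, 0]), vinv(W[:, 1])])
        coef = np.linalg.solve(W.T @ VW, VW.T @ z)
        assert coef[1] == pytest.approx(fit.coef("max_age"), abs=1e-8)

    def test_hand_computed_small_example(self):
        """Matches the textbook definition computed by hand: marginal
        residual plus the predictor's own fixed-effect contribution."""
        df = pd.DataFrame({
            "distance_km": [10.0, 12.0, 9.0, 15.0, 11.0, 14.0, 8.0],
            "max_age": [1.0, 2.0, 3.0, 4.0, 5.0, 2.0, 6.0],
            "temp_anomaly": [0.2, 0.1, 0.4, 0.3, 0.5, 0.2, 0.6],
            "grain_cover": [5.0, 7.0, 2.0, 9.0, 4.0, 6.0, 1.0],
            "autocov": [0.1, -0.2, 0.3, 0.0, -0.1, 0.2, -0.3],
            "first_use_year": [1, 1, 2, 2, 1, 2, 1],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_distance_lmm(df)
        X = sm.add_constant(df[["max_age", "temp_anomaly", "grain_cover",
                                "autocov"]].to_numpy())
        beta = fit.fe_table["estimate"].to_numpy()
        hand = df["distance_km"].to_numpy() - X @ beta + beta[1] * df["max_age"].to_numpy()
        pr = models.partial_residuals(fit, "max_age")
        np.testing.assert_allclose(pr["partial_residual"], hand, atol=1e-8)

    def test_unknown_predictor_rejected(self):
        rows, _ = simulate_site_rows(seed=3)
        fit = models.fit_distance_lmm(rows)
        with pytest.raises(ValueError, match="unknown predictor"):
            models.partial_residuals(fit, "moon_phase")


class TestExperienceLmm:
    def test_parameter_recovery_and_sign(self):
        records, truth = simulate_experience_records(seed=4)
        fit = models.fit_experience_lmm(records)
        assert fit.coef("age") < 0
        assert abs(fit.coef("age") - truth["age"]) < 2 * fit.se("age")

    def test_constant_response_gives_zero_slope(self):
        records, _ = simulate_experience_records(seed=4)
        records["log_min_prev"] = 3.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_experience_lmm(records)
        assert fit.coef("age") == pytest.approx(0.0, abs=1e-6)
        assert all(v == pytest.approx(0.0, abs=1e-6)
                   for v in fit.random_components.values())

    def test_backtransformed_predictions_monotone_for_negative_slope(self):
        records, _ = simulate_experience_records(seed=4)
        fit = models.fit_experience_lmm(records)
        pred = fit.extra["prediction"]
        assert fit.coef("age") < 0
        assert (np.diff(pred["pred_km"]) < 0).all()
        assert (pred["log_lo"] <= pred["log_pred"]).all()
        assert (pred["log_pred"] <= pred["log_hi"]).all()

    def test_single_level_grouping_rejected(self):
        records, _ = simulate_experience_records(seed=4)
        records["year"] = 2005
        with pytest.raises(ValueError, match="year"):
            models.fit_experience_lmm(records)


class TestShortstopGlmm:
    def test_parameter_recovery_and_signs(self):
        records, truth = simulate_shortstop_records(seed=8)
        fit = models.fit_shortstop_glmm(records)
        for term in ("age", "year"):
            assert fit.coef(term) > 0
            assert abs(fit.coef(term) - truth[term]) < 2 * fit.se(term)

    def test_zero_variance_data_agree_with_plain_logistic(self):
        """With no individual heterogeneity the GLMM collapses onto
        ordinary logistic regression (within 2%)."""
        records, _ = simulate_shortstop_records(n_birds=400, sigma_u=0.0, seed=9)
        fit = models.fit_shortstop_glmm(records)
        X = np.column_stack([
            np.ones(len(records)), records["age"],
            records["year"] - fit.extra["year_mid"]])
        ref = sm.Logit(records["shortstopped"].astype(float), X).fit(disp=0)
        got = fit.fe_table["estimate"].to_numpy()
        np.testing.assert_allclose(got, ref.params, rtol=0.02, atol=0.02)

    def test_fitted_probabilities_bounded(self):
        records, _ = simulate_shortstop_records(seed=8)
        fit = models.fit_shortstop_glmm(records)
        assert (fit.fitted > 0).all() and (fit.fitted < 1).all()
        grid = fit.extra["prediction"]
        assert grid["p_shortstop"].between(0, 1, inclusive="neither").all()
        observed = set(map(tuple, records[["age", "year"]].drop_duplicates()
                           .to_numpy()))
        assert set(map(tuple, grid[["age", "year"]].to_numpy())) == observed

    def test_single_class_rejected(self):
        records, _ = simulate_shortstop_records(seed=8)
        records["shortstopped"] = True
        with pytest.raises(ValueError, match="outcome classes"):
            models.fit_shortstop_glmm(records)

    def test_complete_separation_rejected(self):
        n = 80
        records = pd.DataFrame({
            "bird_id": [f"b{i % 20}" for i in range(n)],
            "age": np.arange(n, dtype=float) % 10 + 1,
            "year": 2005 + np.arange(n) % 8,
        })
        records["shortstopped"] = records["age"] > 5
        with pytest.raises(ValueError, match="separation"):
            models.fit_shortstop_glmm(records)

    def test_wald_pvalues_uniform_under_null(self):
        """Type-I calibration: with zero age and year effects, Wald
        p-values for the age term are uniform across simulations."""
        from scipy import stats

        ps = []
        for s in range(200):
            records, _ = simulate_shortstop_records(
                n_birds=40, n_years=8, beta0=0.0, beta_age=0.0,
                beta_year=0.0, sigma_u=0.6, seed=3000 + s)
            if records["shortstopped"].nunique() < 2:
                continue
            try:
                fit = models.fit_shortstop_glmm(records)
            except (ValueError, models.ConvergenceError):
                continue
            ps.append(float(fit.fe_table.set_index("term").loc["age", "p"]))
        assert len(ps) > 150
        assert stats.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def small_fit():
    records, _ = simulate_shortstop_records(n_birds=40, n_years=8, seed=12)
    return models.fit_shortstop_glmm(records)


class TestBootstrapBand:
    def test_band_brackets_point_prediction(self, small_fit):
        band = models.bootstrap_prediction_band(small_fit, n_reps=60, seed=1)
        merged = band.merge(small_fit.extra["prediction"], on=["age", "year"])
        inside = ((merged["lo"] <= merged["p_shortstop"])
                  & (merged["p_shortstop"] <= merged["hi"]))
        assert inside.mean() >= 0.95

    def test_seed_determinism_and_distinct_streams(self, small_fit):
        b1 = models.bootstrap_prediction_band(small_fit, n_reps=40, seed=5)
        b2 = models.bootstrap_prediction_band(small_fit, n_reps=40, seed=5)
        pd.testing.assert_frame_equal(b1, b2)
        b3 = models.bootstrap_prediction_band(small_fit, n_reps=40, seed=6)
        assert not np.allclose(b1["lo"], b3["lo"])
        # different seeds still describe the same model: bands overlap
        assert (np.maximum(b1["lo"], b3["lo"])
                <= np.minimum(b1["hi"], b3["hi"])).all()

    def test_more_replicates_stabilise_band_endpoints(self, small_fit):
        """Monte Carlo jitter of the band endpoints shrinks when the
        replicate count doubles."""
        def endpoint_sd(n_reps, seeds):
            los = [models.bootstrap_prediction_band(small_fit, n_reps=n_reps,
                                                    seed=s)["lo"].to_numpy()
                   for s in seeds]
            return np.std(np.vstack(los), axis=0).mean()

        assert endpoint_sd(15, (21, 22, 23, 24)) > endpoint_sd(60, (25, 26, 27, 28))
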