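"""Random-lasso immunological age model and residual-age analyses."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

import cytoaging as ca
from cytoaging.agemodel import elbow_point, estimate_cutoff


def standardized_frame(rng, n, p, names=None):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=names or [f"f{j}" for j in range(p)])
    return (X - X.mean()) / X.std(ddof=1)


class TestOracleReduction:
    def test_reduces_to_single_lasso(self, rng):
        n, p = 120, 15
        X = standardized_frame(rng, n, p)
        y = 30 + 3 * X["f0"].to_numpy() - 2 * X["f3"].to_numpy() + rng.normal(0, 1, n)
        cfg = ca.RandomLassoConfig(
            n_splits=1, test_fraction=0.0, n_boot1=1, n_boot2=1,
            q1_range=(1.0, 1.0), q2=1.0, alpha=0.1, passthrough_bootstrap=True, seed=0,
        )
        model = ca.fit_random_lasso(X, y, cfg)
        ref = Lasso(alpha=0.1, max_iter=5000, tol=1e-6).fit(X.to_numpy(), y)
        assert np.max(np.abs(model.importance.to_numpy() - ref.coef_)) < 1e-6
        assert model.intercept == pytest.approx(ref.intercept_, abs=1e-9)

    def test_single_feature_matches_soft_threshold_closed_form(self, rng):
        # lasso with one standardized predictor has the closed-form
        # soft-threshold solution b = S(x'y/n, alpha) / (x'x/n)
        n = 200
        X = standardized_frame(rng, n, 1)
        x = X["f0"].to_numpy()
        y = 1.7 * x + rng.normal(0, 0.3, n)
        yc = y - y.mean()
        alpha = 0.2
        rho = x @ yc / n
        oracle = np.sign(rho) * max(abs(rho) - alpha, 0.0) / (x @ x / n)
        cfg = ca.RandomLassoConfig(
            n_splits=1, test_fraction=0.0, n_boot1=1, n_boot2=1,
            q1_range=(1.0, 1.0), q2=1.0, alpha=alpha, passthrough_bootstrap=True, seed=0,
        )
        model = ca.fit_random_lasso(X, y, cfg)
        assert model.importance["f0"] == pytest.approx(oracle, abs=1e-6)


class TestStages:
    def test_stage1_ranks_true_feature_first(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = standardized_frame(rng, 200, 50)
            y = 2.0 * X["f0"].to_numpy() + rng.normal(0, 1.0, 200)
            cfg = ca.RandomLassoConfig(n_boot1=200, seed=seed)
            imp = ca.random_lasso_stage1(
                X.to_numpy(), y, cfg, np.random.default_rng(seed), alpha=0.05
            )
            hits += int(np.argmax(np.abs(imp)) == 0)
        assert hits >= 4

    def test_stage2_degenerate_sampler_uses_the_single_weighted_feature(self, rng):
        n, p = 100, 10
        X = standardized_frame(rng, n, p)
        y = X["f4"].to_numpy() + rng.normal(0, 0.1, n)
        imp = np.zeros(p)
        imp[4] = 1.0
        cfg = ca.RandomLassoConfig(n_boot2=50, q2=0.1, seed=1)  # q2*p = 1 feature
        coef, _ = ca.random_lasso_stage2(
            X.to_numpy(), y, imp, cfg, np.random.default_rng(1), alpha=0.01
        )
        assert np.flatnonzero(coef).tolist() == [4]

    def test_all_zero_importance_falls_back_to_uniform(self, rng):
        n, p = 80, 12
        X = standardized_frame(rng, n, p)
        y = rng.normal(size=n)
        cfg = ca.RandomLassoConfig(n_boot2=100, q2=0.25, seed=2)
        coef, _ = ca.random_lasso_stage2(
            X.to_numpy(), y, np.zeros(p), cfg, np.random.default_rng(2), alpha=0.5
        )
        assert coef.shape == (p,)  # runs; uniform sampling covered all features


class TestCutoff:
    def test_flat_curve_elbow_at_largest_cutoff(self):
        assert elbow_point(np.arange(6), np.ones(6)) == 5

    def test_sharp_knee_found_by_chord_rule(self):
        # piecewise-linear curve: flat at 1.0 until x=6, then climbs steeply;
        # the max-distance-to-chord point is the knee
        x = np.arange(10.0)
        y = np.concatenate([np.ones(7), [2.0, 3.0, 4.0]])
        assert elbow_point(x, y) == 6

    def test_fewer_than_two_points_raise(self):
        with pytest.raises(ValueError):
            elbow_point(np.array([1.0]), np.array([2.0]))

    def test_cutoff_separates_signal_from_noise_importances(self, rng):
        n, p = 250, 40
        X = standardized_frame(rng, n, p)
        y = (2.0 * X["f0"] + 1.5 * X["f1"] + 1.0 * X["f2"]).to_numpy()
        y += rng.normal(0, 1.0, n)
        imp = np.zeros(p)
        imp[:3] = [2.0, 1.5, 1.0]
        imp[3:] = rng.normal(0, 0.01, p - 3)
        cfg = ca.RandomLassoConfig(cv_repeats=5, seed=3)
        c = estimate_cutoff(imp, X.to_numpy(), y, cfg, rng=np.random.default_rng(3))
        assert np.max(np.abs(imp[3:])) <= c < 1.0


class TestPredictAndDeterminism:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(8)
        X = standardized_frame(rng, 150, 20)
        y = 35 + 4 * X["f0"].to_numpy() + 2 * X["f5"].to_numpy() + rng.normal(0, 2, 150)
        cfg = ca.RandomLassoConfig(n_splits=8, n_boot1=20, n_boot2=20, cv_repeats=3, seed=8)
        return X, y, ca.fit_random_lasso(X, y, cfg)

    def test_training_mean_vector_predicts_mean_age(self, fitted):
        X, y, model = fitted
        center = pd.DataFrame([np.zeros(X.shape[1])], columns=X.columns)
        pred = ca.predict_age(model, center)
        assert pred.iloc[0] == pytest.approx(y.mean(), abs=1.0)

    def test_column_order_irrelevant(self, fitted):
        X, _, model = fitted
        shuffled = X[list(X.columns[::-1])]
        p1 = ca.predict_age(model, X)
        p2 = ca.predict_age(model, shuffled)
        pd.testing.assert_series_equal(p1, p2)

    def test_missing_retained_column_raises_with_name(self, fitted):
        X, _, model = fitted
        victim = model.retained[0]
        with pytest.raises(KeyError, match=victim):
            ca.predict_age(model, X.drop(columns=[victim]))

    def test_same_seed_reproduces_importances_bitwise(self, fitted):
        X, y, model = fitted
        again = ca.fit_random_lasso(X, y, model.config)
        assert model.importance.equals(again.importance)
        assert model.cutoff == again.cutoff

    def test_json_serialization_round_trip(self, fitted, tmp_path):
        _, _, model = fitted
        import json

        payload = json.loads(model.to_json(tmp_path / "model.json"))
        assert payload["retained"] == model.retained
        assert payload["config"]["seed"] == model.config.seed


class TestResidualAge:
    def _cohort(self, seed=0, accel=0.0, cov_accel=None):
        cfg = ca.CohortConfig(
            n_per_group={"CTR": 150, "REL": 100, "T1D": 150},
            n_features_per_cluster=(4, 2, 4, 2),
            disease_shift=(0, 0, 0, 0), aging_acceleration_years=accel,
            covariate_acceleration=cov_accel or {}, seed=seed,
        )
        return ca.generate_cohort(cfg)

    def test_perfect_predictions_give_null_result(self):
        coh = self._cohort()
        pred = coh.age.copy()
        res = ca.residual_age_analysis(pred, coh, age_ceiling=None)
        assert np.allclose(res.residuals, 0.0, atol=1e-10)
        assert res.group_contrast == pytest.approx(0.0, abs=1e-10)
        assert res.reference_fit["slope"] == pytest.approx(1.0)

    def test_residuals_sum_to_zero_on_reference(self):
        rng = np.random.default_rng(4)
        coh = self._cohort(seed=4)
        pred = coh.age + pd.Series(rng.normal(0, 3, coh.n_subjects), index=coh.age.index)
        res = ca.residual_age_analysis(pred, coh, age_ceiling=None)
        ref = coh.group.isin(("CTR", "REL"))
        assert res.residuals[ref].sum() == pytest.approx(0.0, abs=1e-8)

    def test_covariate_recovery_standardized_beta(self):
        # residual aging generated as 1.5 x standardized BMI within T1D:
        # the standardized multivariable coefficient should recover ~1.5
        rng = np.random.default_rng(5)
        coh = self._cohort(seed=5)
        t1d = coh.group.eq("T1D")
        bmi = coh.covariates["bmi_percentile"]
        z = (bmi - bmi.mean()) / bmi.std(ddof=1)
        pred = coh.age + 1.5 * z.where(t1d, 0.0) + pd.Series(
            rng.normal(0, 0.8, coh.n_subjects), index=coh.age.index
        )
        res = ca.residual_age_analysis(pred, coh, age_ceiling=None,
                                       covariates=["bmi_percentile", "hba1c"])
        assert res.covariate_table.loc["bmi_percentile", "beta_std"] == pytest.approx(
            1.5, abs=0.3
        )
        assert res.covariate_table.loc["bmi_percentile", "p"] < 1e-6

    def test_zero_variance_covariate_dropped_with_warning(self, caplog):
        coh = self._cohort(seed=6)
        coh.covariates["flat"] = 1.0
        pred = coh.age.copy()
        with caplog.at_level("WARNING"):
            res = ca.residual_age_analysis(
                pred, coh, age_ceiling=None, covariates=["flat", "hba1c"]
            )
        assert "flat" not in res.covariate_table.index

    def test_piecewise_fit_reports_break_terms(self):
        coh = self._cohort(seed=7)
        pred = coh.age.copy()
        res = ca.residual_age_analysis(pred, coh, age_ceiling=None)
        assert res.piecewise["break"] == 30.0
        assert res.piecewise["slope_below"] == pytest.approx(1.0, abs=1e-8)
        assert res.piecewise["slope_change"] == pytest.approx(0.0, abs=1e-8)
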