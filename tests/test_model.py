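"""Elastic-net brain-age model: folds, tuning, bias correction, permutation."""

import warnings

import numpy as np
import pandas as pd
import pytest

import brainage_delta as bd
from brainage_delta.model import HyperparameterGrid, _fit_enet


def _linear_problem(n, p, noise, seed, slope_scale=1.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 89, n)
    slopes = rng.uniform(-0.004, -0.001, p) * slope_scale
    baselines = rng.uniform(0.9, 1.6, p)
    X = baselines + np.outer(ages, slopes) + rng.normal(0, noise, (n, p))
    return pd.DataFrame(X, columns=[f"roi{j}" for j in range(p)]), ages


SMALL_GRID = HyperparameterGrid(
    alpha_values=(0.001, 0.5, 0.99),
    lambda_values=np.logspace(-5, 5, 30),
)


class TestStratifiedAgeFolds:
    def test_equal_fold_sizes_when_divisible(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 89, 100)
        folds = bd.stratified_age_folds(ages, k=10, seed=1)
        assert np.bincount(folds).tolist() == [10] * 10

    def test_fold_means_close_to_grand_mean(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(18, 89, 200)
        folds = bd.stratified_age_folds(ages, k=10, seed=3)
        for f in range(10):
            assert abs(ages[folds == f].mean() - ages.mean()) < 5.0

    def test_determinism_and_k_checks(self):
        ages = np.linspace(20, 80, 50)
        a = bd.stratified_age_folds(ages, k=5, seed=7)
        b = bd.stratified_age_folds(ages, k=5, seed=7)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            bd.stratified_age_folds(ages, k=51)


class TestTuneAndFit:
    def test_recoverable_linear_signal(self):
        X_all, ages_all = _linear_problem(400, 20, noise=0.02, seed=1)
        X, ages = X_all.iloc[:300], ages_all[:300]
        X_test, ages_test = X_all.iloc[300:], ages_all[300:]
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=1)
        pred = bd.predict(model, X_test)
        res = bd.apply_bias_correction(model, pred, ages_test)
        r2, _ = bd.evaluate(res)
        assert r2 > 0.9
        assert model.lam < 1.0

    def test_null_signal_predicts_mean_age(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(150, 10)),
                         columns=[f"f{j}" for j in range(10)])
        ages = rng.uniform(18, 89, 150)
        X_test = pd.DataFrame(rng.normal(size=(80, 10)), columns=X.columns)
        ages_test = rng.uniform(18, 89, 80)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=5)
        pred = bd.predict(model, X_test)
        assert abs(pred.mean() - ages.mean()) < 3.0
        ss_res = ((pred - ages_test) ** 2).sum()
        ss_tot = ((ages_test - ages_test.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot <= 0.05

    def test_full_shrinkage_limit_predicts_training_mean(self):
        X, ages = _linear_problem(100, 10, noise=0.05, seed=6)
        grid = HyperparameterGrid(lambda_values=np.array([1e5]))
        model = bd.tune_and_fit(X, ages, grid, seed=6)
        assert np.all(model.coef == 0)
        pred = bd.predict(model, X)
        np.testing.assert_allclose(pred, ages.mean(), atol=1e-6)

    def test_zero_variance_column_dropped(self):
        X, ages = _linear_problem(80, 5, noise=0.05, seed=7)
        X["flat"] = 1.0
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=7)
        assert "flat" not in model.feature_names

    def test_leakage_canary(self):
        # the fitted model depends only on training data: refits agree
        # exactly, and perturbing one held-out row changes only that row
        X, ages = _linear_problem(120, 8, noise=0.05, seed=8)
        X_test, _ = _linear_problem(30, 8, noise=0.05, seed=9)
        m1 = bd.tune_and_fit(X, ages, SMALL_GRID, seed=8)
        m2 = bd.tune_and_fit(X, ages, SMALL_GRID, seed=8)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.to_dict() == m2.to_dict()
        pred = bd.predict(m1, X_test)
        perturbed = X_test.copy()
        perturbed.iloc[0, :] += 10.0
        pred_perturbed = bd.predict(m1, perturbed)
        assert abs(pred_perturbed[0] - pred[0]) > 1.0
        np.testing.assert_allclose(pred_perturbed[1:], pred[1:], atol=1e-9)

    def test_small_penalty_converges_to_least_squares(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 5))
        beta = np.array([2.0, -1.0, 0.5, 3.0, -2.5])
        y = X @ beta + rng.normal(0, 0.1, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = _fit_enet(X, y, alpha=0.001, lam=1e-7)
        ols = np.linalg.lstsq(
            np.column_stack([X, np.ones(200)]), y, rcond=None
        )[0]
        assert np.max(np.abs(est.coef_ - ols[:5])) < 1e-3


class TestPredict:
    def test_all_zero_standardized_features_give_intercept(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=11)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=11)
        at_mean = pd.DataFrame([model.scaler_mean], columns=model.feature_names)
        assert bd.predict(model, at_mean)[0] == pytest.approx(model.intercept)

    def test_matches_dot_product_oracle(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=12)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=12)
        rows = X.iloc[:5]
        expected = (
            (rows.to_numpy() - model.scaler_mean) / model.scaler_scale
        ) @ model.coef + model.intercept
        np.testing.assert_allclose(bd.predict(model, rows), expected, atol=1e-12)

    def test_missing_features_raise(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=13)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=13)
        with pytest.raises(ValueError, match="missing"):
            bd.predict(model, X[model.feature_names[:2]])

    def test_json_round_trip(self, tmp_path):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=14)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=14)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = bd.BrainAgeModel.load(path)
        np.testing.assert_allclose(bd.predict(loaded, X), bd.predict(model, X))


class TestBiasCorrection:
    def test_identity_when_predictions_perfect(self):
        ages = np.linspace(20, 80, 30)
        a, b = bd.fit_bias_correction(ages, ages)
        assert (a, b) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-9))

    def test_exact_linear_relation_recovered(self):
        ages = np.linspace(20, 80, 30)
        a, b = bd.fit_bias_correction(0.5 * ages + 30, ages)
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(30.0)

    def test_matches_polyfit_oracle_on_noisy_data(self):
        rng = np.random.default_rng(15)
        ages = rng.uniform(18, 89, 100)
        pred = 0.8 * ages + 10 + rng.normal(0, 3, 100)
        a, b = bd.fit_bias_correction(pred, ages)
        oracle = np.polyfit(ages, pred, 1)
        assert a == pytest.approx(oracle[0], abs=1e-10)
        assert b == pytest.approx(oracle[1], abs=1e-10)

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bd.fit_bias_correction(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))

    def test_apply_identity_and_exact_cases(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=16)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=16)
        model.bias_slope, model.bias_intercept = 1.0, 0.0
        pred = bd.predict(model, X)
        res = bd.apply_bias_correction(model, pred, ages)
        np.testing.assert_allclose(res.corrected_predicted, pred)
        # predictions generated exactly as a*age + b correct to zero delta
        model.bias_slope, model.bias_intercept = 0.7, 12.0
        res = bd.apply_bias_correction(model, 0.7 * ages + 12.0, ages)
        np.testing.assert_allclose(res.corrected_delta, 0.0, atol=1e-10)

    def test_zero_slope_fails_loudly(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=17)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=17)
        model.bias_slope = 0.0
        with pytest.raises(ValueError, match="bias"):
            bd.apply_bias_correction(model, ages, ages)


class TestEvaluate:
    def _result(self, age, corrected):
        return bd.PredictionResult(
            ids=np.arange(len(age)), age=np.asarray(age, float),
            predicted=np.asarray(corrected, float),
            corrected_predicted=np.asarray(corrected, float),
        )

    def test_perfect_predictions(self):
        ages = np.linspace(20, 80, 10)
        r2, mae = bd.evaluate(self._result(ages, ages))
        assert (r2, mae) == (1.0, 0.0)

    def test_constant_prediction_at_mean_age(self):
        ages = np.linspace(20, 80, 10)
        r2, _ = bd.evaluate(self._result(ages, np.full(10, ages.mean())))
        assert r2 == pytest.approx(0.0)

    def test_matches_hand_computed_sums(self):
        rng = np.random.default_rng(18)
        ages = rng.uniform(18, 89, 25)
        corrected = ages + rng.normal(0, 5, 25)
        r2, mae = bd.evaluate(self._result(ages, corrected))
        resid = corrected - ages
        assert mae == pytest.approx(np.abs(resid).mean())
        assert r2 == pytest.approx(
            1 - (resid**2).sum() / ((ages - ages.mean()) ** 2).sum()
        )


class TestPermutationTest:
    def test_strong_signal_attains_minimum_p(self):
        X_all, ages_all = _linear_problem(210, 10, noise=0.02, seed=19)
        X, ages = X_all.iloc[:150], ages_all[:150]
        X_test, ages_test = X_all.iloc[150:], ages_all[150:]
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=19)
        perm = bd.permutation_test(
            X, ages, X_test, ages_test, model, n_perm=99, seed=19
        )
        assert perm.p_value == pytest.approx(1 / 100)
        assert perm.null_mae.min() > perm.observed_mae

    def test_p_value_bounds(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{j}" for j in range(5)])
        ages = rng.uniform(18, 89, 60)
        X_test = pd.DataFrame(rng.normal(size=(30, 5)), columns=X.columns)
        ages_test = rng.uniform(18, 89, 30)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, k=5, seed=21)
        perm = bd.permutation_test(
            X, ages, X_test, ages_test, model, n_perm=49, seed=22
        )
        assert 1 / 50 <= perm.p_value <= 1.0

    def test_invalid_n_perm(self):
        X, ages = _linear_problem(60, 4, noise=0.05, seed=23)
        model = bd.tune_and_fit(X, ages, SMALL_GRID, seed=23)
        with pytest.raises(ValueError):
            bd.permutation_test(X, ages, X, ages, model, n_perm=0)
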