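import numpy as np
import pandas as pd
import pytest

from corneafluor.estimator import (
    HybridAGERegressor,
    HybridModelDocument,
    SelectionRule,
    SvrHyperparams,
    evaluate_models,
    fit_mlr,
    fit_svr,
    select_features,
)
from corneafluor.exceptions import (
    CollinearFeaturesError,
    ConfigurationError,
    EmptySelectionError,
    InputError,
    SampleSizeError,
)


def linear_cohort(n=120, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    intensity = rng.uniform(90, 190, n)
    bmi = rng.uniform(18, 32, n)
    y = 0.05 * intensity - 2.5 + noise * rng.normal(size=n)
    X = pd.DataFrame({"intensity": intensity, "bmi": bmi})
    return X, y


class TestSelection:
    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        X = np.column_stack([np.full(50, 3.0), y])
        selected = select_features(X, y)
        assert list(selected) == [1]

    def test_reference_itself_always_selected(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        selected = select_features(y[:, None], y)
        assert list(selected) == [0]

    def test_independent_feature_rarely_survives(self):
        """|r| with an independent feature almost never reaches 0.3 at
        n = 1000, so the rule should exclude it in >= 95% of replicates."""
        excluded = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=1000)
            X = np.column_stack([rng.normal(size=1000), y])
            selected = select_features(X, y)
            excluded += 0 not in selected
        assert excluded >= 95

    def test_selection_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=80)
        x = 0.6 * y + rng.normal(size=80)
        rule = SelectionRule(variance_floor=0.0, min_abs_corr=0.3)
        base = select_features(x[:, None], y, rule)
        rescaled = select_features((5.0 * x + 100.0)[:, None], y, rule)
        assert list(base) == list(rescaled)

    def test_empty_selection_is_an_error(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        X = rng.normal(size=(200, 2))  # independent of y
        with pytest.raises(EmptySelectionError):
            select_features(X, y)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ConfigurationError):
            SelectionRule(variance_floor=-1.0)
        with pytest.raises(ConfigurationError):
            SelectionRule(min_abs_corr=1.5)


class TestMlr:
    def test_two_point_closed_form(self):
        beta = fit_mlr(np.array([[0.0], [1.0], [2.0]]), np.array([1.0, 3.0, 5.0]))
        assert beta[0] == pytest.approx(1.0, abs=1e-10)
        assert beta[1] == pytest.approx(2.0, abs=1e-10)

    def test_exact_linear_data_recovered(self):
        X, y = linear_cohort(noise=0.0)
        beta = fit_mlr(X["intensity"].to_numpy()[:, None], y)
        assert beta[0] == pytest.approx(-2.5, abs=1e-8)
        assert beta[1] == pytest.approx(0.05, abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        X, y = linear_cohort(noise=0.5, seed=5)
        M = X.to_numpy()
        beta = fit_mlr(M, y)
        residuals = y - (beta[0] + M @ beta[1:])
        design = np.column_stack([np.ones(len(y)), M])
        np.testing.assert_allclose(design.T @ residuals, 0.0, atol=1e-7)

    def test_collinear_design_names_offender(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(CollinearFeaturesError) as err:
            fit_mlr(X, rng.normal(size=40), feature_names=["a", "a_doubled"])
        assert any(name in err.value.features for name in ("a", "a_doubled"))

    def test_sample_size_guard(self):
        with pytest.raises(SampleSizeError):
            fit_mlr(np.ones((3, 2)), np.ones(3))


class TestSvr:
    def test_constant_target_predicted_within_epsilon(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 1))
        model = fit_svr(X, np.full(30, 4.2))
        np.testing.assert_allclose(model.predict(X), 4.2, atol=0.011)

    def test_noiseless_monotone_map_within_tube(self):
        x = np.linspace(-1.5, 1.5, 50)[:, None]
        y = 2.0 + np.tanh(x).ravel()
        model = fit_svr(x, y, SvrHyperparams(C=10.0, gamma=0.1, epsilon=0.01))
        mae = np.mean(np.abs(model.predict(x) - y))
        assert mae <= 0.01 + 0.02  # epsilon plus kernel-bias slack

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        p1 = fit_svr(X, y).predict(X)
        p2 = fit_svr(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ConfigurationError):
            SvrHyperparams(C=0.0)
        with pytest.raises(ConfigurationError):
            SvrHyperparams(epsilon=-1.0)


class TestHybrid:
    def test_prediction_is_stated_convex_combination(self):
        X, y = linear_cohort(noise=0.3, seed=9)
        est = HybridAGERegressor(select=False).fit(X, y)
        mlr, svr = est.predict_components(X)
        np.testing.assert_allclose(
            est.predict(X), 0.7 * mlr + 0.3 * svr, rtol=1e-12
        )

    def test_equal_components_pass_through(self):
        # dual_coef 0 makes the SVR output its intercept; match it to the MLR
        doc = HybridModelDocument(
            feature_names=["x"],
            selected_features=[0],
            w_mlr=0.4,
            w_svr=0.6,
            mlr_coef=[5.0, 0.0],
            scaler_mean=[0.0],
            scaler_scale=[1.0],
            gamma=0.1,
            support_vectors=[[0.0]],
            dual_coef=[0.0],
            svr_intercept=5.0,
        )
        np.testing.assert_allclose(doc.predict([[123.0]]), 5.0)

    def test_default_weights_arithmetic(self):
        # MLR(x) = 10, SVR(x) = 0 with defaults (0.7, 0.3) gives 7.0
        doc = HybridModelDocument(
            feature_names=["x"],
            selected_features=[0],
            w_mlr=0.7,
            w_svr=0.3,
            mlr_coef=[10.0, 0.0],
            scaler_mean=[0.0],
            scaler_scale=[1.0],
            gamma=0.1,
            support_vectors=[[0.0]],
            dual_coef=[0.0],
            svr_intercept=0.0,
        )
        assert doc.predict([[1.0]])[0] == pytest.approx(7.0, abs=1e-12)

    def test_degenerate_weight_gives_pure_mlr(self):
        X, y = linear_cohort(noise=0.2, seed=10)
        est = HybridAGERegressor(w_mlr=1.0, w_svr=0.0, select=False).fit(X, y)
        mlr, _ = est.predict_components(X)
        np.testing.assert_array_equal(est.predict(X), mlr)

    def test_invalid_weights_rejected(self):
        X, y = linear_cohort()
        with pytest.raises(ConfigurationError):
            HybridAGERegressor(w_mlr=0.7, w_svr=0.4).fit(X, y)
        with pytest.raises(ConfigurationError):
            HybridAGERegressor(w_mlr=-0.1, w_svr=1.1).fit(X, y)

    def test_missing_feature_reported(self):
        X, y = linear_cohort(noise=0.1, seed=11)
        est = HybridAGERegressor(select=False).fit(X, y)
        with pytest.raises(InputError, match="missing"):
            est.predict(X[["intensity"]])

    def test_sklearn_params_roundtrip(self):
        est = HybridAGERegressor(w_mlr=0.6, w_svr=0.4)
        params = est.get_params()
        clone = HybridAGERegressor(**params)
        assert clone.get_params() == params


class TestDocument:
    def test_json_roundtrip_preserves_predictions(self):
        X, y = linear_cohort(noise=0.3, seed=12)
        est = HybridAGERegressor(select=False).fit(X, y)
        doc = est.to_document()
        doc2 = HybridModelDocument.from_json(doc.to_json())
        np.testing.assert_array_equal(doc.predict(X), doc2.predict(X))

    def test_document_matches_live_estimator(self):
        X, y = linear_cohort(noise=0.3, seed=13)
        est = HybridAGERegressor(select=False).fit(X, y)
        np.testing.assert_allclose(
            est.to_document().predict(X), est.predict(X), rtol=1e-9, atol=1e-9
        )

    def test_unknown_schema_version_rejected(self):
        from corneafluor.exceptions import SchemaVersionError

        X, y = linear_cohort(noise=0.3, seed=14)
        doc = HybridAGERegressor(select=False).fit(X, y).to_document()
        payload = doc.to_json().replace('"schema_version": "1.0"', '"schema_version": "2.0"')
        with pytest.raises(SchemaVersionError):
            HybridModelDocument.from_json(payload)


class TestEvaluate:
    def test_noiseless_linear_cohort_near_zero_error(self):
        X, y = linear_cohort(n=100, noise=0.0, seed=15)
        result = evaluate_models(X, y, seed=0)
        assert result["mlr"]["mare_percent"] < 0.1
        assert result["hybrid"]["mare_percent"] < 1.5

    def test_hybrid_error_bounded_by_worst_component(self):
        """Triangle inequality: MARE(hybrid) <= max(MARE(MLR), MARE(SVR))."""
        for seed in range(10):
            X, y = linear_cohort(n=80, noise=0.4, seed=seed)
            result = evaluate_models(X, y, seed=seed)
            worst = max(
                result["mlr"]["mare_percent"], result["svr"]["mare_percent"]
            )
            assert result["hybrid"]["mare_percent"] <= worst + 1e-9

    def test_small_cohorts_refused(self):
        X, y = linear_cohort(n=8)
        with pytest.raises(SampleSizeError):
            evaluate_models(X, y)

    def test_deterministic_given_seed(self):
        X, y = linear_cohort(n=60, noise=0.3, seed=16)
        r1 = evaluate_models(X, y, seed=42)
        r2 = evaluate_models(X, y, seed=42)
        assert r1 == r2
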