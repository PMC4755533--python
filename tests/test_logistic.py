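"""Fitting, linear predictors and probabilities, checked against closed
forms, an independent maximum-likelihood implementation (statsmodels), and
the generating coefficients of simulated data."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from transportc import (
    CollinearPredictorsError,
    Dataset,
    DegenerateOutcomeError,
    FittedModel,
    ModelSpec,
    SpecMismatchError,
    fit_logistic,
    linear_predictor,
    predict_probability,
)


def _simulate(beta, sigma, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sigma, n)
    y = (rng.random(n) < expit(beta * x)).astype(float)
    return Dataset(y, x[:, None], ["x"])


class TestFitLogistic:
    def test_null_effect_slope_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 10_000)
        y = (rng.random(10_000) < 0.5).astype(float)
        model = fit_logistic(Dataset(y, x[:, None], ["x"]))
        assert abs(model.coefficients[0]) < 0.1

    def test_recovers_generating_slope(self):
        # strong-effect generator, large n: estimate within 5% of beta=3
        model = fit_logistic(_simulate(3.0, 1.0, 100_000, seed=2))
        assert model.converged
        assert model.coefficients[0] == pytest.approx(3.0, rel=0.05)

    def test_symmetric_two_by_two_table(self):
        # equal events/non-events at both x levels: log-odds-ratio 0, intercept 0
        ds = Dataset(
            np.array([1.0, 0.0, 1.0, 0.0]),
            np.array([[0.0], [0.0], [1.0], [1.0]]),
            ["x"],
        )
        model = fit_logistic(ds)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_mle(self, toy_bivariable):
        model = fit_logistic(toy_bivariable)
        X = sm.add_constant(toy_bivariable.covariates)
        ref = sm.Logit(toy_bivariable.outcomes, X).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-4)
        np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-4)

    def test_row_order_invariance(self, toy_univariable, rng):
        model_a = fit_logistic(toy_univariable)
        perm = rng.permutation(toy_univariable.n)
        shuffled = Dataset(
            toy_univariable.outcomes[perm],
            toy_univariable.covariates[perm],
            toy_univariable.predictor_names,
        )
        model_b = fit_logistic(shuffled)
        assert model_a.intercept == pytest.approx(model_b.intercept, abs=1e-8)
        np.testing.assert_allclose(model_a.coefficients, model_b.coefficients, atol=1e-8)

    def test_degenerate_outcomes_rejected(self):
        ds = Dataset(np.ones(20), np.arange(20.0)[:, None], ["x"])
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(ds)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        ds = Dataset(y, np.column_stack([x, 2.0 * x]), ["a", "b"])
        with pytest.raises(CollinearPredictorsError):
            fit_logistic(ds)

    def test_separation_returns_finite_flagged_fit(self):
        # complete separation: slope runs off; fit must stay finite and be
        # flagged, and the linear predictor must still rank subjects correctly
        x = np.concatenate([np.linspace(-2, -1, 10), np.linspace(1, 2, 10)])
        y = np.concatenate([np.zeros(10), np.ones(10)])
        ds = Dataset(y, x[:, None], ["x"])
        model = fit_logistic(ds)
        assert np.isfinite(model.intercept)
        assert np.isfinite(model.coefficients).all()
        assert model.coefficients[0] > 0


class TestLinearPredictor:
    def test_constant_model(self):
        ds = Dataset(np.array([0.0, 1.0, 1.0]), np.ones((3, 1)), ["x"])
        model = FittedModel(-1.2, np.array([0.0]), ["x"])
        np.testing.assert_allclose(linear_predictor(model, ds), [-1.2] * 3)

    def test_hand_arithmetic(self):
        ds = Dataset(np.array([0.0, 1.0]), np.array([[0.0], [1.0]]), ["x"])
        model = FittedModel(0.5, np.array([2.0]), ["x"])
        np.testing.assert_allclose(linear_predictor(model, ds), [0.5, 2.5])

    def test_matrix_product_oracle(self, rng):
        # lp_V = X_V beta_D with the development model's coefficients
        X = rng.normal(size=(5, 2))
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        val = Dataset(y, X, ["a", "b"])
        model = FittedModel(0.7, np.array([1.1, -2.2]), ["a", "b"])
        np.testing.assert_allclose(
            linear_predictor(model, val), 0.7 + X @ np.array([1.1, -2.2]), atol=1e-12
        )

    def test_affine_in_intercept(self, toy_univariable):
        model = fit_logistic(toy_univariable)
        shifted = FittedModel(
            model.intercept + 3.5, model.coefficients, model.predictor_names
        )
        np.testing.assert_allclose(
            linear_predictor(shifted, toy_univariable),
            linear_predictor(model, toy_univariable) + 3.5,
            atol=1e-12,
        )

    def test_name_mismatch(self, toy_univariable):
        model = FittedModel(0.0, np.array([1.0]), ["not_there"])
        with pytest.raises(SpecMismatchError):
            linear_predictor(model, toy_univariable)


class TestPredictProbability:
    def test_formula_oracle_and_bounds(self, rng):
        X = rng.normal(size=(10, 1))
        ds = Dataset((rng.random(10) < 0.5).astype(float), X, ["x"])
        model = FittedModel(0.0, np.array([0.8]), ["x"])
        lp = linear_predictor(model, ds)
        np.testing.assert_allclose(
            predict_probability(model, ds), 1.0 / (1.0 + np.exp(-lp)), atol=1e-12
        )

    def test_zero_lp_gives_half(self):
        ds = Dataset(np.array([0.0, 1.0]), np.zeros((2, 1)), ["x"])
        model = FittedModel(0.0, np.array([5.0]), ["x"])
        np.testing.assert_allclose(predict_probability(model, ds), [0.5, 0.5])

    def test_saturation_stays_inside_unit_interval(self):
        ds = Dataset(np.array([0.0, 1.0]), np.array([[-1e4], [1e4]]), ["x"])
        model = FittedModel(0.0, np.array([10.0]), ["x"])
        p = predict_probability(model, ds)
        assert np.isfinite(p).all()
        assert (p > 0.0).all() and (p < 1.0).all()


def test_spec_subset_of_columns(toy_bivariable):
    spec = ModelSpec(["x2"])
    model = fit_logistic(toy_bivariable, spec)
    assert model.predictor_names == ["x2"]
    assert len(model.coefficients) == 1
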