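"""Logistic regression machinery: fitting, linear predictors, probabilities.

The fitter is a Newton/IRLS solver with a tiny ridge penalty on the slopes
(never the intercept).  The penalty (default 1e-6) exists purely to
stabilize fits under complete or quasi-separation, which occurs with small
samples and strong effects; it is orders of magnitude below any level that
would shift the rank- and spread-based quantities computed downstream
(c-statistics, SDs of the linear predictor).  A hand-written solver is used
because the permutation test refits the model hundreds of thousands of
times in a simulation study, and because the slope-only penalty is part of
the fitting contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import Dataset
from .exceptions import (
    CollinearPredictorsError,
    DegenerateOutcomeError,
    SpecMismatchError,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_logistic",
    "linear_predictor",
    "predict_probability",
]

#: L2 strength applied to slopes (not the intercept) during fitting.
DEFAULT_RIDGE = 1e-6
#: Newton/IRLS iteration cap; hitting it flags ``converged=False``.
MAX_ITER = 100
#: Convergence tolerance on the max absolute Newton step.
TOL = 1e-10


@dataclass
class ModelSpec:
    """Which predictors enter the model, in which order.

    The intercept is included by default; the simulated data-generating
    process has none, but fitted prediction models conventionally estimate
    one (see the methods note).
    """

    predictor_names: list[str]
    include_intercept: bool = True

    def __post_init__(self) -> None:
        self.predictor_names = [str(nm) for nm in self.predictor_names]
        if not self.predictor_names:
            raise SpecMismatchError("a model needs at least one predictor")

    @classmethod
    def for_dataset(cls, data: Dataset) -> "ModelSpec":
        return cls(list(data.predictor_names))


@dataclass
class FittedModel:
    """Estimated intercept and slopes of a logistic model."""

    intercept: float
    coefficients: np.ndarray
    predictor_names: list[str]
    converged: bool = True
    n_used: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if len(self.coefficients) != len(self.predictor_names):
            raise SpecMismatchError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.predictor_names)} predictor names"
            )

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": dict(zip(self.predictor_names, map(float, self.coefficients))),
            "converged": bool(self.converged),
            "n_used": int(self.n_used),
        }


# ---------------------------------------------------------------------------
# Core solver on raw arrays (hot path for the permutation engine)
# ---------------------------------------------------------------------------

def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    penalize: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS on a ready-made design matrix.

    ``penalize`` marks columns receiving the ridge penalty (slopes);
    unmarked columns (the intercept) are unpenalized.  Returns the
    coefficient vector and a convergence flag.  Under separation the slope
    grows until the flat penalized likelihood stalls Newton or the
    iteration cap is hit; either way the last finite iterate is returned
    with ``converged=False`` when the cap was the stopping rule.
    """
    n, q = X.shape
    if penalize is None:
        penalize = np.ones(q, dtype=bool)
    pen = np.where(penalize, ridge, 0.0)
    beta = np.zeros(q)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        g = X.T @ (y - p) - pen * beta
        H = (X * w[:, None]).T @ X
        H[np.arange(q), np.arange(q)] += pen
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break  # weights collapsed under separation; keep last iterate
        if not np.isfinite(step).all():
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged


def _design(data: Dataset, spec: ModelSpec) -> np.ndarray:
    X = data.matrix(spec.predictor_names)
    if spec.include_intercept:
        return np.column_stack([np.ones(len(X)), X])
    return X


def fit_logistic(
    data: Dataset,
    spec: ModelSpec | None = None,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> FittedModel:
    """Fit a logistic regression model by (lightly penalized) ML.

    Parameters
    ----------
    data
        Cohort with at least one event and one non-event.
    spec
        Predictors to use; defaults to all columns of ``data`` with an
        intercept.
    ridge
        L2 strength on slopes only (intercept never penalized).

    Raises
    ------
    DegenerateOutcomeError
        All-zero or all-one outcomes.
    CollinearPredictorsError
        Rank-deficient design (e.g. constant or duplicated predictors).
    """
    if spec is None:
        spec = ModelSpec.for_dataset(data)
    y = data.outcomes
    n_events = int(y.sum())
    if n_events == 0 or n_events == data.n:
        raise DegenerateOutcomeError(
            f"outcomes are all {int(y[0])}; logistic fit undefined"
        )
    X = _design(data, spec)
    n, q = X.shape
    if q > n:
        raise CollinearPredictorsError(f"more parameters ({q}) than rows ({n})")
    if np.linalg.matrix_rank(X) < q:
        raise CollinearPredictorsError(
            "rank-deficient design matrix (collinear or constant predictors)"
        )
    penalize = np.ones(q, dtype=bool)
    if spec.include_intercept:
        penalize[0] = False
    beta, converged = _irls(X, y, ridge=ridge, max_iter=max_iter, tol=tol, penalize=penalize)
    if spec.include_intercept:
        intercept, slopes = float(beta[0]), beta[1:]
    else:
        intercept, slopes = 0.0, beta
    return FittedModel(
        intercept=intercept,
        coefficients=slopes,
        predictor_names=list(spec.predictor_names),
        converged=converged,
        n_used=n,
    )


def linear_predictor(model: FittedModel, data: Dataset) -> np.ndarray:
    """lp_i = intercept + x_i . beta, with columns matched by name.

    Applying a development-fitted model to validation covariates yields
    lp_V = X_V beta_D, the case-mix-bearing quantity compared across
    samples.
    """
    try:
        X = data.matrix(model.predictor_names)
    except Exception as exc:
        raise SpecMismatchError(
            f"dataset columns {data.predictor_names} do not cover model "
            f"predictors {model.predictor_names}"
        ) from exc
    return model.intercept + X @ model.coefficients


def predict_probability(model: FittedModel, data: Dataset) -> np.ndarray:
    """Element-wise inverse-logit of the linear predictor, in (0, 1).

    Values are nudged away from exact 0/1 (float saturation under huge
    |lp|) so Bernoulli resampling and log-scores stay well defined.
    """
    p = expit(linear_predictor(model, data))
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - 1e-16)
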