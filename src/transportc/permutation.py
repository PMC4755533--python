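"""Permutation test of development/validation homogeneity.

The test asks whether the observed validation c-statistic c^V is unusually
low relative to what re-splitting the pooled subjects would produce: all
n_D + n_V subjects are pooled, randomly reassigned into sets of the
original sizes, the model is refitted on each permuted development set and
scored on the matching permuted validation set.  The p-value is the plain
proportion of permuted c-statistics strictly below c^V — one-sided, no
smoothing — so p can legitimately be exactly 0 or 1.

The test is blind to case-mix: a validation sample with a genuinely
narrower predictor spread but perfectly valid coefficients lowers c^V
below every permuted value and drives p toward 0, while weaker
coefficients hidden behind a wider case-mix can leave p unremarkable.
Quantifying that failure mode is what the simulation engine is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .concordance import _c_from_arrays, c_statistic
from .data import Dataset
from .exceptions import DataValidationError, DegenerateOutcomeError
from .logistic import FittedModel, ModelSpec, _irls, fit_logistic, linear_predictor

__all__ = ["PermutationResult", "permutation_test", "rejection_rate"]

#: Hard cap on redraws of degenerate permuted splits, as a multiple of k.
_MAX_REDRAW_FACTOR = 100


@dataclass
class PermutationResult:
    """Observed c^V, the permuted reference distribution, and the verdict."""

    c_observed: float
    permuted_c: np.ndarray
    p_value: float
    k: int
    alpha: float
    reject: bool
    n_redraws: int = 0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.permuted_c = np.asarray(self.permuted_c, dtype=float)


def permutation_test(
    dev: Dataset,
    val: Dataset,
    spec: ModelSpec | None = None,
    k: int = 1000,
    alpha: float = 0.05,
    rng=None,
    rng_seed: int | None = None,
    model: FittedModel | None = None,
) -> PermutationResult:
    """Run the homogeneity permutation test.

    Parameters
    ----------
    dev, val
        Development and validation cohorts sharing the spec's predictors.
    spec
        Model specification; defaults to all development predictors.
    k
        Number of permutations (1000 in typical use).
    alpha
        Decision threshold; the null of homogeneity is rejected when
        p < alpha.
    rng, rng_seed
        A numpy Generator, or a seed; ``rng`` wins if both given.
    model
        Optionally a model already fitted on ``dev`` (skips one fit).

    Notes
    -----
    Permutations preserve the original group sizes.  A permuted split in
    which either side has all-0 or all-1 outcomes (unfittable, or c
    undefined) is redrawn and counted; a warning is emitted when more than
    1% of rounds needed a redraw.
    """
    if k < 1:
        raise DataValidationError(f"k must be >= 1, got {k}")
    if not 0.0 < alpha < 1.0:
        raise DataValidationError(f"alpha must be in (0, 1), got {alpha}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    if spec is None:
        spec = ModelSpec.for_dataset(dev)
    if model is None:
        model = fit_logistic(dev, spec)
    c_obs = c_statistic(linear_predictor(model, val), val.outcomes)

    # Pooled arrays, built once; the loop only permutes row indices.
    X_pool = np.vstack([dev.matrix(spec.predictor_names), val.matrix(spec.predictor_names)])
    if spec.include_intercept:
        X_pool = np.column_stack([np.ones(len(X_pool)), X_pool])
    y_pool = np.concatenate([dev.outcomes, val.outcomes])
    n_total = y_pool.shape[0]
    n_events = y_pool.sum()
    if n_events == 0 or n_events == n_total:
        raise DegenerateOutcomeError("pooled outcomes are all identical")
    n_dev = dev.n
    penalize = np.ones(X_pool.shape[1], dtype=bool)
    if spec.include_intercept:
        penalize[0] = False

    permuted_c = np.empty(k)
    n_redraws = 0
    for i in range(k):
        while True:
            idx = rng.permutation(n_total)
            y_d = y_pool[idx[:n_dev]]
            y_v = y_pool[idx[n_dev:]]
            s_d, s_v = y_d.sum(), y_v.sum()
            if 0 < s_d < n_dev and 0 < s_v < n_total - n_dev:
                break
            n_redraws += 1
            if n_redraws > _MAX_REDRAW_FACTOR * k:
                raise DegenerateOutcomeError(
                    "could not draw a non-degenerate permutation; outcomes too unbalanced"
                )
        beta, _ = _irls(X_pool[idx[:n_dev]], y_d, penalize=penalize)
        lp_v = X_pool[idx[n_dev:]] @ beta
        permuted_c[i] = _c_from_arrays(lp_v, y_v)

    if n_redraws > 0.01 * k:
        warnings.warn(
            f"{n_redraws} degenerate permuted splits redrawn over {k} rounds",
            RuntimeWarning,
            stacklevel=2,
        )
    p_value = float(np.count_nonzero(permuted_c < c_obs)) / k
    return PermutationResult(
        c_observed=c_obs,
        permuted_c=permuted_c,
        p_value=p_value,
        k=k,
        alpha=alpha,
        reject=bool(p_value < alpha),
        n_redraws=n_redraws,
        rng_seed=rng_seed,
    )


def rejection_rate(results) -> float:
    """Fraction of permutation tests that rejected homogeneity."""
    results = list(results)
    if not results:
        raise DataValidationError("empty collection of permutation results")
    alphas = {r.alpha for r in results}
    if len(alphas) > 1:
        raise DataValidationError(f"mixed alpha levels: {sorted(alphas)}")
    return float(np.mean([r.reject for r in results]))
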