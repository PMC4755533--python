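"""The c-statistic and case-mix heterogeneity measures.

The c-statistic (concordance; AUC for binary outcomes) is computed from
midranks via the Mann-Whitney identity — O(n log n), which matters because
the permutation test evaluates it for every permuted refit.  Case-mix
heterogeneity is summarized by the standard deviation of the linear
predictor: a population whose subjects span a wider risk range has a
larger SD and, other things equal, a more discriminable outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import rankdata

from .data import Dataset
from .exceptions import DataValidationError, UndefinedCStatisticError
from .logistic import FittedModel, linear_predictor

__all__ = ["c_statistic", "sd_linear_predictor", "CasemixSummary", "casemix_summary"]


def _c_from_arrays(scores: np.ndarray, outcomes: np.ndarray) -> float:
    # Mann-Whitney with midranks: ties between an event and a non-event
    # score count 1/2.
    n = scores.shape[0]
    n1 = int(outcomes.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedCStatisticError(
            "c-statistic needs at least one event and one non-event"
        )
    r = rankdata(scores)
    u = r[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def c_statistic(scores, outcomes) -> float:
    """Concordance probability of ``scores`` for binary ``outcomes``.

    The proportion of event/non-event pairs in which the event subject has
    the higher score, with ties counted as 1/2.  Equals the area under the
    ROC curve.

    Raises
    ------
    UndefinedCStatisticError
        If outcomes contain no events or no non-events.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise DataValidationError("scores and outcomes must be 1-d and equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataValidationError("outcomes must be 0/1")
    return _c_from_arrays(s, y)


def sd_linear_predictor(lp) -> float:
    """Sample standard deviation (denominator n-1) of a linear predictor."""
    lp = np.asarray(lp, dtype=float)
    if lp.ndim != 1 or lp.shape[0] < 2:
        raise DataValidationError("need at least 2 values for an SD")
    if lp.max() == lp.min():  # exactly constant; avoid summation round-off
        return 0.0
    return float(np.std(lp, ddof=1))


@dataclass
class CasemixSummary:
    """Linear-predictor SDs in both samples, and their ratio.

    Both SDs use the development model's coefficients; the ratio is
    validation over development, so values below 1 indicate a narrower
    (more homogeneous) validation case-mix.
    """

    sd_lp_dev: float
    sd_lp_val: float

    @property
    def ratio(self) -> float:
        if self.sd_lp_dev == 0.0:
            return float("nan")
        return self.sd_lp_val / self.sd_lp_dev


def casemix_summary(model: FittedModel, dev: Dataset, val: Dataset) -> CasemixSummary:
    """SD of lp in development and validation under the development model."""
    sd_dev = sd_linear_predictor(linear_predictor(model, dev))
    sd_val = sd_linear_predictor(linear_predictor(model, val))
    if sd_dev == 0.0:
        warnings.warn(
            "development linear predictor is constant; SD ratio undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return CasemixSummary(sd_lp_dev=sd_dev, sd_lp_val=sd_val)
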