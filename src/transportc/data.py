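"""Cohort container and CSV input.

A :class:`Dataset` is the unit on which models are fitted and validated: a
binary outcome vector plus a numeric predictor matrix.  Missing values are
rejected at load time — never silently dropped — so that every downstream
quantity refers to the full cohort the user supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    MissingColumnError,
    MissingValueError,
    NonBinaryOutcomeError,
)

__all__ = ["Dataset", "read_dataset_csv"]


@dataclass
class Dataset:
    """A cohort: binary outcomes and an n x p matrix of numeric predictors.

    Parameters
    ----------
    outcomes
        Length-n vector of 0/1 outcome indicators.
    covariates
        n x p array of predictor values, no missing entries.
    predictor_names
        p column labels, aligned with the covariate columns.
    sample_label
        Optional tag, conventionally ``"development"`` or ``"validation"``.
    """

    outcomes: np.ndarray
    covariates: np.ndarray
    predictor_names: list[str]
    sample_label: str | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes, dtype=float)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise DataValidationError("covariates must be a 2-d array")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise DataValidationError(
                f"outcome length {y.shape[0] if y.ndim == 1 else y.shape} does not "
                f"match covariate row count {X.shape[0]}"
            )
        if np.isnan(y).any() or np.isnan(X).any():
            raise MissingValueError("missing values in outcomes or covariates")
        if not np.isfinite(X).all():
            raise DataValidationError("non-finite covariate values")
        if not np.isin(y, (0.0, 1.0)).all():
            bad = sorted(set(np.unique(y)) - {0.0, 1.0})
            raise NonBinaryOutcomeError(f"non-binary outcome values: {bad}")
        names = [str(nm) for nm in self.predictor_names]
        if len(names) != X.shape[1]:
            raise DataValidationError(
                f"{len(names)} predictor names for {X.shape[1]} covariate columns"
            )
        if len(set(names)) != len(names):
            raise DataValidationError("duplicate predictor names")
        self.outcomes = y
        self.covariates = X
        self.predictor_names = names

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of subjects."""
        return self.outcomes.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n_predictors(self) -> int:
        return self.covariates.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.predictor_names.index(name)
        except ValueError:
            raise MissingColumnError(f"predictor {name!r} not in dataset") from None
        return self.covariates[:, j]

    def matrix(self, names: list[str]) -> np.ndarray:
        """Covariate sub-matrix in the requested column order."""
        missing = [nm for nm in names if nm not in self.predictor_names]
        if missing:
            raise MissingColumnError(f"predictors not in dataset: {missing}")
        idx = [self.predictor_names.index(nm) for nm in names]
        return self.covariates[:, idx]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        outcome_column: str,
        predictor_columns: list[str],
        sample_label: str | None = None,
    ) -> "Dataset":
        """Build a Dataset from a DataFrame, validating the used columns."""
        missing = [c for c in [outcome_column, *predictor_columns] if c not in frame.columns]
        if missing:
            raise MissingColumnError(f"columns not found: {missing}")
        used = frame[[outcome_column, *predictor_columns]]
        n_bad = int(used.isna().any(axis=1).sum())
        if n_bad:
            rows = used.index[used.isna().any(axis=1)].tolist()[:10]
            raise MissingValueError(
                f"{n_bad} row(s) with missing values in used columns "
                f"(first offending rows: {rows}); remove or impute them explicitly"
            )
        try:
            y = used[outcome_column].to_numpy(dtype=float)
            X = used[predictor_columns].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"non-numeric values in used columns: {exc}") from exc
        return cls(y, X, list(predictor_columns), sample_label=sample_label)

    def to_dataframe(self, outcome_column: str = "outcome") -> pd.DataFrame:
        out = pd.DataFrame(self.covariates, columns=self.predictor_names)
        out.insert(0, outcome_column, self.outcomes.astype(int))
        return out


def read_dataset_csv(
    path,
    outcome_column: str,
    predictor_columns: list[str],
    sample_label: str | None = None,
) -> Dataset:
    """Read a cohort from CSV (header row, ``.`` decimal separator).

    Rows with missing values in the used columns are rejected with a count,
    never dropped silently.
    """
    frame = pd.read_csv(path)
    return Dataset.from_dataframe(
        frame, outcome_column, predictor_columns, sample_label=sample_label
    )
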