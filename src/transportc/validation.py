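"""External-validation orchestration: the model/results pair.

:class:`ExternalValidation` bundles a development and a validation cohort
with a model specification; :meth:`ExternalValidation.fit` develops the
logistic model, validates it externally, and returns
:class:`ExternalValidationResults` carrying the full panel a validation
report needs: the apparent and external c-statistics, the case-mix
measures (SDs of the linear predictor and their ratio), the benchmark
c-statistics (mbc, c^refitted) and the permutation-test p-value — plus the
provenance (seeds, k, repetitions) required to reproduce the run.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import logging

import numpy as np
import pandas as pd

from .benchmarks import model_based_c, refitted_c
from .concordance import c_statistic, casemix_summary
from .data import Dataset, read_dataset_csv
from .logistic import FittedModel, ModelSpec, fit_logistic, linear_predictor
from .permutation import permutation_test

__all__ = ["ExternalValidation", "ExternalValidationResults", "ValidationReport", "validate_external"]

logger = logging.getLogger("transportc")


class ExternalValidation:
    """An external-validation exercise: develop on one cohort, test on another.

    Parameters
    ----------
    dev, val
        Development and validation cohorts.  Both must contain the
        predictors named in ``spec``.
    spec
        Model specification; defaults to all development predictors with
        an intercept.

    Examples
    --------
    >>> ev = ExternalValidation.from_dataframes(dev_df, val_df, "death", ["age", "motor"])
    >>> res = ev.fit(k=1000, n_reps=100, seed=42)
    >>> print(res.summary())
    """

    def __init__(self, dev: Dataset, val: Dataset, spec: ModelSpec | None = None):
        self.dev = dev
        self.val = val
        self.spec = spec if spec is not None else ModelSpec.for_dataset(dev)
        # fail early on incompatible columns
        dev.matrix(self.spec.predictor_names)
        val.matrix(self.spec.predictor_names)

    @classmethod
    def from_dataframes(
        cls,
        dev_frame: pd.DataFrame,
        val_frame: pd.DataFrame,
        outcome_column: str,
        predictor_columns: list[str],
    ) -> "ExternalValidation":
        dev = Dataset.from_dataframe(dev_frame, outcome_column, predictor_columns, "development")
        val = Dataset.from_dataframe(val_frame, outcome_column, predictor_columns, "validation")
        return cls(dev, val)

    @classmethod
    def from_csv(
        cls,
        dev_path,
        val_path,
        outcome_column: str,
        predictor_columns: list[str],
    ) -> "ExternalValidation":
        dev = read_dataset_csv(dev_path, outcome_column, predictor_columns, "development")
        val = read_dataset_csv(val_path, outcome_column, predictor_columns, "validation")
        return cls(dev, val)

    def fit(
        self,
        k: int = 1000,
        n_reps: int = 100,
        alpha: float = 0.05,
        permutation: bool = True,
        seed: int | None = None,
        study_label: str | None = None,
    ) -> "ExternalValidationResults":
        """Develop, validate, benchmark and (optionally) permutation-test.

        Parameters
        ----------
        k
            Number of permutations for the homogeneity test.
        n_reps
            Outcome-resimulation repetitions per subject for the mbc.
        alpha
            Permutation-test decision threshold.
        permutation
            Skip the (expensive) permutation test when False.
        seed
            Master seed; all randomness (mbc resimulation, permutations)
            flows from it.
        """
        rng = np.random.default_rng(seed)
        model = fit_logistic(self.dev, self.spec)
        if not model.converged:
            logger.warning("development fit hit the iteration cap (possible separation)")
        lp_dev = linear_predictor(model, self.dev)
        lp_val = linear_predictor(model, self.val)
        c_dev = c_statistic(lp_dev, self.dev.outcomes)
        c_val = c_statistic(lp_val, self.val.outcomes)
        cm = casemix_summary(model, self.dev, self.val)
        mbc = model_based_c(model, self.val, n_reps=n_reps, rng=rng)
        c_refit = refitted_c(self.val, self.spec)
        perm_p = reject = perm_redraws = None
        if permutation:
            perm = permutation_test(
                self.dev, self.val, self.spec, k=k, alpha=alpha, rng=rng, model=model
            )
            perm_p, reject, perm_redraws = perm.p_value, perm.reject, perm.n_redraws
            logger.info("permutation test: p=%.3f (%d redraws)", perm_p, perm_redraws)
        logger.info(
            "external validation: c_dev=%.3f c_val=%.3f ratio=%.3f mbc=%.3f c_refitted=%.3f",
            c_dev, c_val, cm.ratio, mbc, c_refit,
        )
        return ExternalValidationResults(
            study_label=study_label,
            model=model,
            c_dev=c_dev,
            c_val=c_val,
            sd_lp_dev=cm.sd_lp_dev,
            sd_lp_val=cm.sd_lp_val,
            ratio=cm.ratio,
            mbc=mbc,
            c_refitted=c_refit,
            perm_p=perm_p,
            reject=reject,
            perm_redraws=perm_redraws,
            k=k if permutation else None,
            n_reps=n_reps,
            alpha=alpha,
            seed=seed,
        )


@dataclass
class ExternalValidationResults:
    """Full panel of one external validation (one report row).

    ``perm_p``/``reject`` are None when the permutation test was skipped;
    every other field is always present.
    """

    model: FittedModel
    c_dev: float
    c_val: float
    sd_lp_dev: float
    sd_lp_val: float
    ratio: float
    mbc: float
    c_refitted: float
    n_reps: int
    alpha: float
    perm_p: float | None = None
    reject: bool | None = None
    perm_redraws: int | None = None
    k: int | None = None
    seed: int | None = None
    study_label: str | None = None

    def summary(self) -> str:
        """Human-readable report, one line per quantity."""
        w = 46
        lines = []
        title = "External validation" + (f": {self.study_label}" if self.study_label else "")
        lines.append(title)
        lines.append("=" * (w + 10))
        coef = ", ".join(
            f"{nm}={b:+.4f}" for nm, b in zip(self.model.predictor_names, self.model.coefficients)
        )
        lines.append(f"{'Model (development fit)':<{w}} intercept={self.model.intercept:+.4f}, {coef}")
        if not self.model.converged:
            lines.append(f"{'':<{w}} WARNING: iteration cap hit (separation?)")
        lines.append(f"{'c-statistic, development (apparent)':<{w}} {self.c_dev:.3f}")
        lines.append(f"{'c-statistic, external validation (c_V)':<{w}} {self.c_val:.3f}")
        lines.append(f"{'SD linear predictor, development':<{w}} {self.sd_lp_dev:.3f}")
        lines.append(f"{'SD linear predictor, validation':<{w}} {self.sd_lp_val:.3f}")
        lines.append(f"{'SD ratio (validation / development)':<{w}} {self.ratio:.3f}")
        lines.append(f"{'Model-based c-statistic (mbc)':<{w}} {self.mbc:.3f}")
        lines.append(f"{'Refitted c-statistic (c_refitted)':<{w}} {self.c_refitted:.3f}")
        if self.perm_p is not None:
            lines.append(f"{'Permutation test p-value':<{w}} {self.perm_p:.3f}  (k={self.k})")
            verdict = "rejected" if self.reject else "not rejected"
            lines.append(f"{'Homogeneity null (alpha=%.2f)' % self.alpha:<{w}} {verdict}")
        lines.append("-" * (w + 10))
        lines.append(
            f"mbc - c_V = {self.mbc - self.c_val:+.3f} (coefficient validity); "
            f"SD ratio = {self.ratio:.2f} (case-mix)"
        )
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "study_label": self.study_label,
            "model": self.model.to_dict(),
            "c_dev": self.c_dev,
            "c_val": self.c_val,
            "sd_lp_dev": self.sd_lp_dev,
            "sd_lp_val": self.sd_lp_val,
            "ratio": self.ratio,
            "mbc": self.mbc,
            "c_refitted": self.c_refitted,
            "perm_p": self.perm_p,
            "reject": self.reject,
            "perm_redraws": self.perm_redraws,
            "k": self.k,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "ExternalValidationResults":
        m = payload["model"]
        model = FittedModel(
            intercept=m["intercept"],
            coefficients=np.array(list(m["coefficients"].values()), dtype=float),
            predictor_names=list(m["coefficients"].keys()),
            converged=m["converged"],
            n_used=m["n_used"],
        )
        fields = {k: v for k, v in payload.items() if k != "model"}
        return cls(model=model, **fields)

    @classmethod
    def from_json(cls, source) -> "ExternalValidationResults":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls.from_dict(payload)


#: Alias matching report-oriented naming.
ValidationReport = ExternalValidationResults


def validate_external(
    dev: Dataset,
    val: Dataset,
    spec: ModelSpec | None = None,
    k: int = 1000,
    n_reps: int = 100,
    alpha: float = 0.05,
    permutation: bool = True,
    seed: int | None = None,
    study_label: str | None = None,
) -> ExternalValidationResults:
    """One-call external validation (functional facade over the class API)."""
    return ExternalValidation(dev, val, spec).fit(
        k=k,
        n_reps=n_reps,
        alpha=alpha,
        permutation=permutation,
        seed=seed,
        study_label=study_label,
    )
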