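"""Simulation engine: scenario generation, replicates, and study summaries.

Data are generated from a single-predictor logistic model without
intercept: x ~ N(0, sigma_j^2), y ~ Bernoulli(logit^-1(beta_j x)), with
(sigma, beta) set separately for the development and validation samples.
Three canonical scenario rows are provided:

====================================  =======  =======  ======  ======
scenario                              sigma_D  sigma_V  beta_D  beta_V
====================================  =======  =======  ======  ======
Homogeneous populations                  1        1        3       3
Different case-mix & predictor           1        1.5      3       2
effects
Different case-mix & same predictor      1        0.75     3       3
effects
====================================  =======  =======  ======  ======

crossed with per-sample sizes n in {40, 100, 200} (nine cells).  Because x
is symmetric about 0 and there is no intercept, the event rate is 50% in
every cell, so n = 40/100/200 corresponds to roughly 20/50/100 events per
fitted variable.

Each replicate draws a fresh development/validation pair, fits the model
on the development sample, and computes the full panel of validation
metrics; a study aggregates medians, interquartile ranges and the
permutation-test rejection proportion over replicates.  Replicates run on
independent child streams spawned from one seed, so any single replicate
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .benchmarks import model_based_c, refitted_c
from .concordance import c_statistic, casemix_summary
from .data import Dataset
from .exceptions import DataValidationError
from .logistic import ModelSpec, fit_logistic, linear_predictor
from .permutation import permutation_test

__all__ = [
    "ScenarioConfig",
    "ReplicateResult",
    "MetricSummary",
    "SimulationSummary",
    "SCENARIO_ROWS",
    "table1_grid",
    "generate_scenario_pair",
    "run_replicate",
    "summarize_replicates",
    "run_study",
]

#: Metrics carried by every replicate, in reporting order.
METRICS = ("c_dev", "c_val", "sd_lp_dev", "sd_lp_val", "ratio", "mbc", "c_refitted")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell: generator parameters and per-sample sizes."""

    sigma_dev: float
    sigma_val: float
    beta_dev: float
    beta_val: float
    n_dev: int
    n_val: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma_dev <= 0 or self.sigma_val <= 0:
            raise DataValidationError("predictor SDs must be strictly positive")
        if self.n_dev < 10 or self.n_val < 10:
            raise DataValidationError("sample sizes below 10 are not supported")


#: The three canonical parameter rows (sigma_dev, sigma_val, beta_dev, beta_val).
SCENARIO_ROWS: dict[str, tuple[float, float, float, float]] = {
    "Homogeneous populations": (1.0, 1.0, 3.0, 3.0),
    "Different case-mix & predictor effects": (1.0, 1.5, 3.0, 2.0),
    "Different case-mix & same predictor effects": (1.0, 0.75, 3.0, 3.0),
}

#: Per-sample sizes crossed with the scenario rows.
SAMPLE_SIZES = (40, 100, 200)


def scenario(label: str, n: int) -> ScenarioConfig:
    """Named scenario row at per-sample size ``n`` (n_dev = n_val = n)."""
    if label not in SCENARIO_ROWS:
        raise DataValidationError(
            f"unknown scenario {label!r}; choose from {list(SCENARIO_ROWS)}"
        )
    sd_d, sd_v, b_d, b_v = SCENARIO_ROWS[label]
    return ScenarioConfig(sd_d, sd_v, b_d, b_v, n, n, label=label)


def table1_grid() -> list[ScenarioConfig]:
    """The full 3 x 3 grid: scenario rows crossed with n in {40, 100, 200}."""
    return [scenario(label, n) for label in SCENARIO_ROWS for n in SAMPLE_SIZES]


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _draw_sample(
    n: int, sigma: float, beta: float, rng: np.random.Generator, label: str
) -> Dataset:
    x = rng.normal(0.0, sigma, size=n)
    y = (rng.random(n) < _expit(beta * x)).astype(float)
    return Dataset(y, x[:, None], ["x"], sample_label=label)


def generate_scenario_pair(
    config: ScenarioConfig, rng=None
) -> tuple[Dataset, Dataset]:
    """Draw one development/validation pair from the generating model."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dev = _draw_sample(config.n_dev, config.sigma_dev, config.beta_dev, rng, "development")
    val = _draw_sample(config.n_val, config.sigma_val, config.beta_val, rng, "validation")
    return dev, val


@dataclass
class ReplicateResult:
    """Metric panel for one simulated development/validation pair."""

    c_dev: float
    c_val: float
    sd_lp_dev: float
    sd_lp_val: float
    ratio: float
    mbc: float
    c_refitted: float
    perm_p: float | None = None
    reject: bool | None = None
    n_pair_redraws: int = 0


def run_replicate(
    config: ScenarioConfig,
    rng=None,
    with_permutation: bool = False,
    k: int = 1000,
    n_reps: int = 100,
    alpha: float = 0.05,
) -> ReplicateResult:
    """Generate one pair and compute the full validation metric panel.

    A generated pair in which either sample has all-0 or all-1 outcomes
    (possible, if rare, at n = 40) is discarded and redrawn, preserving
    the nominal replicate count; the number of redraws is recorded.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_pair_redraws = 0
    while True:
        dev, val = generate_scenario_pair(config, rng)
        if 0 < dev.n_events < dev.n and 0 < val.n_events < val.n:
            break
        n_pair_redraws += 1
        if n_pair_redraws > 1000:
            raise DataValidationError(
                "persistent degenerate samples; check scenario parameters"
            )
    spec = ModelSpec(["x"])
    model = fit_logistic(dev, spec)
    lp_dev = linear_predictor(model, dev)
    cm = casemix_summary(model, dev, val)
    result = ReplicateResult(
        c_dev=c_statistic(lp_dev, dev.outcomes),
        c_val=c_statistic(linear_predictor(model, val), val.outcomes),
        sd_lp_dev=cm.sd_lp_dev,
        sd_lp_val=cm.sd_lp_val,
        ratio=cm.ratio,
        mbc=model_based_c(model, val, n_reps=n_reps, rng=rng),
        c_refitted=refitted_c(val, spec),
        n_pair_redraws=n_pair_redraws,
    )
    if with_permutation:
        perm = permutation_test(dev, val, spec, k=k, alpha=alpha, rng=rng, model=model)
        result.perm_p = perm.p_value
        result.reject = perm.reject
    return result


@dataclass
class MetricSummary:
    """Median and interquartile range of one metric across replicates."""

    median: float
    q25: float
    q75: float


@dataclass
class SimulationSummary:
    """Study-level aggregation: per-metric medians/IQRs plus rejection rate."""

    config: ScenarioConfig
    n_replicates: int
    metrics: dict[str, MetricSummary]
    rejection_proportion: float | None = None
    k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-metric table for CSV export."""
        rows = [
            {
                "scenario": self.config.label,
                "n_dev": self.config.n_dev,
                "n_val": self.config.n_val,
                "metric": name,
                "median": ms.median,
                "q25": ms.q25,
                "q75": ms.q75,
            }
            for name, ms in self.metrics.items()
        ]
        if self.rejection_proportion is not None:
            rows.append(
                {
                    "scenario": self.config.label,
                    "n_dev": self.config.n_dev,
                    "n_val": self.config.n_val,
                    "metric": "rejection_proportion",
                    "median": self.rejection_proportion,
                    "q25": float("nan"),
                    "q75": float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "scenario": self.config.label,
            "n_dev": self.config.n_dev,
            "n_val": self.config.n_val,
            "n_replicates": self.n_replicates,
            "metrics": {
                name: {"median": ms.median, "q25": ms.q25, "q75": ms.q75}
                for name, ms in self.metrics.items()
            },
        }
        if self.rejection_proportion is not None:
            out["rejection_proportion"] = self.rejection_proportion
            out["k"] = self.k
        return out


def summarize_replicates(
    results: list[ReplicateResult],
    config: ScenarioConfig | None = None,
    k: int | None = None,
) -> SimulationSummary:
    """Aggregate a list of replicate panels into medians, IQRs, rejection rate."""
    if len(results) < 2:
        raise DataValidationError("need at least 2 replicates to summarize")
    metrics: dict[str, MetricSummary] = {}
    for name in METRICS:
        values = np.array([getattr(r, name) for r in results], dtype=float)
        q25, med, q75 = np.percentile(values, [25.0, 50.0, 75.0])
        metrics[name] = MetricSummary(median=float(med), q25=float(q25), q75=float(q75))
    rejects = [r.reject for r in results if r.reject is not None]
    rejection = float(np.mean(rejects)) if rejects else None
    return SimulationSummary(
        config=config,
        n_replicates=len(results),
        metrics=metrics,
        rejection_proportion=rejection,
        k=k,
    )


def run_study(
    config: ScenarioConfig,
    n_replicates: int = 1000,
    seed=None,
    with_permutation: bool = False,
    k: int = 1000,
    n_reps: int = 100,
    alpha: float = 0.05,
    return_replicates: bool = False,
):
    """Run ``n_replicates`` independent replicates of one scenario cell.

    ``seed`` may be an int or a numpy SeedSequence; per-replicate
    substreams are spawned from it so replicate r is reproducible alone.
    """
    if n_replicates < 2:
        raise DataValidationError("n_replicates must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    results = [
        run_replicate(
            config,
            rng=np.random.default_rng(child),
            with_permutation=with_permutation,
            k=k,
            n_reps=n_reps,
            alpha=alpha,
        )
        for child in children
    ]
    summary = summarize_replicates(results, config=config, k=k if with_permutation else None)
    if return_replicates:
        return summary, results
    return summary
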