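"""Replicated simulation studies: interval-set choice, dataset size, method bias.

Each *experiment* simulates one track dataset per recording interval,
estimates the apparent lifetime per interval with both the survival MLE and
the conventional shifted-mean comparator, and fits the photobleaching model
to each series.  A *study* replicates the experiment with distinct seeds and
summarises the fitted bond lifetimes as mean +/- std, counting failed fits
separately (failed fits are excluded from the moments, as their parameter
values are meaningless).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bleachfit import ApparentLifetimeSeries, fit_characteristic_lifetime
from .exceptions import EstimationError, StudyError
from .simulate import SimulationConfig, simulate_dataset
from .survival import ApparentLifetimeMLE
from .trackdata import ApparentLifetimeEstimate, LifetimeFitResult

__all__ = [
    "INTERVAL_SETS",
    "DATASET_SIZES",
    "ExperimentResult",
    "StudySummary",
    "run_experiment",
    "run_study",
]

# recording-interval sets probing the steep part, the bend and the flat part
# of the tau_app(delta_t) curve for a 10 s lifetime with c_b = 30
INTERVAL_SETS: dict[str, tuple[float, ...]] = {
    "short": (0.05, 0.1, 0.15, 0.25, 0.4),
    "medium": (0.25, 0.5, 1.0, 2.0, 3.0),
    "long": (2.0, 3.0, 4.0, 5.0, 6.0),
}

# tracks per recording interval: small / typical / large experiment
DATASET_SIZES: dict[str, int] = {"small": 50, "medium": 100, "large": 200}

METHODS = ("survival", "conventional")


def _failed_fit(reason: str = "no_convergence") -> LifetimeFitResult:
    return LifetimeFitResult(
        tau_lt=math.nan,
        c_b=math.nan,
        se_tau_lt=math.nan,
        se_c_b=math.nan,
        covariance=np.full((2, 2), math.nan),
        failed=True,
        failure_reason=reason,
    )


@dataclass
class ExperimentResult:
    """Fits (and per-interval estimates) from one simulated experiment."""

    fits: dict[str, LifetimeFitResult]
    estimates: dict[str, list[ApparentLifetimeEstimate]]
    seed: int


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """Simulate one experiment and fit the bond lifetime with both methods.

    Estimation failures at a single recording interval (e.g. an all-censored
    dataset) mark the affected method's fit as failed instead of aborting.
    """
    if len(config.delta_t_set) < 2:
        raise ValueError("need >= 2 recording intervals for the lifetime fit")
    estimates: dict[str, list[ApparentLifetimeEstimate]] = {m: [] for m in METHODS}
    broken: set[str] = set()
    for delta_t in config.delta_t_set:
        dataset = simulate_dataset(config, delta_t)
        for method in METHODS:
            try:
                est = ApparentLifetimeMLE(method=method).fit(dataset).estimate_
                estimates[method].append(est)
            except (EstimationError, ValueError):
                broken.add(method)
    fits: dict[str, LifetimeFitResult] = {}
    for method in METHODS:
        if method in broken or any(e.std_error <= 0 for e in estimates[method]):
            fits[method] = _failed_fit()
            continue
        series = ApparentLifetimeSeries.from_estimates(estimates[method])
        fits[method] = fit_characteristic_lifetime(series)
    return ExperimentResult(fits=fits, estimates=estimates, seed=config.seed)


@dataclass
class StudySummary:
    """Aggregate of a replicated study.

    ``results`` holds one row per experiment and method; ``summary`` one row
    per method with mean/std of the fitted bond lifetime over non-failed
    fits.  With a single experiment the std is reported as 0 and
    ``std_undefined`` is set.
    """

    results: pd.DataFrame
    summary: pd.DataFrame
    n_experiments: int
    std_undefined: bool = False

    def mean_tau_lt(self, method: str = "survival") -> float:
        return float(self.summary.loc[method, "mean_tau_lt"])

    def std_tau_lt(self, method: str = "survival") -> float:
        return float(self.summary.loc[method, "std_tau_lt"])

    def n_failed(self, method: str = "survival") -> int:
        return int(self.summary.loc[method, "n_failed_fits"])


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Distinct, deterministic per-experiment seeds below 2**31."""
    return [(base_seed * 1_000_003 + 7919 * i + i * i) % (2**31) for i in range(n)]


def run_study(
    base_config: SimulationConfig,
    n_experiments: int,
    seeds: Sequence[int] | None = None,
) -> StudySummary:
    """Replicate :func:`run_experiment` and summarise the fitted lifetimes."""
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    if seeds is None:
        seeds = derive_seeds(base_config.seed, n_experiments)
    seeds = list(seeds)
    if len(seeds) != n_experiments:
        raise ValueError("seeds must match n_experiments")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")

    rows = []
    for i, seed in enumerate(seeds):
        result = run_experiment(replace(base_config, seed=seed))
        for method in METHODS:
            fit = result.fits[method]
            rows.append(
                {
                    "experiment": i,
                    "seed": seed,
                    "method": method,
                    "tau_lt": fit.tau_lt,
                    "c_b": fit.c_b,
                    "se_tau_lt": fit.se_tau_lt,
                    "se_c_b": fit.se_c_b,
                    "failed": fit.failed,
                    "failure_reason": fit.failure_reason,
                }
            )
    results = pd.DataFrame(rows)

    summary_rows = []
    any_ok = False
    for method in METHODS:
        sub = results[(results["method"] == method) & (~results["failed"])]
        n_failed = int(n_experiments - len(sub))
        if len(sub):
            any_ok = True
            mean = float(sub["tau_lt"].mean())
            std = float(sub["tau_lt"].std(ddof=1)) if len(sub) > 1 else 0.0
        else:
            mean = math.nan
            std = math.nan
        summary_rows.append(
            {
                "method": method,
                "mean_tau_lt": mean,
                "std_tau_lt": std,
                "n_experiments": n_experiments,
                "n_failed_fits": n_failed,
            }
        )
    if not any_ok:
        raise StudyError("every experiment's fit failed for both methods")
    summary = pd.DataFrame(summary_rows).set_index("method")
    return StudySummary(
        results=results,
        summary=summary,
        n_experiments=n_experiments,
        std_undefined=(n_experiments == 1),
    )
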