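"""Hyperparameter selection and seed-stability analysis for the embedding fit.

The sparsity penalty lambda is selected on a fixed arithmetic grid: one
model is trained per (lambda, seed) combination, the best validation
cross-entropy of each run is averaged over seeds per lambda, and the lambda
with the smallest mean validation loss wins.  Because the fit is
stochastic, the effective dimensionality of the final embedding is itself
examined over repeated runs at the chosen lambda (seed stability).
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .model import TrainingConfig, train, with_params


@dataclass
class GridSearchResult:
    lambdas: list[float]
    losses: pd.DataFrame          # rows: lambda, columns: seed, values: val loss
    mean_losses: dict[float, float]
    best_lambda: float
    runs: int
    skipped: list[tuple[float, int, str]] = field(default_factory=list)


@dataclass
class StabilityResult:
    k_per_run: list[int]
    mean_k: float
    n_runs: int


def lambda_grid(low: float, high: float, step: float) -> list[float]:
    """Inclusive arithmetic grid, rounded to the step's decimal precision."""
    if step <= 0:
        raise ValueError("step must be positive")
    if low > high:
        raise ValueError("low must not exceed high")
    decimals = max(0, -decimal.Decimal(str(step)).as_tuple().exponent)
    n = int(round((high - low) / step))
    return [round(low + i * step, decimals) for i in range(n + 1)]


def grid_search(choices: pd.DataFrame, item_ids: Sequence[str],
                grid: Sequence[float], n_seeds: int,
                config: TrainingConfig = TrainingConfig(),
                base_seed: int = 0) -> GridSearchResult:
    """Train one model per (lambda, seed) and pick the lambda with the
    smallest seed-averaged validation loss.

    Seeds are ``base_seed + 1 .. base_seed + n_seeds``.  A run that raises is
    recorded in ``skipped`` and left out of that lambda's average.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be at least 1")

    seeds = [base_seed + s for s in range(1, n_seeds + 1)]
    losses = pd.DataFrame(np.nan, index=grid, columns=seeds)
    skipped: list[tuple[float, int, str]] = []
    for lam, seed in product(grid, seeds):
        run_config = with_params(config, lam=lam, seed=seed)
        try:
            result = train(choices, item_ids, run_config)
        except Exception as err:  # noqa: BLE001 - a failed run is data, not fatal
            warnings.warn(f"run (lambda={lam}, seed={seed}) failed: {err}",
                          stacklevel=2)
            skipped.append((lam, seed, str(err)))
            continue
        losses.loc[lam, seed] = result.best_validation_loss

    mean_losses = losses.mean(axis=1, skipna=True)
    if mean_losses.isna().all():
        raise RuntimeError("every grid-search run failed")
    best_lambda = float(mean_losses.idxmin())
    return GridSearchResult(
        lambdas=grid,
        losses=losses,
        mean_losses={float(k): float(v) for k, v in mean_losses.items()},
        best_lambda=best_lambda,
        runs=len(grid) * n_seeds,
        skipped=skipped,
    )


def seed_stability(choices: pd.DataFrame, item_ids: Sequence[str],
                   lam: float, n_runs: int,
                   config: TrainingConfig = TrainingConfig(),
                   base_seed: int = 0,
                   seeds: Sequence[int] | None = None) -> StabilityResult:
    """Distribution of the effective dimensionality over repeated fits.

    Trains ``n_runs`` models at a fixed lambda with distinct seeds
    (``base_seed + 1 ..`` unless ``seeds`` is given explicitly) and reports
    each run's post-pruning dimension count and its mean.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    if seeds is None:
        seeds = [base_seed + s for s in range(1, n_runs + 1)]
    elif len(seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")

    k_per_run = []
    for seed in seeds:
        result = train(choices, item_ids, with_params(config, lam=lam, seed=seed))
        k_per_run.append(result.k_effective)
    return StabilityResult(k_per_run=k_per_run,
                           mean_k=float(np.mean(k_per_run)),
                           n_runs=n_runs)
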