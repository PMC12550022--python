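"""Synthetic odd-one-out experiments from a known sparse positive embedding.

Everything downstream (quality control, embedding training, hyperparameter
selection, interpretation) is exercised against data produced here: a
ground-truth non-negative sparse embedding drives the softmax choice rule,
simulated workers answer the trials of a :class:`~sposekit.design.TrialDesign`,
and contaminated worker profiles (speeders, position-biased responders) are
planted to give the exclusion filters something to catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .choice import TripletBatch, triplet_probabilities
from .design import TrialDesign
from .io import CHOICE_COLUMNS

# Reaction-time defaults (log-normal, ms). Compliant workers answer around
# 2 s so that essentially no trial falls under the 900 ms exclusion line;
# speeders sit at a 600 ms median, far inside it.
COMPLIANT_RT = (math.log(2000.0), 0.35)
SPEEDER_RT = (math.log(600.0), 0.35)


@dataclass(frozen=True)
class GroundTruthEmbedding:
    """A known n_items x k_true non-negative embedding used as simulation truth."""

    weights: np.ndarray
    item_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        if len(self.item_ids) != self.weights.shape[0]:
            raise ValueError("item_ids length must match the number of rows")
        if np.any(self.weights < 0):
            raise ValueError("ground-truth weights must be non-negative")

    @property
    def index(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.item_ids)}

    def gram(self) -> np.ndarray:
        """Item x item dot-product similarity matrix."""
        return self.weights @ self.weights.T


@dataclass(frozen=True)
class WorkerProfile:
    """Behavioral profile of one simulated worker.

    ``kind`` selects the response pathology: ``compliant`` workers follow the
    softmax choice model (with an occasional uniform lapse), ``speeder``
    workers behave like compliant ones but draw implausibly fast reaction
    times, and ``position_biased`` workers click one fixed screen position
    with probability ``bias_strength`` regardless of the stimuli.

    ``rt_params`` are the (mu, sigma) of a log-normal reaction-time
    distribution in ms; the median RT is exp(mu).
    """

    worker_id: str
    kind: str = "compliant"
    lapse_rate: float = 0.05
    rt_params: tuple[float, float] = COMPLIANT_RT
    bias_position: int | None = None
    bias_strength: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in {"compliant", "speeder", "position_biased"}:
            raise ValueError(f"unknown worker kind: {self.kind!r}")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.rt_params[1] <= 0:
            raise ValueError("rt sigma must be positive")
        if self.kind == "position_biased":
            if self.bias_position not in {1, 2, 3}:
                raise ValueError("position_biased workers need bias_position in {1,2,3}")
            if not 0.0 <= self.bias_strength <= 1.0:
                raise ValueError("bias_strength must lie in [0, 1]")

    @classmethod
    def compliant(cls, worker_id: str, lapse_rate: float = 0.05) -> "WorkerProfile":
        return cls(worker_id=worker_id, kind="compliant", lapse_rate=lapse_rate)

    @classmethod
    def speeder(cls, worker_id: str, lapse_rate: float = 0.05) -> "WorkerProfile":
        return cls(worker_id=worker_id, kind="speeder", lapse_rate=lapse_rate,
                   rt_params=SPEEDER_RT)

    @classmethod
    def position_biased(cls, worker_id: str, position: int,
                        strength: float = 0.8) -> "WorkerProfile":
        return cls(worker_id=worker_id, kind="position_biased",
                   bias_position=position, bias_strength=strength)


@dataclass
class SimulatedDataset:
    """Choice table plus the truth and worker profiles that generated it."""

    choices: pd.DataFrame
    truth: GroundTruthEmbedding
    profiles: list[WorkerProfile] = field(default_factory=list)
    design_ref: str = ""


def generate_ground_truth(n_items: int, k_true: int, sparsity: float = 0.5,
                          scale: float = 1.0, seed: int = 0) -> GroundTruthEmbedding:
    """Draw a non-negative sparse ground-truth embedding.

    Nonzero entries are exponential with mean ``scale``; each entry is zeroed
    independently with probability ``sparsity`` (Bernoulli mask).  Rows that
    come out all-zero are redrawn so every item loads on at least one
    dimension.  Same seed and parameters give an identical matrix.

    Parameters
    ----------
    n_items : number of stimuli (>= 3).
    k_true : number of latent dimensions (1 <= k_true <= n_items).
    sparsity : expected fraction of exactly-zero entries, in [0, 1).
    scale : mean of the exponential distribution of nonzero entries (> 0).
    seed : RNG seed.
    """
    if n_items < 3:
        raise ValueError("n_items must be at least 3")
    if not 1 <= k_true <= n_items:
        raise ValueError("k_true must satisfy 1 <= k_true <= n_items")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")

    rng = np.random.default_rng(seed)

    def draw(n_rows: int) -> np.ndarray:
        values = rng.exponential(scale, size=(n_rows, k_true))
        mask = rng.random(size=(n_rows, k_true)) >= sparsity
        return values * mask

    weights = draw(n_items)
    # resample all-zero rows until every item expresses >= 1 dimension
    while True:
        dead = np.flatnonzero(weights.sum(axis=1) == 0)
        if dead.size == 0:
            break
        weights[dead] = draw(dead.size)

    item_ids = tuple(f"item_{i:04d}" for i in range(n_items))
    return GroundTruthEmbedding(weights=weights, item_ids=item_ids, seed=seed)


def choice_distribution(truth: GroundTruthEmbedding,
                        triplet: Sequence[str]) -> np.ndarray:
    """Odd-one-out probabilities for one displayed triplet of item ids.

    Entry m is the probability that the m-th listed item is chosen as the odd
    one out, i.e. the softmax weight of the dot product of the *other* two
    items' embedding rows.  The three entries sum to one.
    """
    if len(triplet) != 3 or len(set(triplet)) != 3:
        raise ValueError("triplet must contain three distinct item ids")
    index = truth.index
    try:
        a, b, c = (index[item] for item in triplet)
    except KeyError as err:
        raise ValueError(f"unknown item id: {err.args[0]!r}") from None
    batch = TripletBatch(*(np.array([i]) for i in (a, b, c)),
                         odd=np.array([0]))
    return triplet_probabilities(truth.weights, batch)[0]


def simulate_dataset(truth: GroundTruthEmbedding, design: TrialDesign,
                     profiles: Sequence[WorkerProfile],
                     seed: int = 0) -> SimulatedDataset:
    """Answer every trial of ``design`` with simulated workers.

    Sets are assigned to workers round-robin in the order the profiles are
    given.  Each trial's response is drawn from the ground-truth choice
    distribution, replaced by a uniform lapse with the worker's
    ``lapse_rate``, or — for position-biased workers — by their preferred
    screen position with probability ``bias_strength``.  Reaction times are
    log-normal per worker.  Fully reproducible under ``seed``.
    """
    trials = design.trials
    if len(trials) == 0:
        raise ValueError("design contains no trials")
    if not profiles:
        raise ValueError("at least one worker profile is required")

    index = truth.index
    stim_cols = trials[["stim_left", "stim_center", "stim_right"]]
    if not bool(stim_cols.isin(set(index)).all(axis=None)):
        raise ValueError("design references items absent from the ground truth")
    a = stim_cols["stim_left"].map(index).to_numpy(dtype=np.int64)
    b = stim_cols["stim_center"].map(index).to_numpy(dtype=np.int64)
    c = stim_cols["stim_right"].map(index).to_numpy(dtype=np.int64)

    rng = np.random.default_rng(seed)
    n = len(trials)
    batch = TripletBatch(a, b, c, odd=np.zeros(n, dtype=np.int64))
    probs = triplet_probabilities(truth.weights, batch)

    # round-robin set -> worker assignment
    set_idx = trials["set_index"].to_numpy()
    unique_sets = np.unique(set_idx)
    worker_of_set = {s: profiles[i % len(profiles)] for i, s in enumerate(unique_sets)}
    trial_profiles = [worker_of_set[s] for s in set_idx]

    lapse = np.array([p.lapse_rate for p in trial_profiles])
    mu = np.array([p.rt_params[0] for p in trial_profiles])
    sigma = np.array([p.rt_params[1] for p in trial_profiles])
    biased = np.array([p.kind == "position_biased" for p in trial_profiles])
    bias_pos = np.array([(p.bias_position or 1) - 1 for p in trial_profiles])
    bias_strength = np.array([p.bias_strength for p in trial_profiles])

    # model-driven choice via inverse CDF over the three probabilities
    u = rng.random(n)
    choice = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    lapse_mask = rng.random(n) < lapse
    choice[lapse_mask] = rng.integers(0, 3, size=int(lapse_mask.sum()))
    bias_mask = biased & (rng.random(n) < bias_strength)
    choice[bias_mask] = bias_pos[bias_mask]

    rt = rng.lognormal(mean=mu, sigma=sigma)

    choices = pd.DataFrame({
        "worker_id": [p.worker_id for p in trial_profiles],
        "set_index": set_idx,
        "trial_index": trials["trial_index"].to_numpy(),
        "stim_left": trials["stim_left"].to_numpy(),
        "stim_center": trials["stim_center"].to_numpy(),
        "stim_right": trials["stim_right"].to_numpy(),
        "choice_position": choice + 1,
        "rt_ms": rt,
    }, columns=CHOICE_COLUMNS)
    return SimulatedDataset(choices=choices, truth=truth,
                            profiles=list(profiles),
                            design_ref=repr(design.params))
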