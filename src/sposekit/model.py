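"""Sparse positive similarity embedding (SPoSE) learned from odd-one-out choices.

The model assigns every stimulus a non-negative weight vector; the dot
product of two vectors is their similarity, and the probability of an
observed odd-one-out choice is the softmax of the three pairwise
similarities of a trial (see :mod:`sposekit.choice`).  Training minimizes
the mean cross-entropy of the observed choices plus an L1 penalty
``lambda * sum(W) / n_items`` with Adam, projecting the weights onto the
non-negative orthant after every update.  A validation split drives early
stopping; after training, dimensions whose total weight falls below a
threshold are removed and the survivors are sorted by descending total
weight.  The number of surviving columns is the model's effective
dimensionality — it is an *output* of the fit, controlled by the sparsity
penalty rather than chosen a priori.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd

from . import choice as _choice
from .choice import TripletBatch


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one embedding fit.

    Defaults follow the standard crowdsourced-triplet setup: 100 starting
    dimensions, lambda 0.008, Adam with learning rate 0.001 and batches of
    128, at most 500 epochs with an early-stopping patience (``window``) of
    50 epochs on validation loss, a 90/10 train/validation split, and a
    pruning threshold of 0.1 on the post-training column sums.
    """

    k_init: int = 100
    lam: float = 0.008
    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 500
    window: int = 50
    validation_fraction: float = 0.1
    prune_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_init < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("k_init, batch_size and max_epochs must be positive")
        if self.lam < 0 or self.learning_rate <= 0 or self.window < 1:
            raise ValueError("lam must be >= 0; learning_rate and window positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class EmbeddingMatrix:
    """n_items x K non-negative weight matrix with item and dimension labels."""

    weights: np.ndarray
    item_ids: tuple[str, ...]
    dim_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.item_ids), len(self.dim_labels)):
            raise ValueError("weights shape does not match labels")
        if np.any(self.weights < 0):
            raise ValueError("embedding weights must be non-negative")

    @property
    def index(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.item_ids)}

    @property
    def k(self) -> int:
        return self.weights.shape[1]

    def gram(self) -> np.ndarray:
        return self.weights @ self.weights.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.item_ids),
                            columns=list(self.dim_labels))


@dataclass
class TrainingResult:
    embedding: EmbeddingMatrix
    k_effective: int
    train_loss_history: list[float]
    validation_loss_history: list[float]
    holdout_accuracy: float
    tie_fraction: float
    best_epoch: int
    best_validation_loss: float
    config: TrainingConfig = field(repr=False, default=None)


def _default_dim_labels(k: int) -> tuple[str, ...]:
    return tuple(f"dim_{i + 1:03d}" for i in range(k))


def choices_to_batch(choices: pd.DataFrame, item_ids: Sequence[str]) -> TripletBatch:
    """Convert a choice table to index arrays against an item catalog."""
    index = {item: i for i, item in enumerate(item_ids)}
    stim_cols = choices[["stim_left", "stim_center", "stim_right"]]
    if not bool(stim_cols.isin(set(index)).all(axis=None)):
        raise ValueError("choices reference items absent from the catalog")
    odd = choices["choice_position"].to_numpy(dtype=np.int64) - 1
    if odd.min() < 0 or odd.max() > 2:
        raise ValueError("choice_position must lie in {1, 2, 3}")
    return TripletBatch(
        a=stim_cols["stim_left"].map(index).to_numpy(dtype=np.int64),
        b=stim_cols["stim_center"].map(index).to_numpy(dtype=np.int64),
        c=stim_cols["stim_right"].map(index).to_numpy(dtype=np.int64),
        odd=odd,
    )


def choice_probabilities(embedding: EmbeddingMatrix,
                         triplet: Sequence[str]) -> np.ndarray:
    """Model odd-one-out probabilities for one displayed triplet of item ids."""
    if len(triplet) != 3 or len(set(triplet)) != 3:
        raise ValueError("triplet must contain three distinct item ids")
    index = embedding.index
    try:
        a, b, c = (index[item] for item in triplet)
    except KeyError as err:
        raise ValueError(f"unknown item id: {err.args[0]!r}") from None
    batch = TripletBatch(*(np.array([i]) for i in (a, b, c)), odd=np.array([0]))
    return _choice.triplet_probabilities(embedding.weights, batch)[0]


def loss(embedding: EmbeddingMatrix | np.ndarray, batch: TripletBatch,
         lam: float) -> float:
    """Objective value on a batch; see :func:`sposekit.choice.loss`."""
    weights = embedding.weights if isinstance(embedding, EmbeddingMatrix) else embedding
    return _choice.loss(weights, batch, lam)


def gradient(embedding: EmbeddingMatrix | np.ndarray, batch: TripletBatch,
             lam: float) -> np.ndarray:
    """Analytic gradient of :func:`loss`; see :func:`sposekit.choice.gradient`."""
    weights = embedding.weights if isinstance(embedding, EmbeddingMatrix) else embedding
    return _choice.gradient(weights, batch, lam)


def prune_and_sort(embedding: EmbeddingMatrix,
                   threshold: float = 0.1) -> EmbeddingMatrix:
    """Drop low-weight dimensions and order the rest by total weight.

    Columns whose sum is strictly below ``threshold`` are removed (a column
    summing to exactly ``threshold`` survives); remaining columns are sorted
    by descending column sum (ties keep their original order) and relabeled
    ``dim_001 ...``.
    """
    sums = embedding.weights.sum(axis=0)
    keep = np.flatnonzero(sums >= threshold)
    if keep.size == 0:
        warnings.warn("every dimension fell below the pruning threshold; "
                      "returning an empty embedding", stacklevel=2)
    order = keep[np.argsort(-sums[keep], kind="stable")]
    return EmbeddingMatrix(
        weights=embedding.weights[:, order],
        item_ids=embedding.item_ids,
        dim_labels=_default_dim_labels(order.size),
    )


def _subset(batch: TripletBatch, idx: np.ndarray) -> TripletBatch:
    return TripletBatch(batch.a[idx], batch.b[idx], batch.c[idx], batch.odd[idx])


def train(choices: pd.DataFrame, item_ids: Sequence[str],
          config: TrainingConfig = TrainingConfig(),
          on_epoch_end: Callable[[int, np.ndarray], None] | None = None
          ) -> TrainingResult:
    """Fit the embedding to a table of odd-one-out choices.

    The weight matrix (n_items x k_init) is initialized uniformly in [0, 1),
    the trials are split into train/validation (``1 - validation_fraction``
    / ``validation_fraction``, at the trial level), and Adam runs over
    shuffled mini-batches; after every update the weights are clipped at
    zero.  Training stops at ``max_epochs`` or once the validation
    cross-entropy has not improved for ``window`` consecutive epochs.  The
    final weights are then pruned and sorted, and holdout accuracy (argmax
    predicted probability vs. the observed choice, ties resolved to the
    lowest screen position) is measured on the validation split with the
    pruned embedding.

    ``on_epoch_end(epoch, weights)``, if given, is called after each epoch
    (used e.g. to verify invariants along the training trace).

    Everything is reproducible under ``config.seed``.
    """
    item_ids = tuple(item_ids)
    full = choices_to_batch(choices, item_ids)
    n_trials = len(full)
    if n_trials < config.batch_size:
        raise ValueError(
            f"{n_trials} trials cannot fill one batch of {config.batch_size}")

    rng = np.random.default_rng(config.seed)
    n_items = len(item_ids)

    order = rng.permutation(n_trials)
    n_val = max(1, round(config.validation_fraction * n_trials))
    val = _subset(full, order[:n_val])
    tr = _subset(full, order[n_val:])
    n_train = len(tr)

    weights = rng.random((n_items, config.k_init))
    m = np.zeros_like(weights)
    v = np.zeros_like(weights)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_epoch = 0
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            idx = perm[start:start + config.batch_size]
            batch = _subset(tr, idx)
            batch_loss, grad = _choice.loss_and_gradient(weights, batch, config.lam)
            epoch_losses.append(batch_loss)
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad * grad
            m_hat = m / (1 - beta1 ** step)
            v_hat = v / (1 - beta2 ** step)
            weights = weights - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            np.maximum(weights, 0.0, out=weights)

        train_hist.append(float(np.mean(epoch_losses)))
        val_loss = _choice.cross_entropy(weights, val)
        val_hist.append(val_loss)
        if on_epoch_end is not None:
            on_epoch_end(epoch, weights)

        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.window:
                break

    embedding = prune_and_sort(
        EmbeddingMatrix(weights=weights, item_ids=item_ids,
                        dim_labels=_default_dim_labels(config.k_init)),
        threshold=config.prune_threshold,
    )

    if embedding.k > 0:
        probs = _choice.triplet_probabilities(embedding.weights, val)
    else:
        probs = np.full((len(val), 3), 1.0 / 3.0)
    # argmax with ties resolved to the lowest screen position
    predicted = probs.argmax(axis=1)
    ties = (probs == probs.max(axis=1, keepdims=True)).sum(axis=1) > 1
    holdout_accuracy = float((predicted == val.odd).mean())
    tie_fraction = float(ties.mean())

    return TrainingResult(
        embedding=embedding,
        k_effective=embedding.k,
        train_loss_history=train_hist,
        validation_loss_history=val_hist,
        holdout_accuracy=holdout_accuracy,
        tie_fraction=tie_fraction,
        best_epoch=best_epoch,
        best_validation_loss=float(best_val),
        config=config,
    )


def with_params(config: TrainingConfig, **kwargs) -> TrainingConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
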