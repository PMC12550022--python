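"""Softmax-of-dot-products choice rule for triplet odd-one-out judgments.

The odd-one-out is modeled as the item left over once the most similar pair
has been identified: given items ``(a, b, c)`` with embedding rows
``w_a, w_b, w_c`` and pairwise similarities ``s_xy = w_x . w_y``, the
probability that ``a`` is the odd one out is the softmax weight of the
*opposite* pair,

    p(odd = a) = exp(s_bc) / (exp(s_bc) + exp(s_ac) + exp(s_ab)).

This module holds the single implementation of that rule together with the
cross-entropy / L1 objective and its analytic gradient.  Both the synthetic
generator and the embedding learner call into it.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class TripletBatch(NamedTuple):
    """Index representation of a batch of odd-one-out trials.

    ``a``, ``b``, ``c`` are integer row indices into the embedding matrix for
    the three on-screen positions; ``odd`` is the observed odd-one-out
    position in ``{0, 1, 2}``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    odd: np.ndarray

    def __len__(self) -> int:
        return len(self.a)


def _pair_similarities(weights: np.ndarray, batch: TripletBatch) -> np.ndarray:
    """(B, 3) matrix of opposite-pair dot products.

    Column m holds the similarity of the pair that excludes position m, so the
    softmax over columns is directly the odd-one-out distribution.
    """
    wa = weights[batch.a]
    wb = weights[batch.b]
    wc = weights[batch.c]
    s_bc = np.einsum("ij,ij->i", wb, wc)
    s_ac = np.einsum("ij,ij->i", wa, wc)
    s_ab = np.einsum("ij,ij->i", wa, wb)
    return np.stack([s_bc, s_ac, s_ab], axis=1)


def _softmax(scores: np.ndarray) -> np.ndarray:
    # shift by the row max: exact for the softmax, avoids overflow
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def triplet_probabilities(weights: np.ndarray, batch: TripletBatch) -> np.ndarray:
    """Odd-one-out probabilities, one row of three per trial (rows sum to 1)."""
    return _softmax(_pair_similarities(weights, batch))


def cross_entropy(weights: np.ndarray, batch: TripletBatch) -> float:
    """Mean negative log probability of the observed odd-one-out choices."""
    scores = _pair_similarities(weights, batch)
    shifted = scores - scores.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_p = shifted[np.arange(len(batch)), batch.odd] - log_z
    return float(-log_p.mean())


def loss(weights: np.ndarray, batch: TripletBatch, lam: float) -> float:
    """Training objective: mean cross-entropy plus the scaled L1 penalty.

    The penalty is ``lam * weights.sum() / n_items`` (entries are
    non-negative, so the sum is the L1 norm).  Dividing by the number of
    items keeps ``lam`` comparable across catalog sizes.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    n_items = weights.shape[0]
    return cross_entropy(weights, batch) + lam * float(weights.sum()) / n_items


def loss_and_gradient(weights: np.ndarray, batch: TripletBatch,
                      lam: float) -> tuple[float, np.ndarray]:
    """Objective value and its analytic gradient in one pass.

    For each trial the cross-entropy gradient w.r.t. the pair similarity
    ``s_m`` is ``p_m - 1{m = odd}``; the chain rule scatters that onto the two
    rows forming the pair.  The L1 term contributes the constant
    ``lam / n_items`` everywhere on the non-negative orthant.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    n_items = weights.shape[0]
    n_trials = len(batch)

    scores = _pair_similarities(weights, batch)
    shifted = scores - scores.max(axis=1, keepdims=True)
    exp_s = np.exp(shifted)
    probs = exp_s / exp_s.sum(axis=1, keepdims=True)
    log_p = shifted[np.arange(n_trials), batch.odd] - np.log(exp_s.sum(axis=1))
    value = float(-log_p.mean()) + lam * float(weights.sum()) / n_items

    coef = probs.copy()
    coef[np.arange(n_trials), batch.odd] -= 1.0
    coef /= n_trials

    # Scatter-add via a one-hot matmul: the six (target row, source row)
    # contribution streams — pair (b,c) feeds rows b and c with coef column
    # 0, pair (a,c) rows a and c with column 1, pair (a,b) rows a and b with
    # column 2 — are stacked into one gather, and an indicator matrix routes
    # them onto the embedding rows in a single BLAS call.  Several times
    # faster than np.add.at at these batch sizes.
    a, b, c = batch.a, batch.b, batch.c
    targets = np.concatenate((b, c, a, c, a, b))
    sources = np.concatenate((c, b, c, a, b, a))
    coef_rep = np.concatenate((coef[:, 0], coef[:, 0], coef[:, 1],
                               coef[:, 1], coef[:, 2], coef[:, 2]))
    vals = weights[sources] * coef_rep[:, None]
    onehot = np.zeros((n_items, targets.size))
    onehot[targets, np.arange(targets.size)] = 1.0
    grad = onehot @ vals
    grad += lam / n_items
    return value, grad


def gradient(weights: np.ndarray, batch: TripletBatch, lam: float) -> np.ndarray:
    """Analytic gradient of :func:`loss` with respect to every weight."""
    return loss_and_gradient(weights, batch, lam)[1]
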