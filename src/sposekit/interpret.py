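"""Interpretation of a trained embedding and its validation against ratings.

A dimension is read by looking at the stimuli that load most strongly on it
(:func:`top_ranking_items`) and a stimulus is summarized by its weight
profile across all dimensions (:func:`dimension_profile`, the data behind a
rose plot).  To test whether naive raters can use the dimensions, their
typicality ratings are turned into an item x dimension matrix, both that
matrix and the model weights are converted into item x item Pearson
similarity matrices, and the two matrices are compared by correlating their
lower triangles (representational similarity analysis), with significance
from a label-shuffling randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import EmbeddingMatrix

NOT_AT_ALL = "not_at_all"
N_RATING_LEVELS = 7


@dataclass
class SimilarityMatrix:
    """Symmetric item x item Pearson-correlation matrix."""

    item_ids: tuple[str, ...]
    values: np.ndarray
    flagged_items: tuple[str, ...] = ()   # rows with zero variance (undefined entries)

    def __post_init__(self) -> None:
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match item_ids")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite & finite.T],
                           self.values.T[finite & finite.T], atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class RandomizationResult:
    observed_r: float
    p_value: float
    n_perm: int
    perm_mean: float
    perm_sd: float
    perm_r: np.ndarray = field(repr=False, default=None)


def top_ranking_items(embedding: EmbeddingMatrix, dimension: str,
                      k: int) -> list[str]:
    """The ``k`` stimuli with the highest weight on one dimension.

    Sorted by descending weight; exact ties are broken by lexicographic
    item id so the ranking is reproducible.
    """
    if dimension not in embedding.dim_labels:
        raise ValueError(f"unknown dimension: {dimension!r}")
    if k > len(embedding.item_ids):
        raise ValueError("k exceeds the number of items")
    col = embedding.dim_labels.index(dimension)
    order = sorted(range(len(embedding.item_ids)),
                   key=lambda i: (-embedding.weights[i, col], embedding.item_ids[i]))
    return [embedding.item_ids[i] for i in order[:k]]


def dimension_profile(embedding: EmbeddingMatrix, item: str) -> pd.Series:
    """One stimulus's weights across all dimensions (rose-plot data)."""
    if item not in embedding.index:
        raise ValueError(f"unknown item: {item!r}")
    row = embedding.weights[embedding.index[item]]
    return pd.Series(row, index=list(embedding.dim_labels), name=item)


def preprocess_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Turn long-format typicality ratings into an item x dimension matrix.

    The scale runs over seven levels with level 1 = "very typical" down to
    level 7 = "very untypical", plus the off-scale answer ``not_at_all``.
    ``not_at_all`` maps to 0; level ``l`` maps to ``(8 - l) / 7`` so that
    "very typical" scores 1 and even "very untypical" keeps a small positive
    value (1/7), distinct from "not at all".  Ratings are then averaged
    across raters per (item, dimension) cell.
    """
    if len(ratings) == 0:
        raise ValueError("rating table is empty")
    required = {"rater_id", "stimulus_id", "dimension_id", "level"}
    if not required <= set(ratings.columns):
        raise ValueError(f"rating table needs columns {sorted(required)}")
    if ratings.duplicated(["rater_id", "stimulus_id", "dimension_id"]).any():
        raise ValueError("duplicate (rater, stimulus, dimension) rating")

    def numeric(level) -> float:
        if isinstance(level, str) and level.strip() == NOT_AT_ALL:
            return 0.0
        value = int(level)
        if not 1 <= value <= N_RATING_LEVELS:
            raise ValueError(f"rating level out of range: {level!r}")
        return (N_RATING_LEVELS + 1 - value) / N_RATING_LEVELS

    df = ratings.copy()
    df["score"] = df["level"].map(numeric)
    matrix = df.pivot_table(index="stimulus_id", columns="dimension_id",
                            values="score", aggfunc="mean")
    return matrix


def similarity_matrix(features: pd.DataFrame | np.ndarray,
                      item_ids: Sequence[str] | None = None) -> SimilarityMatrix:
    """Pairwise Pearson correlations of the items' feature vectors.

    Items whose feature vector has zero variance have no defined
    correlation; those rows/columns are set to NaN and the items flagged.
    """
    if isinstance(features, pd.DataFrame):
        item_ids = tuple(str(i) for i in features.index)
        data = features.to_numpy(dtype=float)
    else:
        data = np.asarray(features, dtype=float)
        if item_ids is None:
            item_ids = tuple(f"item_{i:04d}" for i in range(data.shape[0]))
        item_ids = tuple(item_ids)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need at least two features per item")

    sd = data.std(axis=1)
    flagged = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(data)
    values[flagged, :] = np.nan
    values[:, flagged] = np.nan
    np.fill_diagonal(values, 1.0)
    values[flagged, flagged] = np.nan
    return SimilarityMatrix(item_ids=item_ids, values=values,
                            flagged_items=tuple(item_ids[i] for i in flagged))


def scale_model_weights(embedding: EmbeddingMatrix,
                        items: Sequence[str]) -> pd.DataFrame:
    """Min-max scale each dimension to [0, 1] over the selected items.

    Puts model weights on the same scale as preprocessed ratings before the
    two are turned into similarity matrices.  A dimension that is constant
    over the selected items carries no information there and maps to all
    zeros.
    """
    index = embedding.index
    unknown = [i for i in items if i not in index]
    if unknown:
        raise ValueError(f"unknown items: {unknown}")
    rows = embedding.weights[[index[i] for i in items]]
    lo = rows.min(axis=0)
    span = rows.max(axis=0) - lo
    scaled = np.zeros_like(rows)
    ok = span > 0
    scaled[:, ok] = (rows[:, ok] - lo[ok]) / span[ok]
    return pd.DataFrame(scaled, index=list(items), columns=list(embedding.dim_labels))


def _lower_triangle(matrix: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(matrix.shape[0], k=-1)
    return matrix[i, j]


def compare_rsa(m1: SimilarityMatrix, m2: SimilarityMatrix) -> float:
    """Pearson correlation of the two matrices' strict lower triangles."""
    if m1.item_ids != m2.item_ids:
        raise ValueError("similarity matrices must share item ids and order")
    x = _lower_triangle(m1.values)
    y = _lower_triangle(m2.values)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("similarity matrices contain undefined entries")
    return float(stats.pearsonr(x, y).statistic)


def randomization_test(m1: SimilarityMatrix, m2: SimilarityMatrix,
                       n_perm: int, seed: int = 0) -> RandomizationResult:
    """Label-shuffling null distribution for the RSA correlation.

    For each permutation the rows and columns of ``m2`` are relabeled by a
    random item permutation and the lower-triangle correlation with ``m1``
    is recomputed.  The p-value is the plain proportion of permutations
    whose correlation reaches or exceeds the observed one; its smallest
    nonzero value is ``1 / n_perm``, and it is 0 when no permutation
    reaches the observed correlation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    n = len(m1.item_ids)
    if n < 3:
        raise ValueError("need at least 3 items for a meaningful permutation test")
    observed = compare_rsa(m1, m2)

    rng = np.random.default_rng(seed)
    tri_i, tri_j = np.tril_indices(n, k=-1)
    x = m1.values[tri_i, tri_j]
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())

    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permuted lower triangles in one gather: entry (p, e) = m2[perm_p[i_e], perm_p[j_e]]
    y = m2.values[perms[:, tri_i], perms[:, tri_j]]
    yc = y - y.mean(axis=1, keepdims=True)
    ys = np.sqrt((yc ** 2).sum(axis=1))
    perm_r = (yc @ xc) / (ys * xs)

    p_value = float((perm_r >= observed).mean())
    return RandomizationResult(
        observed_r=observed,
        p_value=p_value,
        n_perm=n_perm,
        perm_mean=float(perm_r.mean()),
        perm_sd=float(perm_r.std()),
        perm_r=perm_r,
    )
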