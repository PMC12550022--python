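"""Stimulus-database curation: frame selection, category balancing, validation.

Works on per-frame classifier softmax vectors supplied as a table (one row
per frame: video id, category label, frame index, class probabilities).
For each video the frame whose correct-class probability is highest is
kept; category representatives are the mean of their videos' best-frame
vectors; pairwise cosine dissimilarities between representatives feed an
agglomerative clustering whose flat clusters expose over-represented
groups of near-synonymous categories.  Finally, categories whose exemplars
observers cannot name reliably are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

FRAME_KEY_COLUMNS = ["video_id", "category", "frame_index"]


@dataclass
class CategoryProfile:
    category: str
    vector: np.ndarray
    n_videos: int


@dataclass
class ClusterResult:
    merges: np.ndarray            # scipy linkage matrix (n-1 x 4)
    labels: dict[str, int]        # category -> flat cluster id
    cluster_sizes: dict[int, int]
    mean_cluster_size: float


@dataclass
class NamingFilterResult:
    retained: list[str]
    excluded: list[str]
    reasons: dict[str, str]


def _class_columns(frames: pd.DataFrame) -> list[str]:
    cols = [c for c in frames.columns if c not in FRAME_KEY_COLUMNS]
    if not cols:
        raise ValueError("frame table has no class-probability columns")
    return cols


def best_frame_vector(frames: pd.DataFrame) -> np.ndarray:
    """The full softmax vector of a video's most confidently classified frame.

    ``frames`` holds all rows of one video; the correct class is the video's
    category label and must be one of the probability columns.  Ties go to
    the lowest frame index.
    """
    if len(frames) == 0:
        raise ValueError("video has no frames")
    categories = frames["category"].unique()
    if len(categories) != 1:
        raise ValueError("frames of one video must share a category label")
    category = categories[0]
    class_cols = _class_columns(frames)
    if category not in class_cols:
        raise ValueError(f"category {category!r} is not among the class columns")
    ordered = frames.sort_values("frame_index", kind="stable")
    best = ordered[category].to_numpy().argmax()   # first max = lowest frame index
    return ordered.iloc[best][class_cols].to_numpy(dtype=float)


def category_representatives(frames: pd.DataFrame) -> list[CategoryProfile]:
    """Mean best-frame vector per category, over that category's videos."""
    if len(frames) == 0:
        raise ValueError("frame table is empty")
    profiles = []
    for category, group in frames.groupby("category", sort=True):
        vectors = [best_frame_vector(video_frames)
                   for _, video_frames in group.groupby("video_id", sort=True)]
        profiles.append(CategoryProfile(
            category=str(category),
            vector=np.mean(vectors, axis=0),
            n_videos=len(vectors),
        ))
    return profiles


def cosine_dissimilarity_matrix(profiles: Sequence[CategoryProfile]) -> pd.DataFrame:
    """Pairwise 1 - cosine similarity between representative vectors.

    For non-negative vectors the result lies in [0, 1]; the diagonal is 0.
    """
    vectors = np.array([p.vector for p in profiles], dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("representative vectors must be nonzero")
    unit = vectors / norms[:, None]
    matrix = 1.0 - unit @ unit.T
    np.fill_diagonal(matrix, 0.0)
    matrix = np.clip(matrix, 0.0, None)
    labels = [p.category for p in profiles]
    return pd.DataFrame(matrix, index=labels, columns=labels)


def hierarchical_clusters(dissimilarity: pd.DataFrame,
                          linkage: str = "average",
                          n_clusters: int | None = None,
                          height: float | None = None) -> ClusterResult:
    """Agglomerative clustering of categories from a dissimilarity matrix.

    ``linkage`` is one of single/complete/average.  Flat clusters are cut
    either at a target cluster count (``n_clusters``) or at a dendrogram
    height (``height``); exactly one must be given.  Reports per-cluster
    sizes so over-represented meta-clusters stand out against the mean.
    """
    n = dissimilarity.shape[0]
    if n < 2:
        raise ValueError("need at least two categories to cluster")
    if linkage not in {"single", "complete", "average"}:
        raise ValueError("linkage must be single, complete or average")
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    values = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-12) or np.any(np.diag(values) != 0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")

    condensed = squareform(values, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    if n_clusters is not None:
        flat = hierarchy.fcluster(merges, t=n_clusters, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(merges, t=height, criterion="distance")

    labels = {str(cat): int(c) for cat, c in zip(dissimilarity.index, flat)}
    sizes: dict[int, int] = {}
    for c in flat:
        sizes[int(c)] = sizes.get(int(c), 0) + 1
    return ClusterResult(
        merges=merges,
        labels=labels,
        cluster_sizes=sizes,
        mean_cluster_size=float(np.mean(list(sizes.values()))),
    )


def naming_accuracy_filter(accuracies: Mapping[str, Sequence[float]],
                           threshold: float = 0.7) -> NamingFilterResult:
    """Exclude categories observers cannot name.

    A category is excluded iff its mean exemplar naming accuracy is below
    ``threshold`` *and* at least two exemplars individually fall below it.
    A single bad exemplar does not sink a category whose other exemplars
    are recognized.
    """
    retained, excluded, reasons = [], [], {}
    for category, values in accuracies.items():
        values = list(values)
        if not values:
            raise ValueError(f"category {category!r} has no exemplar accuracies")
        mean = float(np.mean(values))
        n_low = sum(v < threshold for v in values)
        if mean < threshold and n_low >= 2:
            excluded.append(category)
            reasons[category] = (f"mean accuracy {mean:.3f} < {threshold} and "
                                 f"{n_low} exemplars below {threshold}")
        else:
            retained.append(category)
    return NamingFilterResult(retained=retained, excluded=excluded, reasons=reasons)
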