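"""Triplet experiment design: which odd-one-out trials to show, in which sets.

A full design is assembled from three blocks:

* an **exhaustive** block that enumerates every triplet of a small stimulus
  subset one or more times (used to compare cohorts and estimate agreement
  on a densely sampled sub-matrix);
* a **repeat** block that shows a fixed random sample of triplets many times
  each (the basis of the choice-consistency estimate);
* a **main** block that guarantees pair coverage: every unordered pair of
  stimuli appears in a configurable number of triplets, each completed by a
  distinct third stimulus.

Trials from all blocks are randomly interleaved, on-screen position order is
randomized per trial, and the sequence is packed into consecutive sets of
fixed size (one set is the unit of work a crowd worker accepts).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DESIGN_COLUMNS

_POSITION_PERMS = list(itertools.permutations(range(3)))

# below this, triplet sampling just enumerates; above, rejection-samples
_ENUMERATE_LIMIT = 200_000


@dataclass
class TrialDesign:
    """Ordered trial table (block, set_index, trial_index, three stimuli)."""

    trials: pd.DataFrame
    params: dict

    def __len__(self) -> int:
        return len(self.trials)


def count_triplets(n: int) -> int:
    """Number of unordered stimulus triplets, C(n, 3)."""
    if n < 3:
        raise ValueError("need at least 3 items to form a triplet")
    return math.comb(n, 3)


def _sample_distinct_triplets(item_ids: Sequence[str], n_triplets: int,
                              rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Uniform sample of distinct triplets from all C(n, 3)."""
    n = len(item_ids)
    total = count_triplets(n)
    if n_triplets > total:
        raise ValueError(f"cannot sample {n_triplets} distinct triplets from {total}")
    if total <= _ENUMERATE_LIMIT:
        universe = list(itertools.combinations(item_ids, 3))
        picks = rng.choice(total, size=n_triplets, replace=False)
        return [universe[i] for i in picks]
    seen: set[tuple[int, int, int]] = set()
    while len(seen) < n_triplets:
        draw = rng.integers(0, n, size=3)
        if draw[0] < draw[1] < draw[2]:
            seen.add(tuple(int(x) for x in draw))
    return [tuple(item_ids[i] for i in key) for key in sorted(seen)]


def build_design(item_ids: Sequence[str], *,
                 subset_ids: Sequence[str] = (),
                 subset_passes: int = 0,
                 repeat_n_triplets: int = 0,
                 repeat_count: int = 0,
                 pair_coverage: int = 1,
                 set_size: int = 32,
                 seed: int = 0) -> TrialDesign:
    """Assemble the three-block triplet design and pack it into sets.

    Parameters
    ----------
    item_ids : the full stimulus catalog (distinct identifiers).
    subset_ids : stimuli of the exhaustive block (must be within the catalog).
    subset_passes : how many times the exhaustive block enumerates every
        triplet of ``subset_ids``.
    repeat_n_triplets, repeat_count : the repeat block shows
        ``repeat_n_triplets`` randomly chosen triplets ``repeat_count``
        times each.
    pair_coverage : number of main-block triplets per unordered stimulus
        pair; the third stimuli of a pair's triplets are pairwise distinct.
    set_size : trials per set.
    seed : RNG seed; the design is reproducible.
    """
    item_ids = list(item_ids)
    if not item_ids:
        raise ValueError("item_ids must be non-empty")
    if len(set(item_ids)) != len(item_ids):
        raise ValueError("item_ids must be distinct")
    subset_ids = list(subset_ids)
    if not set(subset_ids) <= set(item_ids):
        raise ValueError("subset_ids must be a subset of item_ids")
    for name, value in [("subset_passes", subset_passes),
                        ("repeat_n_triplets", repeat_n_triplets),
                        ("repeat_count", repeat_count),
                        ("pair_coverage", pair_coverage)]:
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if set_size < 1:
        raise ValueError("set_size must be at least 1")
    n = len(item_ids)
    if pair_coverage > 0 and pair_coverage > n - 2:
        raise ValueError(
            f"pair_coverage={pair_coverage} infeasible: only {n - 2} distinct "
            "third stimuli exist per pair")

    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, tuple[str, str, str]]] = []

    if subset_passes > 0 and len(subset_ids) >= 3:
        subset_triplets = list(itertools.combinations(subset_ids, 3))
        for _ in range(subset_passes):
            blocks += [("exhaustive", t) for t in subset_triplets]

    if repeat_n_triplets > 0 and repeat_count > 0:
        chosen = _sample_distinct_triplets(item_ids, repeat_n_triplets, rng)
        for t in chosen:
            blocks += [("repeat", t)] * repeat_count

    if pair_coverage > 0:
        for i, j in itertools.combinations(range(n), 2):
            pool = np.delete(np.arange(n), [i, j])
            thirds = rng.choice(pool, size=pair_coverage, replace=False)
            blocks += [("main", (item_ids[i], item_ids[j], item_ids[k]))
                       for k in thirds]

    if not blocks:
        raise ValueError("design is empty: enable at least one block")

    order = rng.permutation(len(blocks))
    perm_choice = rng.integers(0, len(_POSITION_PERMS), size=len(blocks))

    rows = []
    for trial_index, (src, which) in enumerate(zip(order, perm_choice)):
        block, triplet = blocks[src]
        p = _POSITION_PERMS[which]
        rows.append((block, trial_index // set_size, trial_index,
                     triplet[p[0]], triplet[p[1]], triplet[p[2]]))

    if len(rows) % set_size:
        warnings.warn(
            f"total trial count {len(rows)} is not divisible by set_size "
            f"{set_size}; the final set is short", stacklevel=2)

    trials = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    params = dict(n_items=n, subset_ids=subset_ids, subset_passes=subset_passes,
                  repeat_n_triplets=repeat_n_triplets, repeat_count=repeat_count,
                  pair_coverage=pair_coverage, set_size=set_size, seed=seed)
    return TrialDesign(trials=trials, params=params)


def design_summary(design: TrialDesign) -> dict:
    """Per-block counts, unique-triplet count and unique fraction of C(n, 3)."""
    trials = design.trials
    block_counts = trials["block"].value_counts().to_dict()
    triplets = {
        tuple(sorted(t))
        for t in trials[["stim_left", "stim_center", "stim_right"]].itertuples(index=False)
    }
    n = design.params["n_items"]
    possible = count_triplets(n)
    unique = len(triplets)
    return {
        "n_trials": len(trials),
        "n_sets": int(trials["set_index"].nunique()),
        "block_counts": {k: int(v) for k, v in block_counts.items()},
        "unique_triplets": unique,
        "possible_triplets": possible,
        "unique_fraction": unique / possible,
    }
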