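"""Worker- and trial-level exclusion rules and choice-consistency estimation.

Crowdsourced odd-one-out data contains workers who click through sets too
fast to have watched the stimuli and workers who park on one screen
position.  A worker is dropped when

* at least 3 of their sets are *fast* — a set counts as fast when >= 12.5%
  of its responses are under 900 ms **and** >= 50% are under 1200 ms; or
* at least 6 of their sets are *deterministic* — one screen position chosen
  in >= 50% of the set's trials.

After worker exclusion every remaining individual trial with RT < 900 ms
(strictly) is dropped.  Choice consistency is then estimated from triplets
answered more than once: the fraction of response pairs that picked the
same stimulus (identity, not screen position), averaged over triplets.
Chance level for three alternatives is 1/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAST_RT_MS = 900.0
SLOW_RT_MS = 1200.0
FAST_FRACTION = 0.125
SLOW_FRACTION = 0.5
FAST_SET_LIMIT = 3
DETERMINISTIC_FRACTION = 0.5
DETERMINISTIC_SET_LIMIT = 6


@dataclass(frozen=True)
class WorkerExclusion:
    worker_id: str
    reason: str  # "fast_sets" or "deterministic"
    n_flagged_sets: int


@dataclass
class QCReport:
    excluded_workers: list[WorkerExclusion] = field(default_factory=list)
    retained_trials: int = 0
    total_trials: int = 0
    retained_fraction: float = 0.0
    consistency: float = float("nan")


def flag_fast_sets(rt_ms) -> bool:
    """True iff a set of trials trips both reaction-time thresholds."""
    rt = np.asarray(rt_ms, dtype=float)
    if rt.size == 0:
        raise ValueError("a trial set cannot be empty")
    if np.isnan(rt).any():
        raise ValueError("missing reaction time in set")
    return bool((rt < FAST_RT_MS).mean() >= FAST_FRACTION
                and (rt < SLOW_RT_MS).mean() >= SLOW_FRACTION)


def exclude_workers(choices: pd.DataFrame) -> list[WorkerExclusion]:
    """Apply both worker-level rules; one record per excluded worker.

    If a worker trips both rules the ``fast_sets`` reason is recorded.
    """
    exclusions: list[WorkerExclusion] = []
    for worker_id, worker in choices.groupby("worker_id", sort=True):
        n_fast = 0
        n_det = 0
        for _, trials in worker.groupby("set_index"):
            if flag_fast_sets(trials["rt_ms"].to_numpy()):
                n_fast += 1
            position_share = trials["choice_position"].value_counts(normalize=True)
            if position_share.max() >= DETERMINISTIC_FRACTION:
                n_det += 1
        if n_fast >= FAST_SET_LIMIT:
            exclusions.append(WorkerExclusion(str(worker_id), "fast_sets", n_fast))
        elif n_det >= DETERMINISTIC_SET_LIMIT:
            exclusions.append(WorkerExclusion(str(worker_id), "deterministic", n_det))
    return exclusions


def filter_trials(choices: pd.DataFrame,
                  excluded: list[WorkerExclusion]) -> tuple[pd.DataFrame, float]:
    """Drop excluded workers' trials, then all trials with RT < 900 ms.

    The 900 ms boundary itself is kept (the rule is strictly "below").
    Returns the retained table and the retained fraction of the input.
    """
    if len(choices) == 0:
        return choices.copy(), 0.0
    bad_workers = {e.worker_id for e in excluded}
    kept = choices[~choices["worker_id"].astype(str).isin(bad_workers)]
    kept = kept[kept["rt_ms"] >= FAST_RT_MS]
    return kept.reset_index(drop=True), len(kept) / len(choices)


def _chosen_identity(choices: pd.DataFrame) -> pd.Series:
    stims = choices[["stim_left", "stim_center", "stim_right"]].to_numpy()
    pos = choices["choice_position"].to_numpy(dtype=int) - 1
    return pd.Series(stims[np.arange(len(choices)), pos], index=choices.index)


def choice_consistency(choices: pd.DataFrame, method: str = "pairwise") -> float:
    """Between-response agreement over repeatedly presented triplets.

    Responses are grouped by the unordered stimulus triplet; agreement is on
    the chosen stimulus *identity*, so the per-trial screen randomization
    does not matter.  With ``method="pairwise"`` (default) a triplet's
    agreement is the fraction of unordered response pairs that chose the
    same stimulus; ``method="modal"`` uses the modal-choice fraction
    instead.  Triplets with fewer than two responses are skipped with a
    warning; the result is the unweighted mean over the remaining triplets.
    """
    if method not in {"pairwise", "modal"}:
        raise ValueError("method must be 'pairwise' or 'modal'")
    if len(choices) == 0:
        raise ValueError("no choices given")

    df = choices.copy()
    df["_chosen"] = _chosen_identity(df)
    df["_triplet"] = [
        tuple(sorted(t)) for t in
        df[["stim_left", "stim_center", "stim_right"]].itertuples(index=False)
    ]

    agreements = []
    n_skipped = 0
    for _, group in df.groupby("_triplet"):
        m = len(group)
        if m < 2:
            n_skipped += 1
            continue
        counts = group["_chosen"].value_counts().to_numpy()
        if method == "pairwise":
            agreements.append((counts * (counts - 1)).sum() / (m * (m - 1)))
        else:
            agreements.append(counts.max() / m)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} triplet(s) with fewer than two responses",
                      stacklevel=2)
    if not agreements:
        raise ValueError("no triplet was answered at least twice")
    return float(np.mean(agreements))


def qc_report(choices: pd.DataFrame, consistency_method: str = "pairwise") -> QCReport:
    """Full quality-control pass: exclusions, trial filter, consistency.

    Consistency is computed on the retained trials' repeated triplets and is
    NaN when no triplet was answered at least twice.
    """
    excluded = exclude_workers(choices)
    retained, fraction = filter_trials(choices, excluded)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            consistency = choice_consistency(retained, method=consistency_method)
    except ValueError:
        consistency = float("nan")
    return QCReport(
        excluded_workers=excluded,
        retained_trials=len(retained),
        total_trials=len(choices),
        retained_fraction=fraction,
        consistency=consistency,
    )
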