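"""Tab-separated readers/writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CHOICE_COLUMNS = [
    "worker_id", "set_index", "trial_index",
    "stim_left", "stim_center", "stim_right",
    "choice_position", "rt_ms",
]

DESIGN_COLUMNS = [
    "block", "set_index", "trial_index",
    "stim_left", "stim_center", "stim_right",
]

RATING_COLUMNS = ["rater_id", "stimulus_id", "dimension_id", "level"]


def write_choices(choices: pd.DataFrame, path: str | Path) -> None:
    choices.to_csv(path, sep="\t", index=False, columns=CHOICE_COLUMNS)


def read_choices(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"choice table missing columns: {sorted(missing)}")
    return df[CHOICE_COLUMNS]


def write_design(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, columns=DESIGN_COLUMNS)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df[DESIGN_COLUMNS]


def write_matrix(weights: np.ndarray, item_ids, dim_labels, path: str | Path) -> None:
    """Write an item x dimension weight matrix as TSV (rows = items)."""
    frame = pd.DataFrame(weights, index=list(item_ids), columns=list(dim_labels))
    frame.to_csv(path, sep="\t", index_label="item_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="item_id")


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, sep="\t", index=False, columns=RATING_COLUMNS)


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"level": str})
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    return df[RATING_COLUMNS]
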