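#!/usr/bin/env python
"""Simulate a contaminated crowdsourced cohort answering the reduced design.

Reads results/design_reduced.tsv (from 01), answers it with a ground-truth
sparse embedding, 20 compliant workers, 2 speeders and 2 position-biased
workers, and writes the raw choice table plus the ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from sposekit import (TrialDesign, WorkerProfile, generate_ground_truth,
                      simulate_dataset)
from sposekit.io import read_design, write_choices, write_matrix

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0

truth = generate_ground_truth(n_items=60, k_true=6, seed=SEED)
trials = read_design(OUT / "design_reduced.tsv")
design = TrialDesign(trials=trials, params={"n_items": 60})

# 124 workers over ~1,000 sets: each does ~8 sets, as in a real cohort
profiles = ([WorkerProfile.compliant(f"ok{i:03d}") for i in range(120)]
            + [WorkerProfile.speeder("sp0"), WorkerProfile.speeder("sp1"),
               WorkerProfile.position_biased("pb0", 1),
               WorkerProfile.position_biased("pb1", 3)])
data = simulate_dataset(truth, design, profiles, seed=SEED + 1)

write_choices(data.choices, OUT / "choices_raw.tsv")
write_matrix(truth.weights, truth.item_ids,
             [f"dim_{k + 1:03d}" for k in range(truth.weights.shape[1])],
             OUT / "ground_truth.tsv")

share = data.choices.groupby("worker_id").size()
print(f"simulated {len(data.choices):,} choices from {len(profiles)} workers")
print(f"trials per worker: min {share.min()}, max {share.max()}")
print(f"median RT: {data.choices['rt_ms'].median():.0f} ms")
print(f"wrote {OUT / 'choices_raw.tsv'} and ground_truth.tsv")
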