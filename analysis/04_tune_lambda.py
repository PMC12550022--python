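#!/usr/bin/env python
"""Grid-search the sparsity penalty on the retained simulated choices.

Reads results/choices_retained.tsv (from 03), trains one reduced-budget
model per (lambda, seed) over a five-point grid spanning 0.006-0.012 with
two seeds each, and picks the lambda with the smallest seed-averaged
validation cross-entropy.  Writes the run-level table and the choice.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sposekit import TrainingConfig, grid_search, lambda_grid
from sposekit.io import read_choices

OUT = Path(__file__).resolve().parents[1] / "results"

choices = read_choices(OUT / "choices_retained.tsv")
item_ids = sorted(set(choices["stim_left"]) | set(choices["stim_center"])
                  | set(choices["stim_right"]))

grid = lambda_grid(0.006, 0.012, 0.0015)
config = TrainingConfig(max_epochs=120, window=25)
result = grid_search(choices, item_ids, grid, n_seeds=2, config=config,
                     base_seed=10)

print(f"{result.runs} runs over {len(grid)} lambdas x 2 seeds")
for lam in grid:
    print(f"  lambda={lam:.4f}: mean validation loss {result.mean_losses[lam]:.4f}")
print(f"selected lambda = {result.best_lambda}")

result.losses.rename_axis("lambda").to_csv(OUT / "grid_search_runs.tsv", sep="\t")
(OUT / "best_lambda.json").write_text(json.dumps(
    {"best_lambda": result.best_lambda, "mean_losses": result.mean_losses},
    indent=2))
print(f"wrote {OUT / 'grid_search_runs.tsv'} and best_lambda.json")
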