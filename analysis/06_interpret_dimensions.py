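#!/usr/bin/env python
"""Interpret the trained embedding and validate it against synthetic ratings.

Reads results/embedding.tsv (from 05).  Exports per-dimension top-8 item
rankings and per-item dimension profiles (rose-plot data); then runs a
synthetic dimension-rating experiment — 21 raters perceive the scaled
model weights of 20 randomly drawn stimuli plus noise — and compares the
rating-based and model-based similarity matrices by lower-triangle Pearson
correlation with a 10,000-shuffle randomization test.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from sposekit.interpret import (compare_rsa, dimension_profile,
                                randomization_test, scale_model_weights,
                                similarity_matrix, top_ranking_items)
from sposekit.io import read_matrix
from sposekit.model import EmbeddingMatrix

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 5

frame = read_matrix(OUT / "embedding.tsv")
embedding = EmbeddingMatrix(weights=frame.to_numpy(),
                            item_ids=tuple(frame.index),
                            dim_labels=tuple(frame.columns))

top = {dim: top_ranking_items(embedding, dim, k=8)
       for dim in embedding.dim_labels}
pd.DataFrame(top).to_csv(OUT / "top8_per_dimension.tsv", sep="\t", index=False)

profiles = pd.DataFrame({item: dimension_profile(embedding, item)
                         for item in embedding.item_ids[:20]}).T
profiles.to_csv(OUT / "dimension_profiles.tsv", sep="\t", index_label="item_id")

rng = np.random.default_rng(SEED)
items = list(rng.choice(embedding.item_ids, size=20, replace=False))
scaled = scale_model_weights(embedding, items)
noisy = np.clip(scaled.to_numpy()[None] + rng.normal(0, 0.3, (21,) + scaled.shape),
                0, 1).mean(axis=0)
model_sim = similarity_matrix(scaled)
rating_sim = similarity_matrix(noisy, item_ids=scaled.index)
r = compare_rsa(model_sim, rating_sim)
test = randomization_test(model_sim, rating_sim, n_perm=10_000, seed=SEED + 1)

print(f"embedding: {embedding.k} dimensions over {len(embedding.item_ids)} items")
print(f"model-vs-synthetic-rating similarity: r = {r:.2f}, "
      f"randomization p = {test.p_value:.5f} ({test.n_perm:,} shuffles)")

pd.DataFrame(model_sim.values, index=items, columns=items).to_csv(
    OUT / "model_similarity.tsv", sep="\t")
pd.DataFrame(rating_sim.values, index=items, columns=items).to_csv(
    OUT / "rating_similarity.tsv", sep="\t")
(OUT / "rsa_result.json").write_text(json.dumps(
    {"r": r, "p": test.p_value, "n_perm": test.n_perm}, indent=2))
print(f"wrote top8_per_dimension.tsv, dimension_profiles.tsv, "
      f"similarity matrices and rsa_result.json under {OUT}")
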