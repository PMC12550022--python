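#!/usr/bin/env python
"""Demonstrate the stimulus-curation pipeline on synthetic classifier output.

Generates synthetic per-frame class-probability vectors for 12 action
categories (3 videos x 5 frames each) with three built-in "meta-groups" of
mutually confusable categories, then: selects each video's best frame,
averages category representatives, computes cosine dissimilarities, cuts
the dendrogram, and applies the naming-accuracy exclusion rule to a
synthetic accuracy table.  Writes merge list, cluster table and exclusions.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from sposekit.curation import (category_representatives,
                               cosine_dissimilarity_matrix,
                               hierarchical_clusters, naming_accuracy_filter)

OUT = Path(__file__).resolve().parents[1] / "results"
rng = np.random.default_rng(7)

groups = {"locomotion": ["run", "walk", "jog", "sprint"],
          "manipulation": ["cut", "slice", "chop"],
          "social": ["hug", "wave", "greet", "salute", "bow"]}
categories = [c for group in groups.values() for c in group]
rows = []
for g, (group, members) in enumerate(groups.items()):
    for category in members:
        for video in range(3):
            for frame in range(5):
                # probability mass concentrated on the category and its group
                p = rng.dirichlet(np.ones(len(categories)) * 0.2)
                p = 0.1 * p
                own = categories.index(category)
                p[own] += 0.5 + 0.1 * rng.random()
                for other in members:
                    p[categories.index(other)] += 0.3 / len(members)
                p /= p.sum()
                rows.append([f"{category}_v{video}", category, frame, *p])
frames = pd.DataFrame(rows, columns=["video_id", "category", "frame_index",
                                     *categories])

profiles = category_representatives(frames)
dissim = cosine_dissimilarity_matrix(profiles)
clusters = hierarchical_clusters(dissim, linkage="average", n_clusters=3)

print(f"{len(profiles)} category representatives, "
      f"{len(clusters.cluster_sizes)} meta-clusters "
      f"(mean {clusters.mean_cluster_size:.1f} categories per cluster)")
for cid, size in sorted(clusters.cluster_sizes.items()):
    members = [c for c, l in clusters.labels.items() if l == cid]
    print(f"  cluster {cid}: {members}")

accuracies = {c: list(np.clip(rng.normal(0.85, 0.1, 3), 0, 1))
              for c in categories}
accuracies["jog"] = [0.55, 0.6, 0.8]       # hard to name: should be excluded
accuracies["greet"] = [0.5, 0.9, 0.95]     # one bad exemplar: retained
naming = naming_accuracy_filter(accuracies, threshold=0.7)
print(f"naming filter excluded: {naming.excluded}")

dissim.to_csv(OUT / "category_dissimilarity.tsv", sep="\t")
pd.DataFrame(clusters.merges,
             columns=["left", "right", "height", "size"]).to_csv(
    OUT / "dendrogram_merges.tsv", sep="\t", index=False)
pd.Series(clusters.labels, name="cluster").rename_axis("category").to_csv(
    OUT / "category_clusters.tsv", sep="\t")
(OUT / "naming_exclusions.json").write_text(json.dumps(
    {"retained": naming.retained, "excluded": naming.excluded,
     "reasons": naming.reasons}, indent=2))
print(f"wrote curation outputs under {OUT}")
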