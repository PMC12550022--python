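import numpy as np
import pytest

from sposekit import (GroundTruthEmbedding, WorkerProfile, build_design,
                      generate_ground_truth, simulate_dataset)


@pytest.fixture(scope="session")
def small_truth():
    """20 items, 3 latent dimensions — shared simulation ground truth."""
    return generate_ground_truth(n_items=20, k_true=3, seed=11)


@pytest.fixture(scope="session")
def one_dim_truth():
    """Three items on one dimension with weights (1, 1, 0).

    The closed-form odd-one-out distribution is (1, 1, e) / (e + 2).
    """
    weights = np.array([[1.0], [1.0], [0.0]])
    return GroundTruthEmbedding(weights=weights, item_ids=("i", "j", "k"), seed=0)


@pytest.fixture(scope="session")
def zero_truth():
    """Five items with all-zero weights: the uniform choice model."""
    weights = np.zeros((5, 2))
    ids = tuple(f"z{i}" for i in range(5))
    return GroundTruthEmbedding(weights=weights, item_ids=ids, seed=0)


@pytest.fixture(scope="session")
def compliant_dataset(small_truth):
    """Compliant-only simulated dataset over a pair-coverage design."""
    design = build_design(small_truth.item_ids, pair_coverage=8,
                          set_size=32, seed=5)
    profiles = [WorkerProfile.compliant(f"w{i:02d}") for i in range(10)]
    return simulate_dataset(small_truth, design, profiles, seed=6)
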