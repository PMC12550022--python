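import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sposekit import (EmbeddingMatrix, TrainingConfig, WorkerProfile,
                      build_design, choice_probabilities, prune_and_sort,
                      simulate_dataset, train)
from sposekit.choice import TripletBatch, gradient, loss, triplet_probabilities
from sposekit.model import choices_to_batch
from sposekit.synthetic import GroundTruthEmbedding


def random_batch(rng, n_items, size):
    a = np.empty(size, dtype=np.int64)
    b = np.empty(size, dtype=np.int64)
    c = np.empty(size, dtype=np.int64)
    for t in range(size):
        a[t], b[t], c[t] = rng.choice(n_items, 3, replace=False)
    return TripletBatch(a, b, c, rng.integers(0, 3, size))


def finite_difference_gradient(weights, batch, lam, h=1e-6):
    """Central-difference oracle for the loss gradient."""
    grad = np.zeros_like(weights)
    for i in range(weights.shape[0]):
        for j in range(weights.shape[1]):
            up = weights.copy()
            up[i, j] += h
            down = weights.copy()
            down[i, j] -= h
            grad[i, j] = (loss(up, batch, lam) - loss(down, batch, lam)) / (2 * h)
    return grad


class TestChoiceProbabilities:
    def test_zero_embedding_is_uniform(self):
        emb = EmbeddingMatrix(weights=np.zeros((4, 2)),
                              item_ids=("a", "b", "c", "d"),
                              dim_labels=("dim_001", "dim_002"))
        assert np.allclose(choice_probabilities(emb, ("a", "b", "c")), 1 / 3)

    def test_one_dimensional_closed_form(self):
        emb = EmbeddingMatrix(weights=np.array([[1.0], [1.0], [0.0]]),
                              item_ids=("i", "j", "k"), dim_labels=("dim_001",))
        p = choice_probabilities(emb, ("i", "j", "k"))
        assert p[2] == pytest.approx(math.e / (math.e + 2), abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_probabilities_normalize(self, seed):
        rng = np.random.default_rng(seed)
        weights = rng.random((6, 4)) * 3
        p = triplet_probabilities(weights, random_batch(rng, 6, 5))
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestLoss:
    def test_zero_embedding_chance_level(self):
        rng = np.random.default_rng(0)
        batch = random_batch(rng, 5, 10)
        assert loss(np.zeros((5, 3)), batch, 0.0) == pytest.approx(math.log(3))

    def test_single_triplet_hand_value(self):
        weights = np.array([[1.0], [1.0], [0.0]])
        batch = TripletBatch(*(np.array([i]) for i in (0, 1, 2)),
                             odd=np.array([2]))
        # -log p(odd=k) = log(e+2) - 1
        assert loss(weights, batch, 0.0) == pytest.approx(math.log(math.e + 2) - 1)

    def test_penalty_scaling(self):
        # lam=0.008, total weight 10, n_items=2 -> penalty 0.04 on top of CE
        weights = np.array([[5.0], [5.0]])
        batch = TripletBatch(np.array([0]), np.array([1]), np.array([0]),
                             odd=np.array([0]))
        # isolate the penalty by differencing against lam=0
        assert (loss(weights, batch, 0.008) - loss(weights, batch, 0.0)
                ) == pytest.approx(0.04)


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        weights = rng.random((5, 3))
        batch = random_batch(rng, 5, 8)
        lam = 0.008
        analytic = gradient(weights, batch, lam)
        numeric = finite_difference_gradient(weights, batch, lam)
        rel = np.abs(analytic - numeric) / np.maximum(1e-8, np.abs(numeric))
        assert rel.max() < 1e-6

    def test_at_zero_matrix_only_penalty_remains(self):
        rng = np.random.default_rng(7)
        batch = random_batch(rng, 5, 6)
        grad = gradient(np.zeros((5, 3)), batch, 0.008)
        assert np.allclose(grad, 0.008 / 5, atol=1e-15)

    def test_penalty_gradient_is_constant(self):
        rng = np.random.default_rng(8)
        weights = rng.random((4, 2))
        batch = random_batch(rng, 4, 6)
        diff = gradient(weights, batch, 0.5) - gradient(weights, batch, 0.0)
        assert np.allclose(diff, 0.5 / 4, atol=1e-12)


class TestPruneAndSort:
    def embedding(self, column_sums):
        n_items = 4
        weights = np.array([[s / n_items] * n_items for s in column_sums]).T
        return EmbeddingMatrix(
            weights=weights, item_ids=tuple(f"i{i}" for i in range(n_items)),
            dim_labels=tuple(f"dim_{j + 1:03d}" for j in range(len(column_sums))))

    def test_prunes_below_threshold_and_sorts_descending(self):
        pruned = prune_and_sort(self.embedding([0.05, 5.2, 0.3]), threshold=0.1)
        assert pruned.k == 2
        sums = pruned.weights.sum(axis=0)
        assert sums[0] == pytest.approx(5.2)
        assert sums[1] == pytest.approx(0.3)
        assert pruned.dim_labels == ("dim_001", "dim_002")

    def test_exact_threshold_survives(self):
        pruned = prune_and_sort(self.embedding([0.1, 1.0]), threshold=0.1)
        assert pruned.k == 2

    def test_all_above_threshold_only_reorders(self):
        pruned = prune_and_sort(self.embedding([1.0, 3.0, 2.0]), threshold=0.1)
        assert pruned.k == 3
        assert np.all(np.diff(pruned.weights.sum(axis=0)) <= 0)

    def test_all_pruned_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty embedding"):
            pruned = prune_and_sort(self.embedding([0.01, 0.02]), threshold=0.1)
        assert pruned.k == 0


class TestTrain:
    @pytest.fixture(scope="class")
    def separated_dataset(self):
        # 15 items on one dimension, two well-separated weight groups
        weights = np.concatenate([np.full(8, 2.0), np.zeros(7)])[:, None]
        ids = tuple(f"s{i:02d}" for i in range(15))
        truth = GroundTruthEmbedding(weights=weights, item_ids=ids, seed=0)
        design = build_design(ids, pair_coverage=13, set_size=32, seed=31)
        data = simulate_dataset(
            truth, design, [WorkerProfile.compliant(f"w{i}", lapse_rate=0.0)
                            for i in range(6)], seed=32)
        return truth, data.choices

    def test_learns_above_chance_on_separable_data(self, separated_dataset):
        truth, choices = separated_dataset
        config = TrainingConfig(k_init=10, max_epochs=80, window=20, seed=1)
        result = train(choices, truth.item_ids, config)
        assert result.holdout_accuracy > 1 / 3 + 0.05

    def test_same_seed_reproduces_result(self, separated_dataset):
        truth, choices = separated_dataset
        config = TrainingConfig(k_init=8, max_epochs=15, window=5, seed=3)
        a = train(choices, truth.item_ids, config)
        b = train(choices, truth.item_ids, config)
        assert np.array_equal(a.embedding.weights, b.embedding.weights)
        assert a.validation_loss_history == b.validation_loss_history
        assert a.holdout_accuracy == b.holdout_accuracy

    def test_k_effective_bounded_by_k_init(self, separated_dataset):
        truth, choices = separated_dataset
        config = TrainingConfig(k_init=6, max_epochs=15, window=5, seed=4)
        result = train(choices, truth.item_ids, config)
        assert result.k_effective <= 6

    def test_weights_stay_non_negative_throughout_training(self, separated_dataset):
        truth, choices = separated_dataset
        minima = []
        config = TrainingConfig(k_init=6, max_epochs=12, window=5, seed=5)
        train(choices, truth.item_ids, config,
              on_epoch_end=lambda epoch, w: minima.append(w.min()))
        assert len(minima) > 0
        assert min(minima) >= 0.0

    def test_validation_loss_improves_over_first_epoch(self, separated_dataset):
        truth, choices = separated_dataset
        config = TrainingConfig(k_init=10, max_epochs=60, window=20, seed=6)
        result = train(choices, truth.item_ids, config)
        assert min(result.validation_loss_history) <= result.validation_loss_history[0]

    def test_too_few_trials_rejected(self, separated_dataset):
        truth, choices = separated_dataset
        config = TrainingConfig(batch_size=128)
        with pytest.raises(ValueError, match="batch"):
            train(choices.head(50), truth.item_ids, config)

    def test_learned_probabilities_approach_empirical_frequencies(self):
        # 4 items, all 4 triplets shown many times: the fitted choice
        # probabilities should approach the empirical choice frequencies
        rng = np.random.default_rng(40)
        weights = np.array([[1.5, 0.0], [1.2, 0.3], [0.0, 1.4], [0.2, 1.0]])
        ids = ("a", "b", "c", "d")
        truth = GroundTruthEmbedding(weights=weights, item_ids=ids, seed=0)
        design = build_design(ids, repeat_n_triplets=4, repeat_count=700,
                              pair_coverage=0, set_size=32, seed=41)
        data = simulate_dataset(
            truth, design, [WorkerProfile.compliant("w", lapse_rate=0.0)],
            seed=42)
        config = TrainingConfig(k_init=4, lam=0.001, max_epochs=150,
                                window=40, seed=43)
        result = train(data.choices, truth.item_ids, config)

        batch = choices_to_batch(data.choices, ids)
        model_p = triplet_probabilities(result.embedding.weights, batch)
        kl_total = 0.0
        n_triplets = 0
        frame = data.choices.copy()
        frame["key"] = [tuple(sorted(t)) for t in zip(
            frame.stim_left, frame.stim_center, frame.stim_right)]
        for key, group in frame.groupby("key"):
            stims = group[["stim_left", "stim_center", "stim_right"]].to_numpy()
            pos = group["choice_position"].to_numpy() - 1
            chosen = stims[np.arange(len(group)), pos]
            emp = np.array([(chosen == s).mean() for s in key])
            rows = model_p[group.index.to_numpy()]
            model_mean = np.zeros(3)
            for r, row_stims in zip(rows, stims):
                for val, s in zip(r, row_stims):
                    model_mean[list(key).index(s)] += val
            model_mean /= len(group)
            emp_safe = np.clip(emp, 1e-9, 1)
            kl = float(np.sum(emp_safe * np.log(emp_safe /
                                                np.clip(model_mean, 1e-9, 1))))
            kl_total += kl
            n_triplets += 1
        assert kl_total / n_triplets < 0.02
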