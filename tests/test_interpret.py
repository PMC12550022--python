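import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sposekit.interpret import (RandomizationResult, compare_rsa,
                                dimension_profile, preprocess_ratings,
                                randomization_test, scale_model_weights,
                                similarity_matrix, top_ranking_items)
from sposekit.model import EmbeddingMatrix


def embedding_from(weights, ids=None):
    weights = np.asarray(weights, dtype=float)
    ids = tuple(ids or (f"i{k}" for k in range(weights.shape[0])))
    dims = tuple(f"dim_{j + 1:03d}" for j in range(weights.shape[1]))
    return EmbeddingMatrix(weights=weights, item_ids=ids, dim_labels=dims)


def sim_from(rows, ids=None):
    return similarity_matrix(np.asarray(rows, dtype=float), item_ids=ids)


def sim_from_triangle(lower):
    """3-item similarity matrix with the given strict lower triangle."""
    a, b, c = lower
    m = np.array([[1.0, a, b], [a, 1.0, c], [b, c, 1.0]])
    from sposekit.interpret import SimilarityMatrix
    return SimilarityMatrix(item_ids=("x", "y", "z"), values=m)


class TestTopRankingItems:
    def test_one_hot_column_puts_loading_item_first(self):
        emb = embedding_from([[0.0], [1.0], [0.0]])
        assert top_ranking_items(emb, "dim_001", 1) == ["i1"]

    def test_full_ordering_is_a_permutation(self):
        emb = embedding_from([[0.9, 0], [0.1, 0], [0.5, 0]])
        ranked = top_ranking_items(emb, "dim_001", 3)
        assert sorted(ranked) == ["i0", "i1", "i2"]
        assert ranked == ["i0", "i2", "i1"]

    def test_ties_break_lexicographically(self):
        emb = embedding_from([[0.5], [0.5], [0.9]], ids=("b", "a", "c"))
        assert top_ranking_items(emb, "dim_001", 3) == ["c", "a", "b"]

    def test_unknown_dimension_rejected(self):
        emb = embedding_from([[0.5], [0.5]])
        with pytest.raises(ValueError):
            top_ranking_items(emb, "dim_999", 1)


class TestDimensionProfile:
    def test_profile_is_the_embedding_row(self):
        emb = embedding_from([[0.2, 0.8], [0.0, 0.0]])
        profile = dimension_profile(emb, "i0")
        assert list(profile.index) == ["dim_001", "dim_002"]
        assert np.allclose(profile.to_numpy(), [0.2, 0.8])
        assert profile.sum() == pytest.approx(emb.weights[0].sum())

    def test_zero_row_item_gives_zero_profile(self):
        emb = embedding_from([[0.2, 0.8], [0.0, 0.0]])
        assert np.allclose(dimension_profile(emb, "i1").to_numpy(), 0.0)

    def test_unknown_item_rejected(self):
        emb = embedding_from([[0.2]])
        with pytest.raises(ValueError):
            dimension_profile(emb, "nope")


class TestPreprocessRatings:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["rater_id", "stimulus_id",
                                           "dimension_id", "level"])

    def test_not_at_all_maps_to_zero(self):
        out = preprocess_ratings(self.table([
            ("r1", "s", "d", "not_at_all"), ("r2", "s", "d", "not_at_all")]))
        assert out.loc["s", "d"] == 0.0

    def test_very_typical_maps_to_one(self):
        out = preprocess_ratings(self.table([("r1", "s", "d", "1")]))
        assert out.loc["s", "d"] == pytest.approx(1.0)

    def test_rater_average_after_mapping(self):
        out = preprocess_ratings(self.table([
            ("r1", "s", "d", "1"), ("r2", "s", "d", "7")]))
        assert out.loc["s", "d"] == pytest.approx((1.0 + 1 / 7) / 2)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ratings(self.table([("r1", "s", "d", "8")]))

    def test_duplicate_rating_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ratings(self.table([
                ("r1", "s", "d", "1"), ("r1", "s", "d", "2")]))


class TestSimilarityMatrix:
    def test_duplicated_rows_correlate_perfectly(self):
        m = sim_from([[1, 2, 3], [1, 2, 3]])
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_negated_rows_anticorrelate(self):
        m = sim_from([[1, 2, 3], [-1, -2, -3]])
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        m = sim_from([[1, 2, 3], [1, 2, 4]])
        assert m.values[0, 1] == pytest.approx(0.98198, abs=1e-5)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(1)
        m = sim_from(rng.random((6, 5)))
        assert np.allclose(m.values, m.values.T, atol=1e-12)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.all(np.abs(m.values) <= 1 + 1e-12)

    def test_zero_variance_row_flagged(self):
        m = sim_from([[1, 1, 1], [1, 2, 3], [2, 1, 0]])
        assert m.flagged_items == ("item_0000",)
        assert np.isnan(m.values[0, 1])
        assert np.isfinite(m.values[1, 2])


class TestScaleModelWeights:
    def test_min_max_endpoints(self):
        emb = embedding_from([[0.0], [5.0]])
        out = scale_model_weights(emb, ["i0", "i1"])
        assert list(out["dim_001"]) == [0.0, 1.0]

    def test_linear_rescaling(self):
        emb = embedding_from([[1.0], [2.0], [3.0]])
        out = scale_model_weights(emb, ["i0", "i1", "i2"])
        assert np.allclose(out["dim_001"], [0.0, 0.5, 1.0])

    def test_constant_dimension_maps_to_zero(self):
        emb = embedding_from([[2.0, 1.0], [2.0, 3.0]])
        out = scale_model_weights(emb, ["i0", "i1"])
        assert np.allclose(out["dim_001"], 0.0)


class TestCompareRsa:
    def test_self_comparison_is_exactly_one(self):
        m = sim_from([[1, 2, 3], [3, 1, 2], [1, 1, 4]])
        assert compare_rsa(m, m) == 1.0

    def test_linearly_related_triangles_correlate_perfectly(self):
        m1 = sim_from_triangle([0.1, 0.2, 0.3])
        m2 = sim_from_triangle([0.2, 0.4, 0.6])
        assert compare_rsa(m1, m2) == pytest.approx(1.0)

    def test_reversed_triangles_anticorrelate(self):
        m1 = sim_from_triangle([0.1, 0.2, 0.3])
        m2 = sim_from_triangle([0.3, 0.2, 0.1])
        assert compare_rsa(m1, m2) == pytest.approx(-1.0)

    def test_mismatched_items_rejected(self):
        m1 = sim_from([[1, 2, 3], [3, 1, 2]], ids=("a", "b"))
        m2 = sim_from([[1, 2, 3], [3, 1, 2]], ids=("a", "c"))
        with pytest.raises(ValueError):
            compare_rsa(m1, m2)


class TestRandomizationTest:
    def test_p_is_a_proportion_in_unit_interval(self):
        rng = np.random.default_rng(2)
        m1 = sim_from(rng.random((8, 5)))
        m2 = sim_from(rng.random((8, 5)))
        result = randomization_test(m1, m2, n_perm=200, seed=3)
        assert isinstance(result, RandomizationResult)
        assert 0.0 <= result.p_value <= 1.0
        assert len(result.perm_r) == 200

    def test_single_permutation_beating_observed_gives_one(self):
        # observed r is -1, so any single permutation reaches it
        m1 = sim_from_triangle([0.1, 0.2, 0.3])
        m2 = sim_from_triangle([0.3, 0.2, 0.1])
        result = randomization_test(m1, m2, n_perm=1, seed=0)
        assert result.observed_r == pytest.approx(-1.0)
        assert result.p_value == 1.0

    def test_observed_maximum_gives_minimal_p(self):
        # comparing a generic matrix with itself: only permutations that
        # happen to preserve the triangle can tie the observed r of 1
        rng = np.random.default_rng(4)
        m1 = sim_from(rng.random((8, 5)))
        result = randomization_test(m1, m1, n_perm=400, seed=4)
        ties = int((result.perm_r >= result.observed_r - 1e-12).sum())
        assert result.p_value <= ties / 400 + 1e-12

    def test_matched_structure_is_significant(self):
        rng = np.random.default_rng(5)
        base = rng.random((10, 6))
        m1 = sim_from(base)
        m2 = sim_from(base + rng.normal(0, 0.05, base.shape))
        result = randomization_test(m1, m2, n_perm=500, seed=6)
        assert result.observed_r > 0.9
        assert result.p_value <= 2 / 500

    def test_too_few_items_rejected(self):
        m = sim_from([[1, 2, 3], [3, 2, 1]], ids=("a", "b"))
        with pytest.raises(ValueError):
            randomization_test(m, m, n_perm=10, seed=0)

    def test_rsa_increases_as_rating_noise_decreases(self):
        # synthetic raters perceive the true weights plus noise: the
        # model-vs-rating agreement must grow as the noise shrinks
        rng = np.random.default_rng(7)
        weights = rng.random((12, 5)) * 2
        emb = embedding_from(weights)
        model_sim = similarity_matrix(
            scale_model_weights(emb, list(emb.item_ids)))
        correlations = []
        for noise in (2.0, 0.8, 0.2, 0.05):
            noisy = np.clip(weights + rng.normal(0, noise, weights.shape), 0, None)
            rating_sim = similarity_matrix(noisy, item_ids=emb.item_ids)
            correlations.append(compare_rsa(model_sim, rating_sim))
        assert correlations == sorted(correlations)
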