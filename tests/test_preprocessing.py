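import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grninfer as gi
from grninfer.io_model import ValidationError


class TestGeneFilter:
    def test_published_threshold_arithmetic(self):
        # 1 count per 20 cells at 44,343 cells
        assert gi.filter_threshold(44_343, 20) == 2217

    def test_filter_removes_low_count_genes(self):
        values = np.zeros((3, 40))
        values[1, :5] = 1.0   # total 5
        values[2, :] = 2.5 * 0 + np.tile([2, 3], 20)[:40]  # total 100
        expr = gi.GeneExpressionMatrix(values, ["a", "b", "c"],
                                       [f"s{i}" for i in range(40)])
        out, threshold = gi.filter_genes_by_total_count(expr, per_cells=20)
        assert threshold == 2
        assert out.gene_ids == ["b", "c"]

    def test_threshold_clamps_to_one(self):
        values = np.array([[0, 0], [1, 0]], float)
        expr = gi.GeneExpressionMatrix(values, ["z", "g"], ["s1", "s2"])
        out, threshold = gi.filter_genes_by_total_count(expr, per_cells=100)
        assert threshold == 1
        assert out.gene_ids == ["g"]

    def test_filter_invariant_to_sample_order(self, small_expr):
        perm = [3, 0, 2, 1]
        shuffled = small_expr.subset_samples(perm)
        a, _ = gi.filter_genes_by_total_count(small_expr, 2)
        b, _ = gi.filter_genes_by_total_count(shuffled, 2)
        assert a.gene_ids == b.gene_ids


class TestTransforms:
    def test_ftt_values(self, small_expr):
        out = gi.transform_counts(small_expr, "ftt")
        assert out.values[small_expr.values == 0].max() == 0 if (small_expr.values == 0).any() else True
        np.testing.assert_allclose(
            out.values, np.sqrt(small_expr.values + 1)
            + np.sqrt(small_expr.values) - 1)
        assert not out.is_counts

    def test_ftt_of_three(self):
        expr = gi.GeneExpressionMatrix(np.array([[3.0]]), ["g"], ["s"])
        out = gi.transform_counts(expr, "ftt")
        assert out.values[0, 0] == pytest.approx(np.sqrt(4) + np.sqrt(3) - 1)

    def test_log2_exact_power(self):
        expr = gi.GeneExpressionMatrix(np.array([[3.0, 0.0]]), ["g"],
                                       ["s1", "s2"])
        out = gi.transform_counts(expr, "log2")
        assert out.values[0, 0] == pytest.approx(2.0)
        assert out.values[0, 1] == 0.0

    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=2,
                    max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_zero_preserving(self, counts):
        values = np.array([sorted(counts)], float)
        expr = gi.GeneExpressionMatrix(values, ["g"],
                                       [f"s{i}" for i in range(values.shape[1])])
        for method in ("ftt", "log2"):
            out = gi.transform_counts(expr, method).values[0]
            assert np.all(np.diff(out) > 0)  # strictly monotone on distinct counts
            if values[0, 0] == 0:
                assert out[0] == 0.0

    def test_negative_input_rejected(self):
        expr = gi.GeneExpressionMatrix(np.array([[-1.0]]), ["g"], ["s"],
                                       is_counts=False)
        with pytest.raises(ValidationError):
            gi.transform_counts(expr, "ftt")

    def test_filter_commutes_with_transform(self, small_expr):
        filtered, _ = gi.filter_genes_by_total_count(small_expr, 2)
        a = gi.transform_counts(filtered, "ftt")
        b = gi.transform_counts(small_expr, "ftt").subset_genes(a.gene_ids)
        np.testing.assert_allclose(a.values, b.values)


class TestDepthNormalize:
    def test_columns_scaled_to_median(self):
        values = np.array([[4, 10], [6, 20]], float)  # totals 10, 30
        expr = gi.GeneExpressionMatrix(values, ["a", "b"], ["s1", "s2"])
        out = gi.depth_normalize(expr)
        np.testing.assert_allclose(out.values.sum(axis=0), [20, 20])
        np.testing.assert_allclose(out.values[:, 0], [8, 12])

    def test_equal_totals_is_identity(self):
        values = np.array([[5, 3], [5, 7]], float)
        expr = gi.GeneExpressionMatrix(values, ["a", "b"], ["s1", "s2"])
        out = gi.depth_normalize(expr)
        np.testing.assert_allclose(out.values, values)

    def test_zero_column_unchanged(self):
        values = np.array([[2, 0, 6], [2, 0, 6]], float)  # totals 4, 0, 12
        expr = gi.GeneExpressionMatrix(values, ["a", "b"], ["s1", "s2", "s3"])
        out = gi.depth_normalize(expr)
        np.testing.assert_allclose(out.values[:, 1], 0)
        # median over all three totals (4, 0, 12) is 4
        np.testing.assert_allclose(out.values.sum(axis=0), [4, 0, 4])


class TestNoiseControl:
    @pytest.fixture
    def counts(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(10, size=(20, 50)).astype(float)
        return gi.GeneExpressionMatrix(values, [f"g{i}" for i in range(20)],
                                       [f"s{j}" for j in range(50)])

    def test_column_totals_preserved(self, counts):
        out = gi.make_noise_control(counts, seed=1)
        np.testing.assert_allclose(out.values.sum(axis=0),
                                   counts.values.sum(axis=0), rtol=1e-10)

    def test_constant_gene_stays_constant_before_rescale(self):
        values = np.vstack([np.full(30, 7.0), np.arange(30, dtype=float)])
        expr = gi.GeneExpressionMatrix(values, ["const", "var"],
                                       [f"s{j}" for j in range(30)])
        draws = gi.preprocessing.noise_draws(expr, seed=3)
        np.testing.assert_allclose(draws[0], 7.0)

    def test_draw_means_match_gene_means(self):
        # wide matrix: per-gene draw means within 3 standard errors of mu_i
        rng = np.random.default_rng(9)
        values = rng.poisson(50, size=(5, 10_000)).astype(float)
        expr = gi.GeneExpressionMatrix(values, [f"g{i}" for i in range(5)],
                                       [f"s{j}" for j in range(10_000)])
        draws = gi.preprocessing.noise_draws(expr, seed=4)
        mu = values.mean(axis=1)
        sigma = values.std(axis=1)
        se = sigma / np.sqrt(values.shape[1])
        assert np.all(np.abs(draws.mean(axis=1) - mu) < 3 * se + 1e-9)

    def test_deterministic(self, counts):
        a = gi.make_noise_control(counts, seed=11)
        b = gi.make_noise_control(counts, seed=11)
        np.testing.assert_array_equal(a.values, b.values)


class TestShufflePrior:
    def test_degree_structure_preserved(self, small_prior):
        out = gi.shuffle_prior(small_prior, seed=0)
        assert out.n_edges == small_prior.n_edges
        # TF out-degrees exact
        np.testing.assert_array_equal((out.values != 0).sum(axis=1),
                                      (small_prior.values != 0).sum(axis=1))
        # multiset of gene in-degrees preserved
        assert sorted((out.values != 0).sum(axis=0)) == \
            sorted((small_prior.values != 0).sum(axis=0))

    def test_deterministic(self, small_prior):
        a = gi.shuffle_prior(small_prior, seed=3)
        b = gi.shuffle_prior(small_prior, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestAddRandomPriorEdges:
    def test_fraction_zero_is_identity(self, small_prior):
        out = gi.add_random_prior_edges(small_prior, 0.0, seed=0)
        np.testing.assert_array_equal(out.values, small_prior.values)

    def test_edge_count_arithmetic(self):
        rng = np.random.default_rng(0)
        values = (rng.random((10, 50)) < 0.2).astype(float)
        prior = gi.AdjacencyNetwork(values, [f"t{i}" for i in range(10)],
                                    [f"g{j}" for j in range(50)])
        out = gi.add_random_prior_edges(prior, 0.5, seed=1)
        assert out.n_edges == prior.n_edges + round(0.5 * prior.n_edges)

    def test_originals_untouched(self, small_prior):
        out = gi.add_random_prior_edges(small_prior, 0.5, seed=2)
        orig = small_prior.values != 0
        np.testing.assert_array_equal(out.values[orig],
                                      small_prior.values[orig])

    def test_insufficient_space_rejected(self):
        values = np.ones((2, 2))
        prior = gi.AdjacencyNetwork(values, ["a", "b"], ["x", "y"])
        with pytest.raises(ValidationError):
            gi.add_random_prior_edges(prior, 0.5, seed=0)
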