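"""Graph metrics: thresholding, closed-form small-graph values, null models."""

import numpy as np
import pytest

from jssenet.metrics import (
    BinaryGraph,
    binarize_at_sparsity,
    default_sparsity_grid,
    global_metrics,
    metrics_over_grid,
    nodal_metrics,
    rewire_null,
)
from jssenet.network import ConnectivityMatrix

from _bruteforce import (
    bf_betweenness,
    bf_distances,
    bf_efficiency,
    bf_nodal_clustering,
    bf_path_length,
)


def _random_weights(n, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return ConnectivityMatrix(values=w)


def _graph(edges, n):
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj, sparsity=0.5)


class TestBinarize:
    def test_exact_edge_count_n90(self):
        W = _random_weights(90)
        G = binarize_at_sparsity(W, 0.1)
        assert G.n_edges == 400  # floor(0.1 * 4005)

    def test_nestedness_under_distinct_weights(self):
        W = _random_weights(30, seed=1)
        big = binarize_at_sparsity(W, 0.4)
        small = binarize_at_sparsity(W, 0.15)
        assert np.all(big.adjacency >= small.adjacency)

    def test_dominant_edge_selected_first(self):
        w = np.zeros((5, 5))
        w[1, 3] = w[3, 1] = 9.0
        w[0, 1] = w[1, 0] = 0.1
        G = binarize_at_sparsity(ConnectivityMatrix(values=w), 0.1)
        assert G.n_edges == 1 and G.adjacency[1, 3] == 1

    def test_zero_edges_error(self):
        with pytest.raises(ValueError):
            binarize_at_sparsity(_random_weights(5), 0.05)

    def test_default_grid_has_49_levels(self):
        grid = default_sparsity_grid()
        assert grid.size == 49
        assert grid[0] == 0.02 and grid[-1] == 0.50


class TestClosedFormGraphs:
    def test_triangle(self):
        G = _graph([(0, 1), (1, 2), (0, 2)], 3)
        gm = global_metrics(G, n_null=1, seed=0)
        assert gm.clustering == pytest.approx(1.0)
        assert gm.path_length == pytest.approx(1.0)
        assert gm.global_efficiency == pytest.approx(1.0)
        nm = nodal_metrics(G)
        np.testing.assert_allclose(nm.degree, 2)
        np.testing.assert_allclose(nm.nodal_clustering, 1.0)

    def test_path_graph(self):
        G = _graph([(0, 1), (1, 2)], 3)
        gm = global_metrics(G, n_null=1, seed=0)
        assert gm.clustering == pytest.approx(0.0)
        assert gm.path_length == pytest.approx(4 / 3)  # (1+1+2)/3 by brute force

    def test_star_betweenness(self):
        G = _graph([(0, 1), (0, 2), (0, 3)], 4)
        nm = nodal_metrics(G)
        assert nm.betweenness[0] == pytest.approx(3.0)  # the 3 leaf pairs
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)

    def test_isolated_node_conventions(self):
        G = _graph([(0, 1), (1, 2), (0, 2)], 4)  # node 3 isolated
        nm = nodal_metrics(G)
        assert nm.degree[3] == 0
        assert nm.nodal_efficiency[3] == 0
        assert nm.nodal_clustering[3] == 0
        assert nm.nodal_path_length[3] == 0

    def test_sigma_is_gamma_over_lambda(self):
        W = _random_weights(25, seed=3)
        G = binarize_at_sparsity(W, 0.3)
        gm = global_metrics(G, n_null=5, seed=1)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_, rel=1e-9)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(20))
    def test_deterministic_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        adj = np.zeros((n, n), dtype=np.int8)
        iu = np.triu_indices(n, 1)
        mask = rng.random(iu[0].size) < 0.5
        if mask.sum() == 0:
            mask[0] = True
        adj[iu[0][mask], iu[1][mask]] = 1
        adj += adj.T
        G = BinaryGraph(adjacency=adj, sparsity=0.5)
        nm = nodal_metrics(G)
        dist = bf_distances(adj)
        np.testing.assert_allclose(nm.betweenness, bf_betweenness(adj), atol=1e-9)
        np.testing.assert_allclose(nm.nodal_clustering, bf_nodal_clustering(adj), atol=1e-12)
        gm = global_metrics(G, n_null=1, seed=0)
        assert gm.path_length == pytest.approx(bf_path_length(dist))
        assert gm.global_efficiency == pytest.approx(bf_efficiency(dist))


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        W = _random_weights(20, seed=5)
        G = binarize_at_sparsity(W, 0.25)
        for seed in range(5):
            null = rewire_null(G, seed=seed)
            np.testing.assert_array_equal(
                null.adjacency.sum(axis=1), G.adjacency.sum(axis=1)
            )
        # randomization actually changes the edge set for a dense-enough graph
        assert not np.array_equal(rewire_null(G, seed=0).adjacency, G.adjacency)

    def test_triangle_is_its_own_null(self):
        G = _graph([(0, 1), (1, 2), (0, 2)], 3)
        null = rewire_null(G, seed=0)
        np.testing.assert_array_equal(null.adjacency, G.adjacency)

    def test_random_graphs_have_gamma_near_one(self):
        # a random graph is statistically its own degree-preserving null;
        # average over instances because single-instance clustering is noisy
        gammas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 50
            adj = np.zeros((n, n), dtype=np.int8)
            iu = np.triu_indices(n, 1)
            pick = rng.choice(iu[0].size, size=200, replace=False)
            adj[iu[0][pick], iu[1][pick]] = 1
            adj += adj.T
            G = BinaryGraph(adjacency=adj, sparsity=200 / (n * (n - 1) / 2))
            gammas.append(global_metrics(G, n_null=10, seed=2).gamma)
        assert np.mean(gammas) == pytest.approx(1.0, abs=0.15)

    def test_lattice_graph_gamma_well_above_one(self):
        # a ring lattice is strongly clustered relative to its null
        n = 40
        adj = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for step in (1, 2, 3):
                j = (i + step) % n
                adj[i, j] = adj[j, i] = 1
        G = BinaryGraph(adjacency=adj, sparsity=0.15)
        gm = global_metrics(G, n_null=10, seed=3)
        assert gm.gamma > 1.5


class TestMetricsOverGrid:
    def test_single_threshold_equals_direct_evaluation(self):
        W = _random_weights(15, seed=6)
        M = metrics_over_grid(W, grid=np.array([0.3]), n_null=3, seed=9)
        G = binarize_at_sparsity(W, 0.3)
        nm = nodal_metrics(G)
        np.testing.assert_allclose(M.nodal_sum, nm.to_matrix())
        np.testing.assert_allclose(M.nodal_mean, nm.to_matrix())

    def test_trace_sums_match_reported_sums(self):
        W = _random_weights(12, seed=7)
        M = metrics_over_grid(
            W, grid=np.array([0.2, 0.35, 0.5]), n_null=2, seed=4, keep_trace=True
        )
        glob = np.stack([gm.to_array() for _, gm, _ in M.per_threshold])
        np.testing.assert_allclose(M.global_sum, glob.sum(axis=0), atol=1e-9)
        noda = np.stack([nm.to_matrix() for _, _, nm in M.per_threshold])
        np.testing.assert_allclose(M.nodal_sum, noda.sum(axis=0), atol=1e-9)

    def test_grid_must_ascend(self):
        W = _random_weights(10)
        with pytest.raises(ValueError):
            metrics_over_grid(W, grid=np.array([0.3, 0.2]), n_null=1)
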