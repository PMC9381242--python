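import numpy as np
import networkx as nx
import pytest

from netcog.connectome import BinaryGraph, ZMatrix
from netcog.graphmetrics import (NullConfig, NullEnsemble, auc,
                                 build_null_ensemble,
                                 characteristic_path_length,
                                 clustering_coefficient, global_efficiency,
                                 local_efficiency, metric_curves,
                                 node_efficiency, normalized_smallworld,
                                 rewire_null)

from _oracles import (clustering_oracle, global_efficiency_oracle,
                      local_efficiency_oracle, node_efficiency_oracle,
                      path_length_oracle, random_graph)


def _graph(edges, n):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(adjacency=a)


TRIANGLE = _graph([(0, 1), (1, 2), (0, 2)], 3)
STAR4 = _graph([(0, 1), (0, 2), (0, 3)], 4)
PATH3 = _graph([(0, 1), (1, 2)], 3)
K4_MINUS_EDGE = _graph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)], 4)
K5 = _graph([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)


class TestHandValues:
    def test_clustering(self):
        assert clustering_coefficient(TRIANGLE) == 1.0
        assert clustering_coefficient(STAR4) == 0.0
        # per-node coefficients (1, 1, 2/3, 2/3) average to 5/6
        assert clustering_coefficient(K4_MINUS_EDGE) == pytest.approx(5 / 6)

    def test_path_length(self):
        assert characteristic_path_length(K5) == 1.0
        assert characteristic_path_length(PATH3) == pytest.approx(4 / 3)

    def test_isolated_pair_is_undefined(self):
        g = _graph([], 2)
        with pytest.warns(UserWarning, match="disconnected"):
            assert np.isnan(characteristic_path_length(g))

    def test_global_efficiency(self):
        assert global_efficiency(K5) == 1.0
        assert global_efficiency(PATH3) == pytest.approx(5 / 6)
        assert global_efficiency(_graph([], 4)) == 0.0

    def test_local_efficiency(self):
        assert local_efficiency(TRIANGLE) == 1.0
        assert local_efficiency(STAR4) == 0.0

    def test_node_efficiency(self):
        assert node_efficiency(STAR4)[0] == 1.0          # star center
        assert node_efficiency(PATH3)[0] == pytest.approx(0.75)
        assert node_efficiency(_graph([(0, 1)], 3))[2] == 0.0  # isolated


def test_all_metrics_match_brute_force_on_small_graphs():
    """Shortest-path and subgraph metrics vs Floyd-Warshall oracles."""
    rng = np.random.default_rng(100)
    for _ in range(60):
        n = int(rng.integers(3, 9))
        adj = random_graph(n, float(rng.uniform(0.2, 0.8)), rng)
        g = BinaryGraph(adjacency=adj)
        assert global_efficiency(g) == pytest.approx(
            global_efficiency_oracle(adj), abs=1e-12)
        assert local_efficiency(g) == pytest.approx(
            local_efficiency_oracle(adj), abs=1e-12)
        assert clustering_coefficient(g) == pytest.approx(
            clustering_oracle(adj), abs=1e-12)
        ref_lp = path_length_oracle(adj)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lp = characteristic_path_length(g)
        if np.isnan(ref_lp):
            assert np.isnan(lp)
        else:
            assert lp == pytest.approx(ref_lp, abs=1e-12)
        assert node_efficiency(g) == pytest.approx(
            node_efficiency_oracle(adj), abs=1e-12)


def test_clustering_matches_networkx():
    rng = np.random.default_rng(5)
    for _ in range(20):
        adj = random_graph(10, 0.4, rng)
        g = BinaryGraph(adjacency=adj)
        assert clustering_coefficient(g) == pytest.approx(
            nx.average_clustering(nx.from_numpy_array(adj)), abs=1e-12)


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(6)
        adj = random_graph(30, 0.2, rng)
        g = BinaryGraph(adjacency=adj)
        null = rewire_null(g, 10, rng)
        assert np.array_equal(null.adjacency.sum(axis=0),
                              adj.sum(axis=0))
        assert (np.diag(null.adjacency) == 0).all()
        assert np.array_equal(null.adjacency, null.adjacency.T)

    def test_triangle_has_no_legal_swap(self):
        rng = np.random.default_rng(7)
        null = rewire_null(TRIANGLE, 10, rng)
        assert np.array_equal(null.adjacency, TRIANGLE.adjacency)

    def test_rewiring_changes_edges(self):
        rng = np.random.default_rng(8)
        adj = random_graph(100, 0.1, rng)
        null = rewire_null(BinaryGraph(adjacency=adj), 10, rng)
        overlap = (np.triu(adj, 1) & np.triu(null.adjacency, 1)).sum()
        assert overlap < np.triu(adj, 1).sum()

    def test_too_few_edges_warns(self):
        with pytest.warns(UserWarning, match="too few edges"):
            null = rewire_null(_graph([(0, 1)], 3), 10,
                               np.random.default_rng(9))
        assert np.array_equal(null.adjacency, _graph([(0, 1)], 3).adjacency)


class TestNormalizedSmallworld:
    def test_self_normalization(self):
        nulls = NullEnsemble(graphs=[K4_MINUS_EDGE], n_rewires_per_edge=0,
                             seed=0)
        gamma, lam, sigma = normalized_smallworld(K4_MINUS_EDGE, nulls)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_ring_lattice_is_clustered_vs_nulls(self):
        # ring lattice with k=4 neighbors: high clustering vs degree nulls
        n = 30
        a = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for d in (1, 2):
                a[i, (i + d) % n] = a[(i + d) % n, i] = 1
        g = BinaryGraph(adjacency=a)
        nulls = build_null_ensemble(g, NullConfig(n_nulls=20,
                                                  n_rewires_per_edge=10,
                                                  seed=3))
        gamma, lam, sigma = normalized_smallworld(g, nulls)
        assert gamma > 1.0
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            normalized_smallworld(TRIANGLE, NullEnsemble(
                graphs=[], n_rewires_per_edge=0, seed=0))


class TestMetricCurves:
    @staticmethod
    def _random_zmatrix(n, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, n)) * 0.3
        z = (z + z.T) / 2
        np.fill_diagonal(z, 1.0)
        return ZMatrix(z=z)

    def test_curve_lengths_and_aucs(self):
        zm = self._random_zmatrix(20, 10)
        grid = np.arange(10, 41) / 100
        cs = metric_curves(zm, grid, null_config=NullConfig(n_nulls=3, seed=0))
        assert set(cs.curves) == {"gamma", "lambda", "sigma", "cp", "lp",
                                  "eglobal", "elocal"}
        for curve in cs.curves.values():
            assert curve.shape == (31,)
        for name, curve in cs.curves.items():
            assert cs.aucs[name] == pytest.approx(auc(curve, grid))
        # sigma = gamma/lambda wherever defined
        assert cs.curves["sigma"] == pytest.approx(
            cs.curves["gamma"] / cs.curves["lambda"], abs=1e-12)

    def test_deterministic_given_null_seed(self):
        zm = self._random_zmatrix(15, 11)
        grid = np.arange(10, 41, 10) / 100
        a = metric_curves(zm, grid, null_config=NullConfig(n_nulls=3, seed=5))
        b = metric_curves(zm, grid, null_config=NullConfig(n_nulls=3, seed=5))
        for name in a.curves:
            assert np.array_equal(a.curves[name], b.curves[name])

    def test_eglobal_nondecreasing_in_sparsity(self):
        grid = np.arange(10, 41, 3) / 100
        for seed in range(20):
            zm = self._random_zmatrix(18, 200 + seed)
            cs = metric_curves(zm, grid, metrics=("eglobal",))
            assert (np.diff(cs.curves["eglobal"]) >= -1e-12).all()

    def test_invalid_grid_rejected(self):
        zm = self._random_zmatrix(10, 12)
        with pytest.raises(ValueError):
            metric_curves(zm, np.array([0.4, 0.2]), metrics=("cp",))
        with pytest.raises(ValueError):
            metric_curves(zm, np.array([0.0, 0.2]), metrics=("cp",))
        with pytest.raises(ValueError):
            metric_curves(zm, np.array([0.1, 0.2]), metrics=("gamma",))


class TestAUC:
    def test_constant_curve_is_rectangle(self):
        grid = np.arange(10, 41) / 100
        assert auc(np.full(31, 2.5), grid) == pytest.approx(0.3 * 2.5)

    def test_identity_curve_exact(self):
        grid = np.arange(10, 41) / 100
        # trapezoid is exact for linear curves: integral of s over [.1,.4]
        assert auc(grid, grid) == pytest.approx(0.075, abs=1e-15)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0]), np.array([0.1]))
        with pytest.raises(ValueError):
            auc(np.ones(3), np.ones(2))
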