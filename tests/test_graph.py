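import numpy as np
import pytest

from restfc import (
    BinaryAdjacency,
    SymmetricEdgeMatrix,
    binarize,
    characteristic_path_length,
    clustering_coefficients,
    degree_distribution_diagnostic,
    mean_degree,
    node_degrees,
    threshold_sweep,
)
from restfc.graph import global_efficiency


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryAdjacency(tuple(f"R{i}" for i in range(n)), a, 0.3)


def fc_matrix(values):
    values = np.asarray(values, dtype=float)
    return SymmetricEdgeMatrix(
        tuple(f"R{i}" for i in range(values.shape[0])), values, "pearson_r"
    )


class TestBinarize:
    def test_threshold_semantics_signed_and_strict(self):
        v = np.array(
            [
                [1.00, 0.31, 0.29, -0.90],
                [0.31, 1.00, 0.30, 0.50],
                [0.29, 0.30, 1.00, 0.10],
                [-0.90, 0.50, 0.10, 1.00],
            ]
        )
        adj = binarize(fc_matrix(v), 0.3).adjacency
        assert adj[0, 1] == 1        # 0.31 > 0.3
        assert adj[0, 2] == 0        # 0.29 < 0.3
        assert adj[1, 2] == 0        # exactly 0.30: strict inequality
        assert adj[0, 3] == 0        # -0.9: no absolute value
        assert adj[1, 3] == 1
        assert np.diag(adj).sum() == 0

    def test_edge_sets_nested_across_thresholds(self, rng):
        corr = np.corrcoef(rng.normal(size=(60, 8)), rowvar=False)
        np.fill_diagonal(corr, 1.0)
        fc = fc_matrix(corr)
        low = binarize(fc, 0.1).adjacency
        high = binarize(fc, 0.3).adjacency
        assert ((high == 1) <= (low == 1)).all()


class TestDegrees:
    def test_complete_k4(self):
        adj = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        np.testing.assert_array_equal(node_degrees(adj), 3)
        assert mean_degree(adj) == 3.0

    def test_star_with_three_leaves(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        np.testing.assert_array_equal(node_degrees(adj), [3, 1, 1, 1])
        assert mean_degree(adj) == 1.5

    def test_empty_graph(self):
        adj = adjacency_from_edges(3, [])
        assert mean_degree(adj) == 0.0


class TestClustering:
    def test_triangle_all_one(self):
        adj = adjacency_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(clustering_coefficients(adj), 1.0)

    def test_star_all_zero(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert clustering_coefficients(adj).mean() == 0.0

    def test_triangle_with_pendant(self):
        adj = adjacency_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])
        np.testing.assert_allclose(
            clustering_coefficients(adj), [1.0, 1.0, 1 / 3, 0.0]
        )
        assert clustering_coefficients(adj).mean() == pytest.approx(7 / 12)


class TestPathLength:
    def test_complete_graph_is_one(self):
        adj = adjacency_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        l, frac = characteristic_path_length(adj)
        assert l == 1.0 and frac == 0.0

    def test_path_graph_p3(self):
        adj = adjacency_from_edges(3, [(0, 1), (1, 2)])
        l, _ = characteristic_path_length(adj)
        assert l == pytest.approx(4 / 3)

    def test_star_with_three_leaves(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        l, _ = characteristic_path_length(adj)
        assert l == pytest.approx(1.5)

    def test_disconnected_pairs_reported_not_averaged(self):
        adj = adjacency_from_edges(4, [(0, 1), (2, 3)])
        l, frac = characteristic_path_length(adj)
        assert l == 1.0
        assert frac == pytest.approx(8 / 12)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(adjacency_from_edges(3, []))

    def test_global_efficiency_on_path_graph(self):
        adj = adjacency_from_edges(3, [(0, 1), (1, 2)])
        # ordered pairs: four at distance 1, two at distance 2
        assert global_efficiency(adj) == pytest.approx((4 * 1 + 2 * 0.5) / 6)


class TestAgainstNetworkx:
    def test_reference_match_on_random_graphs(self, rng):
        nx = pytest.importorskip("networkx")
        for k in range(100):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(1e6)))
            a = nx.to_numpy_array(g, dtype=int)
            if a.sum() == 0:
                continue
            adj = BinaryAdjacency(tuple(map(str, range(30))), a, 0.0)
            np.testing.assert_array_equal(
                node_degrees(adj), [d for _, d in sorted(g.degree())]
            )
            np.testing.assert_allclose(
                clustering_coefficients(adj),
                [nx.clustering(g)[i] for i in range(30)],
                atol=1e-10,
            )
            dists = dict(nx.all_pairs_shortest_path_length(g))
            finite = [d for i, row in dists.items() for j, d in row.items() if i != j]
            l, frac = characteristic_path_length(adj)
            assert l == pytest.approx(np.mean(finite), abs=1e-10)
            assert frac == pytest.approx(1 - len(finite) / (30 * 29), abs=1e-12)


@pytest.fixture(scope="module")
def fc(tiny_cohort):
    from restfc import pearson_fc

    return pearson_fc(tiny_cohort[1]["HC_001"])


class TestThresholdSweep:

    def test_sweep_has_41_records(self, fc):
        sweep = threshold_sweep(fc)
        assert len(sweep) == 41

    def test_mean_degree_non_increasing(self, fc):
        sweep = threshold_sweep(fc)
        assert (np.diff(sweep.mean_degree.to_numpy()) <= 1e-12).all()

    def test_threshold_below_min_r_gives_complete_graph(self, fc):
        thr = fc.upper_triangle().min() - 0.01
        sweep = threshold_sweep(fc, r_min=thr, r_max=thr, step=0.01)
        row = sweep.iloc[0]
        n = fc.n_rois
        assert row.mean_degree == n - 1
        assert row.char_path_length == 1.0


class TestScaleFreeDiagnostic:
    def _adjacency_with_degrees(self, degrees):
        nx = pytest.importorskip("networkx")
        g = nx.havel_hakimi_graph(list(degrees))
        a = nx.to_numpy_array(g, dtype=int)
        n = a.shape[0]
        return BinaryAdjacency(tuple(map(str, range(n))), a, 0.0)

    def test_exact_power_law_sequence_scores_high(self):
        # survival exactly a power law: 32 nodes of degree 2, 16 of 4, 8 of 8,
        # 4 of 16 -> log-log survival is a straight line
        degrees = [2] * 32 + [4] * 16 + [8] * 8 + [16] * 4
        adj = self._adjacency_with_degrees(degrees)
        assert degree_distribution_diagnostic(adj) > 0.95

    def test_non_power_law_distribution_scores_low(self):
        # survival decaying linearly in k is strongly curved in log-log
        # coordinates, so the straight-line fit must degrade
        degrees = [d for d in range(2, 22) for _ in range(5)]
        adj = self._adjacency_with_degrees(degrees)
        assert degree_distribution_diagnostic(adj) < 0.8

    def test_regular_graph_is_undefined(self):
        adj = self._adjacency_with_degrees([3] * 12)
        assert np.isnan(degree_distribution_diagnostic(adj))

    def test_too_few_connected_nodes_is_undefined(self):
        adj = adjacency_from_edges(12, [(0, 1)])
        assert np.isnan(degree_distribution_diagnostic(adj))
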