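"""Graph loading, per-vertex metrics, and the edge-density statistic."""

import numpy as np
import networkx as nx
import pytest

from voxelgraph.connectivity import plan_tiles, standardize, threshold_stream, write_edge_list
from voxelgraph.errors import (
    ConvergenceError,
    EdgeListParseError,
    StatisticUndefinedError,
    ThresholdRangeError,
    ValidationError,
)
from voxelgraph.graph import (
    SparseGraph,
    connected_components,
    degrees,
    edge_density_statistic,
    from_weighted_edges,
    load_edge_list,
    local_clustering,
    pagerank,
    select_threshold,
    triangle_counts,
)
from voxelgraph.nifti_io import VoxelTable

from .conftest import random_table
from .oracles import (
    components_bfs,
    pagerank_dense,
    random_simple_graph,
    triangles_bruteforce,
)


def graph_from_edges(n, pairs):
    return SparseGraph(n_vertices=n, edges=np.asarray(pairs, dtype=np.int64))


K4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
STAR = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
C6 = graph_from_edges(6, [(i, (i + 1) % 6) if i < (i + 1) % 6 else ((i + 1) % 6, i)
                          for i in range(6)])


class TestLoadEdgeList:
    def test_dedup_and_self_loops(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("0 1\n1 0\n1 1\n")
        g = load_edge_list(p)
        assert g.n_edges == 1
        np.testing.assert_array_equal(g.edges, [[0, 1]])

    def test_empty_file_with_n_vertices(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        g = load_edge_list(p, n_vertices=5)
        assert g.n_vertices == 5
        assert g.n_edges == 0

    def test_weight_column_ignored(self, tmp_path):
        p = tmp_path / "w.txt"
        p.write_text("# comment\n0 2 -0.75\n1 2 0.9\n")
        g = load_edge_list(p)
        assert g.n_edges == 2
        assert g.n_vertices == 3

    def test_write_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        z = standardize(random_table(rng, 30, 20))
        edges = threshold_stream(z, plan_tiles(20, 8, 20 * 8), 0.2)
        path = write_edge_list(edges, tmp_path / "rt.txt.gz")
        g = load_edge_list(path)
        assert g.n_vertices == 20  # recovered from the header, isolated kept
        np.testing.assert_array_equal(g.edges,
                                      np.column_stack([edges.i, edges.j]))

    def test_parse_error_has_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1\n2 froth\n")
        with pytest.raises(EdgeListParseError) as err:
            load_edge_list(p)
        assert err.value.line_number == 2

    def test_negative_id(self, tmp_path):
        p = tmp_path / "neg.txt"
        p.write_text("0 -3\n")
        with pytest.raises(ValidationError):
            load_edge_list(p)


class TestDegrees:
    def test_triangle(self):
        np.testing.assert_array_equal(degrees(graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])),
                                      [2, 2, 2])

    def test_star(self):
        np.testing.assert_array_equal(degrees(STAR), [3, 1, 1, 1])

    def test_handshake_lemma(self):
        rng = np.random.default_rng(1)
        edges = random_simple_graph(rng, 20, 0.3)
        g = SparseGraph(n_vertices=20, edges=edges)
        assert degrees(g).sum() == 2 * g.n_edges


class TestConnectedComponents:
    def test_min_member_labels(self):
        g = graph_from_edges(7, [(1, 2), (2, 3), (5, 6)])
        np.testing.assert_array_equal(connected_components(g), [0, 1, 1, 1, 4, 5, 5])

    def test_complete_graph(self):
        np.testing.assert_array_equal(connected_components(K4), [0, 0, 0, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        edges = random_simple_graph(rng, n, 0.05)
        g = SparseGraph(n_vertices=n, edges=edges)
        np.testing.assert_array_equal(connected_components(g),
                                      components_bfs(n, edges))

    def test_idempotent(self):
        g = graph_from_edges(7, [(1, 2), (2, 3), (5, 6)])
        first = connected_components(g)
        np.testing.assert_array_equal(first, connected_components(g))


class TestTriangles:
    def test_k4(self):
        np.testing.assert_array_equal(triangle_counts(K4), [3, 3, 3, 3])

    def test_path_has_none(self):
        np.testing.assert_array_equal(triangle_counts(PATH3), [0, 0, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_simple_graph(rng, 15, 0.4)
        g = SparseGraph(n_vertices=15, edges=edges)
        np.testing.assert_array_equal(triangle_counts(g),
                                      triangles_bruteforce(15, edges))

    def test_total_divisible_by_three(self):
        rng = np.random.default_rng(9)
        g = SparseGraph(n_vertices=40, edges=random_simple_graph(rng, 40, 0.2))
        assert triangle_counts(g).sum() % 3 == 0


class TestLocalClustering:
    def test_k4_fully_clustered(self):
        cc = local_clustering(degrees(K4), triangle_counts(K4))
        np.testing.assert_allclose(cc, 1.0)

    def test_path_middle_vertex(self):
        cc = local_clustering(degrees(PATH3), triangle_counts(PATH3))
        assert cc[1] == 0.0  # degree 2, no triangle

    def test_low_degree_convention(self):
        cc = local_clustering(np.array([0, 1]), np.array([0, 0]))
        np.testing.assert_array_equal(cc, [0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_networkx(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_simple_graph(rng, 30, 0.3)
        g = SparseGraph(n_vertices=30, edges=edges)
        cc = local_clustering(degrees(g), triangle_counts(g))
        G = nx.Graph()
        G.add_nodes_from(range(30))
        G.add_edges_from(edges.tolist())
        expected = np.array([nx.clustering(G, v) for v in range(30)])
        np.testing.assert_allclose(cc, expected, atol=1e-12)
        assert np.all((cc >= 0) & (cc <= 1))


class TestPageRank:
    def test_single_edge_symmetric(self):
        g = graph_from_edges(2, [(0, 1)])
        np.testing.assert_allclose(pagerank(g), [0.5, 0.5], atol=1e-9)

    def test_cycle_uniform(self):
        np.testing.assert_allclose(pagerank(C6), 1.0 / 6.0, atol=1e-8)

    def test_star_matches_dense_oracle(self):
        pr = pagerank(STAR, damping=0.85, tol=1e-12)
        oracle = pagerank_dense(4, STAR.edges, damping=0.85)
        np.testing.assert_allclose(pr, oracle, atol=1e-8)

    def test_sums_to_one_with_isolated_vertices(self):
        g = graph_from_edges(10, [(0, 1), (2, 3)])
        pr = pagerank(g)
        assert abs(pr.sum() - 1.0) < 1e-9

    def test_non_convergence_raises(self):
        # a star is far from the uniform starting vector, so one iteration
        # cannot reach a 1e-15 residual
        with pytest.raises(ConvergenceError):
            pagerank(STAR, tol=1e-15, max_iter=1)


class TestEdgeDensityStatistic:
    def test_direct_formula(self):
        s = edge_density_statistic(100, 40)
        assert s.K == 5.0
        np.testing.assert_allclose(s.S, np.log(100) / np.log(5))
        np.testing.assert_allclose(s.S, 2.8614, atol=5e-5)

    def test_exact_power(self):
        s = edge_density_statistic(64, 16)
        assert s.K == 8.0
        np.testing.assert_allclose(s.S, 2.0, atol=1e-12)

    def test_log_base_invariance(self):
        s = edge_density_statistic(123, 45)
        np.testing.assert_allclose(s.S, np.log10(123) / np.log10(2 * 123 / 45),
                                   atol=1e-12)

    def test_undefined_cases(self):
        with pytest.raises(StatisticUndefinedError):
            edge_density_statistic(0, 10)
        with pytest.raises(StatisticUndefinedError):
            edge_density_statistic(5, 10)  # K = 1


class TestSelectThreshold:
    def _two_community_table(self, seed=0):
        rng = np.random.default_rng(seed)
        T, size = 300, 20
        latents = rng.standard_normal((T, 2))
        data = rng.standard_normal((T, 2 * size))
        data[:, :size] += 3.0 * latents[:, :1]
        data[:, size:] += 3.0 * latents[:, 1:]
        return standardize(VoxelTable(data=data, index_map=np.arange(2 * size),
                                      grid_dims=(2 * size, 1, 1), affine=np.eye(4)))

    def test_planted_two_communities_matches_dense_oracle(self):
        """Selection agrees with a dense full-matrix scan applying the same rule."""
        from .oracles import pearson_matrix_bruteforce

        z = self._two_community_table()
        grid = np.arange(0.95, 0.04, -0.05)
        target = 1.5
        threshold, summary = select_threshold(z, target_S=target, grid=grid)
        assert summary.S >= target

        dense = pearson_matrix_bruteforce(z.table.data)
        iu, ju = np.triu_indices(z.n_voxels, k=1)
        absr = np.abs(dense[iu, ju])
        expected = None
        for t in sorted(grid, reverse=True):
            E = int((absr >= t).sum())
            K = 2 * E / z.n_voxels
            if E >= 1 and K > 1 and np.log(E) / np.log(K) >= target:
                expected = t
                break
        assert expected is not None and np.isclose(threshold, expected)

    def test_single_threshold_grid(self):
        z = self._two_community_table(1)
        threshold, summary = select_threshold(z, target_S=1.0, grid=np.array([0.5]))
        assert threshold == 0.5

    def test_returns_largest_qualifying(self):
        """Scanning down, the first threshold meeting the target is returned."""
        z = self._two_community_table(2)
        grid = np.arange(0.9, 0.04, -0.05)
        thr_loose, _ = select_threshold(z, target_S=1.2, grid=grid)
        thr_strict, _ = select_threshold(z, target_S=2.0, grid=grid)
        assert thr_loose >= thr_strict

    def test_unattainable_target(self):
        z = self._two_community_table(3)
        with pytest.raises(ThresholdRangeError):
            select_threshold(z, target_S=50.0, grid=np.arange(0.9, 0.04, -0.05))

    def test_edge_count_monotone_over_grid(self):
        z = self._two_community_table(4)
        plan = plan_tiles(z.n_voxels, 8, z.n_voxels * 8 * 7)
        counts = [threshold_stream(z, plan, t).n_edges
                  for t in np.arange(0.9, 0.04, -0.05)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPipelineInvariance:
    def test_stream_equals_dense_threshold(self):
        """Metrics from the streamed edge list equal metrics from the dense matrix."""
        rng = np.random.default_rng(21)
        z = standardize(random_table(rng, 40, 30))
        edges = threshold_stream(z, plan_tiles(30, 8, 9 * 30 * 8), 0.25)
        g_stream = from_weighted_edges(edges)

        from .oracles import pearson_matrix_bruteforce

        dense = pearson_matrix_bruteforce(z.table.data)
        iu, ju = np.triu_indices(30, k=1)
        keep = np.abs(dense[iu, ju]) >= 0.25
        g_dense = SparseGraph(n_vertices=30,
                              edges=np.column_stack([iu[keep], ju[keep]]))
        np.testing.assert_array_equal(degrees(g_stream), degrees(g_dense))
        np.testing.assert_array_equal(triangle_counts(g_stream),
                                      triangle_counts(g_dense))
        np.testing.assert_array_equal(connected_components(g_stream),
                                      connected_components(g_dense))
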