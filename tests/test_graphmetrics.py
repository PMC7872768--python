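"""Graph measures against analytic values, networkx, and exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from scnkit import graphmetrics as gm
from scnkit.data_io import ValidationError

from conftest import random_graph


def nx_graph(adj: np.ndarray) -> "nx.Graph":
    return nx.from_numpy_array(np.asarray(adj))


def path_graph(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def star_graph(n_leaves: int) -> np.ndarray:
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def complete_graph(n: int) -> np.ndarray:
    return (np.ones((n, n)) - np.eye(n)).astype(np.uint8)


def bc_exhaustive(adj: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating every shortest path (tiny graphs only)."""
    n = adj.shape[0]
    g = nx_graph(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


class TestDegree:
    def test_triangle_and_star(self):
        np.testing.assert_array_equal(gm.degree_sequence(complete_graph(3)), [2, 2, 2])
        np.testing.assert_array_equal(gm.degree_sequence(star_graph(3)), [3, 1, 1, 1])

    def test_handshake_lemma(self, rng):
        a = random_graph(rng, 25, 0.3)
        assert gm.degree_sequence(a).sum() == a.sum()

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        a[0, 1] = 1
        with pytest.raises(ValidationError):
            gm.degree_sequence(a)


class TestDistances:
    def test_path_graph_endpoints(self):
        d = gm.bfs_distances(path_graph(4))
        assert d[0, 3] == 3

    def test_disconnected_dyads_are_infinite(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        d = gm.bfs_distances(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        assert d[0, 1] == 1 and d[2, 3] == 1

    def test_matches_networkx_all_pairs(self, rng):
        for _ in range(10):
            a = random_graph(rng, rng.integers(5, 30), 0.2)
            d = gm.bfs_distances(a)
            expected = np.full_like(d, np.inf)
            np.fill_diagonal(expected, 0)
            for s, lengths in nx.all_pairs_shortest_path_length(nx_graph(a)):
                for t, hop in lengths.items():
                    expected[s, t] = hop
            np.testing.assert_array_equal(d, expected)


class TestPathLength:
    def test_complete_graph_is_one(self):
        assert gm.characteristic_path_length(complete_graph(7)) == pytest.approx(1.0)

    def test_four_node_path(self):
        # unordered pair distances: 1,1,1,2,2,3 -> mean 10/6
        assert gm.characteristic_path_length(path_graph(4)) == pytest.approx(10 / 6)

    def test_disconnected_mean_over_finite_distances(self, rng):
        a = random_graph(rng, 12, 0.12)
        d = gm.bfs_distances(a)
        off = ~np.eye(12, dtype=bool)
        finite = np.isfinite(d) & off
        if a.sum() == 0:
            pytest.skip("edgeless draw")
        assert gm.characteristic_path_length(a) == pytest.approx(d[finite].mean())

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValidationError):
            gm.characteristic_path_length(np.zeros((4, 4), dtype=np.uint8))


class TestEfficiencies:
    def test_complete_graph_global_efficiency_is_one(self):
        assert gm.global_efficiency(complete_graph(5)) == pytest.approx(1.0)

    def test_path_graph_global_efficiency(self):
        assert gm.global_efficiency(path_graph(4)) == pytest.approx(
            (1 + 0.5 + 1 / 3 + 1 + 0.5 + 1) / 6
        )

    def test_empty_graph_efficiency_is_zero(self):
        assert gm.global_efficiency(np.zeros((4, 4), dtype=np.uint8)) == 0.0

    def test_star_nodal_efficiency(self):
        e = gm.nodal_efficiency(star_graph(3))
        assert e[0] == pytest.approx(1.0)
        np.testing.assert_allclose(e[1:], 2 / 3)

    def test_mean_nodal_efficiency_equals_global(self, rng):
        a = random_graph(rng, 15, 0.3)
        assert gm.nodal_efficiency(a).mean() == pytest.approx(gm.global_efficiency(a))

    def test_local_efficiency_complete_k4(self):
        _, net = gm.local_efficiency(complete_graph(4))
        assert net == pytest.approx(1.0)

    def test_local_efficiency_star_is_zero(self):
        _, net = gm.local_efficiency(star_graph(4))
        assert net == 0.0


class TestClustering:
    def test_triangle_all_one_star_all_zero(self):
        c, cp = gm.clustering_coefficients(complete_graph(3))
        np.testing.assert_allclose(c, 1.0)
        assert cp == 1.0
        c, cp = gm.clustering_coefficients(star_graph(4))
        assert cp == 0.0


class TestBetweenness:
    def test_star_center_counts_leaf_pairs(self):
        bc = gm.betweenness_centrality(star_graph(3))
        assert bc[0] == pytest.approx(3.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_three_node_path_middle(self):
        bc = gm.betweenness_centrality(path_graph(3))
        np.testing.assert_allclose(bc, [0, 1, 0])

    def test_normalization_flag(self):
        bc = gm.betweenness_centrality(star_graph(4), normalized=True)
        assert bc[0] == pytest.approx(1.0)  # 6 pairs / ((5-1)(5-2)/2)

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            a = random_graph(rng, n, n_edges=int(rng.integers(3, 13)))
            np.testing.assert_allclose(
                gm.betweenness_centrality(a), bc_exhaustive(a), atol=1e-12
            )


class TestRewire:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        a = random_graph(rng, 20, 0.3)
        b = gm.degree_preserving_rewire(a, rng=rng)
        np.testing.assert_array_equal(gm.degree_sequence(a), gm.degree_sequence(b))
        assert a.sum() == b.sum()
        assert np.all(np.diag(b) == 0)

    def test_lattice_clustering_drops_after_rewiring(self, rng):
        g = nx.watts_strogatz_graph(60, 6, 0.0, seed=1)  # pure ring lattice
        a = nx.to_numpy_array(g).astype(np.uint8)
        _, cp0 = gm.clustering_coefficients(a)
        b = gm.degree_preserving_rewire(a, n_attempts=20 * int(a.sum() // 2), rng=rng)
        _, cp1 = gm.clustering_coefficients(b)
        assert cp1 < cp0


class TestSmallWorldness:
    def test_identity_when_null_equals_graph(self, rng, monkeypatch):
        a = random_graph(rng, 15, 0.4)
        monkeypatch.setattr(gm, "degree_preserving_rewire", lambda adj, **kw: adj)
        assert gm.small_worldness(a, n_null=3, rng=rng) == pytest.approx(1.0)

    def test_dense_random_graph_sigma_near_one(self):
        sigmas = []
        for s in range(20):
            rng = np.random.default_rng(s)
            a = random_graph(rng, 40, 0.4)
            sigmas.append(gm.small_worldness(a, n_null=10, rng=rng))
        assert 0.8 < np.mean(sigmas) < 1.2

    def test_small_world_ring_lattice_sigma_above_one(self):
        hits = 0
        runs = 50
        for s in range(runs):
            g = nx.watts_strogatz_graph(90, 8, 0.05, seed=s)
            a = nx.to_numpy_array(g).astype(np.uint8)
            sigma = gm.small_worldness(a, n_null=10, rng=np.random.default_rng(1000 + s))
            hits += sigma > 1
        assert hits >= 0.95 * runs


class TestInvariances:
    def test_metrics_invariant_under_node_relabeling(self, rng):
        a = random_graph(rng, 18, 0.3)
        perm = rng.permutation(18)
        b = a[np.ix_(perm, perm)]
        assert gm.clustering_coefficients(b)[1] == pytest.approx(
            gm.clustering_coefficients(a)[1]
        )
        assert gm.global_efficiency(b) == pytest.approx(gm.global_efficiency(a))
        np.testing.assert_allclose(
            gm.betweenness_centrality(a)[perm], gm.betweenness_centrality(b), atol=1e-10
        )
        np.testing.assert_allclose(
            gm.nodal_efficiency(a)[perm], gm.nodal_efficiency(b), atol=1e-12
        )

    def test_adding_edge_never_decreases_efficiency(self, rng):
        a = random_graph(rng, 15, 0.2)
        zeros = np.argwhere(np.triu(a == 0, 1))
        i, j = zeros[rng.integers(len(zeros))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        assert gm.global_efficiency(b) >= gm.global_efficiency(a)
        assert np.all(gm.nodal_efficiency(b) >= gm.nodal_efficiency(a) - 1e-12)
        da, db = gm.bfs_distances(a), gm.bfs_distances(b)
        assert np.all(db <= da)
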