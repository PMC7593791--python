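"""Unit and oracle tests for the topological metrics.

Independent routes used here: brute-force triangle enumeration and BFS for
clustering/path oracles, closed-form values on tiny named graphs, and
networkx for betweenness.
"""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from clubnet.connectome import BinaryNetwork, SparsityGrid
from clubnet.errors import ValidationError
from clubnet.graph_metrics import (
    auc_over_sparsity,
    characteristic_path_length,
    clustering,
    global_efficiency,
    global_metrics,
    local_efficiency,
    maslov_sneppen_rewire,
    nodal_metrics,
    null_ensemble,
    shortest_paths,
    small_world,
    NullEnsemble,
)
from conftest import net_from_edges


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_clustering(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def oracle_bfs_distances(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            for w in range(n):
                if adj[v, w] and np.isinf(dist[s, w]):
                    dist[s, w] = dist[s, v] + 1
                    q.append(w)
    return dist


def random_network(rng, n=None):
    n = n or int(rng.integers(4, 13))
    p = rng.uniform(0.15, 0.7)
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return BinaryNetwork(adj, 0.15)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClustering:
    def test_complete_k4(self):
        G = net_from_edges(4, combinations(range(4), 2))
        per, cp = clustering(G)
        np.testing.assert_allclose(per, 1.0)
        assert cp == 1.0

    def test_star_all_zero(self):
        G = net_from_edges(5, [(0, i) for i in range(1, 5)])
        per, cp = clustering(G)
        np.testing.assert_allclose(per, 0.0)
        assert cp == 0.0

    def test_four_cycle_with_chord(self):
        # cycle 0-1-2-3-0 plus chord 0-2: oracle gives (2/3, 1, 2/3, 1)
        G = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)])
        per, cp = clustering(G)
        np.testing.assert_allclose(
            per, oracle_clustering(G.adjacency), atol=1e-12)
        assert cp == pytest.approx(5 / 6)


class TestShortestPaths:
    def test_path_graph(self):
        G = net_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_paths(G)
        assert d[0, 2] == 2

    def test_disconnected_infinite(self):
        G = net_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_paths(G)
        assert np.isinf(d[0, 2])

    def test_petersen_diameter_two(self):
        g = nx.petersen_graph()
        adj = nx.to_numpy_array(g).astype(int)
        d = shortest_paths(BinaryNetwork(adj, 0.15))
        off = ~np.eye(10, dtype=bool)
        nonadj = off & (adj == 0)
        assert (d[nonadj] == 2).all()


class TestPathLengthAndEfficiency:
    def test_complete_graph_lp_one(self):
        G = net_from_edges(5, combinations(range(5), 2))
        assert characteristic_path_length(shortest_paths(G)) == 1.0
        assert global_efficiency(shortest_paths(G)) == 1.0

    def test_p3_enumeration(self):
        G = net_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_paths(G)
        assert characteristic_path_length(d) == pytest.approx(4 / 3)
        assert global_efficiency(d) == pytest.approx(5 / 6)

    def test_two_disjoint_edges_reachable_only(self):
        G = net_from_edges(4, [(0, 1), (2, 3)])
        assert characteristic_path_length(shortest_paths(G)) == 1.0

    def test_edgeless(self):
        G = net_from_edges(4, [])
        assert global_efficiency(shortest_paths(G)) == 0.0
        with pytest.raises(ValidationError, match="reachable"):
            characteristic_path_length(shortest_paths(G))

    def test_local_efficiency_named_graphs(self):
        K4 = net_from_edges(4, combinations(range(4), 2))
        assert local_efficiency(K4) == pytest.approx(1.0)
        star = net_from_edges(5, [(0, i) for i in range(1, 5)])
        assert local_efficiency(star) == 0.0
        # K4 minus edge (2,3): oracle via induced subgraphs
        G = net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        expected = []
        adj = G.adjacency
        for i in range(4):
            nbrs = np.flatnonzero(adj[i])
            sub = adj[np.ix_(nbrs, nbrs)]
            expected.append(
                global_efficiency(
                    oracle_bfs_distances(sub)) if nbrs.size >= 2 else 0.0)
        assert local_efficiency(G) == pytest.approx(np.mean(expected))

    def test_eg_vs_inverse_lp_jensen(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            G = random_network(rng)
            d = shortest_paths(G)
            if np.isinf(d).any() or G.n_edges == 0:
                continue
            assert global_efficiency(d) >= 1.0 / characteristic_path_length(d)


class TestNodalMetrics:
    def test_star_center_and_leaf(self):
        G = net_from_edges(5, [(0, i) for i in range(1, 5)])
        nd = nodal_metrics(G)
        assert nd.betweenness[0] == pytest.approx(1.0)
        assert nd.nodal_efficiency[0] == pytest.approx(1.0)
        assert nd.betweenness[1] == 0.0
        assert nd.degree[0] == 4

    def test_complete_graph_lp(self):
        G = net_from_edges(4, combinations(range(4), 2))
        nd = nodal_metrics(G)
        np.testing.assert_allclose(nd.nodal_Lp, 1.0)

    def test_against_oracles_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            G = random_network(rng)
            nd = nodal_metrics(G)
            adj = G.adjacency
            n = G.n_nodes
            # clustering oracle
            np.testing.assert_allclose(
                nd.nodal_clustering, oracle_clustering(adj), atol=1e-12)
            # distances oracle -> efficiency / Lp
            d = oracle_bfs_distances(adj)
            off = ~np.eye(n, dtype=bool)
            eff = np.where(off & np.isfinite(d), 1.0 / np.where(d > 0, d, 1),
                           0.0).sum(axis=1) / (n - 1)
            np.testing.assert_allclose(nd.nodal_efficiency, eff, atol=1e-12)
            # betweenness vs networkx
            g = nx.from_numpy_array(adj)
            bc = nx.betweenness_centrality(g, normalized=True)
            np.testing.assert_allclose(
                nd.betweenness, [bc[i] for i in range(n)], atol=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        G = random_network(rng, n=10)
        perm = rng.permutation(10)
        adj_p = G.adjacency[np.ix_(perm, perm)]
        Gp = BinaryNetwork(adj_p, 0.15)
        nd, ndp = nodal_metrics(G), nodal_metrics(Gp)
        np.testing.assert_allclose(ndp.nodal_efficiency,
                                   nd.nodal_efficiency[perm], atol=1e-12)
        _, cp = clustering(G)
        _, cpp = clustering(Gp)
        assert cp == pytest.approx(cpp, abs=1e-12)


class TestNullModel:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(4)
        G = random_network(rng, n=12)
        null, done = maslov_sneppen_rewire(G, rng)
        np.testing.assert_array_equal(
            np.sort(null.adjacency.sum(0)), np.sort(G.adjacency.sum(0)))
        np.testing.assert_array_equal(
            null.adjacency.sum(0), G.adjacency.sum(0))

    def test_star_admits_no_swap(self):
        G = net_from_edges(5, [(0, i) for i in range(1, 5)])
        null, done = maslov_sneppen_rewire(G, np.random.default_rng(0))
        assert done == 0
        np.testing.assert_array_equal(null.adjacency, G.adjacency)

    def test_er_graph_self_null(self):
        g = nx.gnp_random_graph(50, 0.2, seed=1)
        G = BinaryNetwork(nx.to_numpy_array(g).astype(int), 0.2)
        _, cp = clustering(G)
        ens = null_ensemble(G, n_null=100, seed=0)
        gamma = cp / ens.Cp_rand
        lam = characteristic_path_length(shortest_paths(G)) / ens.Lp_rand
        assert 0.8 <= gamma <= 1.2
        assert 0.8 <= lam <= 1.2

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        G = random_network(rng, n=12)
        e1 = null_ensemble(G, n_null=5, seed=77)
        e2 = null_ensemble(G, n_null=5, seed=77)
        assert e1.Cp_rand == e2.Cp_rand
        assert e1.Lp_rand == e2.Lp_rand


class TestSmallWorld:
    def test_identity_null(self):
        ens = NullEnsemble(Cp_rand=0.3, Lp_rand=2.0, n_null=1, seed=0)
        g, l, s = small_world(0.3, 2.0, ens)
        assert (g, l, s) == (1.0, 1.0, 1.0)

    def test_arithmetic(self):
        ens = NullEnsemble(Cp_rand=1.0, Lp_rand=1.0, n_null=1, seed=0)
        g, l, s = small_world(2.0, 1.0, ens)
        assert s == 2.0

    def test_zero_null_mean_error(self):
        with pytest.raises(ValidationError):
            small_world(0.5, 1.0, NullEnsemble(0.0, 1.0, 1, 0))

    def test_watts_strogatz_sigma_above_one(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=3)
        G = BinaryNetwork(nx.to_numpy_array(g).astype(int), 0.06)
        m = global_metrics(G, n_null=100, seed=5)
        assert m.sigma > 1.0
        assert m.sigma == pytest.approx(m.gamma / m.lambda_)


class TestAUC:
    def test_constant_curve(self):
        grid = SparsityGrid.default()
        assert auc_over_sparsity(np.ones(10), grid) == pytest.approx(0.45)
        assert auc_over_sparsity(np.zeros(10), grid) == 0.0

    def test_linear_ramp(self):
        grid = SparsityGrid.default()
        vals = np.linspace(0, 1, 10)
        assert auc_over_sparsity(vals, grid) == pytest.approx(0.225)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            auc_over_sparsity(np.ones(9), SparsityGrid.default())
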