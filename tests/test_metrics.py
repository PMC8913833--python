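"""Graph metrics against brute-force and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from metabnet.errors import InvalidParameterError, UndefinedRatioError
from metabnet.metrics import (global_efficiency, local_efficiency,
                              rewire_preserving_degree, shortest_path_lengths,
                              small_worldness)

from conftest import (brute_global_eff, brute_local_eff, floyd_warshall_hops,
                      net_from_edges, random_net)


class TestShortestPaths:
    def test_complete_graph_distances_all_one(self):
        net = net_from_edges(4, itertools.combinations(range(4), 2))
        d = shortest_path_lengths(net)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d[off] == 1.0)
        assert np.all(np.diag(d) == 0.0)

    def test_path_graph_two_hops(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        assert shortest_path_lengths(net)[0, 2] == 2.0

    def test_disconnected_pair_is_infinite(self):
        net = net_from_edges(3, [(0, 1)])
        assert np.isinf(shortest_path_lengths(net)[0, 2])

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            net = random_net(8, int(rng.integers(0, 15)), rng)
            np.testing.assert_array_equal(
                shortest_path_lengths(net),
                floyd_warshall_hops(net.adjacency))


class TestGlobalEfficiency:
    @pytest.mark.parametrize("m", [3, 5, 8])
    def test_complete_graph_is_one(self, m):
        net = net_from_edges(m, itertools.combinations(range(m), 2))
        assert global_efficiency(net) == pytest.approx(1.0)

    def test_edgeless_graph_is_zero(self):
        assert global_efficiency(net_from_edges(5, [])) == 0.0

    def test_path_graph_on_three_nodes(self):
        # pairs (0,1), (1,2) at distance 1 and (0,2) at distance 2:
        # (1 + 1 + 1/2)/3 = 5/6
        net = net_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(net) == pytest.approx(5 / 6)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            net = random_net(7, 6, rng)
            adj = net.adjacency.copy()
            free = [(i, j) for i in range(7) for j in range(i + 1, 7)
                    if not adj[i, j]]
            i, j = free[rng.integers(len(free))]
            adj[i, j] = adj[j, i] = True
            denser = net_from_edges(7, np.argwhere(np.triu(adj, 1)))
            assert global_efficiency(denser) >= global_efficiency(net)

    def test_matches_networkx(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            net = random_net(9, int(rng.integers(2, 20)), rng)
            g = nx.from_numpy_array(net.adjacency.astype(int))
            assert global_efficiency(net) == pytest.approx(
                nx.global_efficiency(g))


class TestLocalEfficiency:
    def test_triangle_every_node_one(self):
        net = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert list(local_efficiency(net).values()) == pytest.approx([1, 1, 1])

    def test_star_center_zero(self):
        net = net_from_edges(5, [(0, i) for i in range(1, 5)])
        el = local_efficiency(net)
        assert el["m0"] == 0.0          # hub neighbours mutually unconnected
        assert all(v == 0.0 for v in el.values())  # leaves have degree 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            net = random_net(8, int(rng.integers(2, 20)), rng)
            vals = np.array(list(local_efficiency(net).values()))
            np.testing.assert_allclose(vals, brute_local_eff(net.adjacency),
                                       atol=1e-12)

    def test_matches_networkx_average(self):
        rng = np.random.default_rng(18)
        for _ in range(5):
            net = random_net(9, 14, rng)
            g = nx.from_numpy_array(net.adjacency.astype(int))
            mean_el = np.mean(list(local_efficiency(net).values()))
            assert mean_el == pytest.approx(nx.local_efficiency(g))

    def test_node_relabeling_permutes_values(self):
        rng = np.random.default_rng(19)
        net = random_net(7, 10, rng)
        perm = rng.permutation(7)
        permuted = net_from_edges(
            7, np.argwhere(np.triu(net.adjacency[np.ix_(perm, perm)], 1)))
        orig = np.array(list(local_efficiency(net).values()))
        relab = np.array(list(local_efficiency(permuted).values()))
        np.testing.assert_allclose(relab, orig[perm], atol=1e-12)
        assert global_efficiency(net) == pytest.approx(
            global_efficiency(permuted))


class TestRewiring:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(20)
        for seed in range(10):
            net = random_net(11, 20, rng)
            rewired = rewire_preserving_degree(net, seed=seed)
            np.testing.assert_array_equal(rewired.degree_sequence(),
                                          net.degree_sequence())
            assert rewired.n_edges == net.n_edges
            assert not np.any(np.diag(rewired.adjacency))

    def test_complete_graph_returned_unchanged(self):
        net = net_from_edges(5, itertools.combinations(range(5), 2))
        with pytest.warns(RuntimeWarning, match="under-mixed"):
            rewired = rewire_preserving_degree(net, seed=1)
        np.testing.assert_array_equal(rewired.adjacency, net.adjacency)

    def test_single_edge_returned_unchanged_with_warning(self):
        net = net_from_edges(4, [(0, 1)])
        with pytest.warns(RuntimeWarning):
            rewired = rewire_preserving_degree(net, seed=0)
        np.testing.assert_array_equal(rewired.adjacency, net.adjacency)

    def test_rewiring_actually_randomizes(self):
        # with 10 swaps/edge on a 20-edge graph, the adjacency should differ
        # from the original in >= 95/100 seeds
        net = random_net(11, 20, np.random.default_rng(21))
        changed = sum(
            not np.array_equal(
                rewire_preserving_degree(net, seed=s).adjacency, net.adjacency)
            for s in range(100))
        assert changed >= 95

    def test_determinism(self):
        net = random_net(10, 15, np.random.default_rng(22))
        a = rewire_preserving_degree(net, seed=5)
        b = rewire_preserving_degree(net, seed=5)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorldness:
    def test_ring_lattice_is_small_world(self):
        # 12 nodes, each linked to its 4 nearest neighbours: high clustering,
        # so sigma > 1 against degree-matched rewirings
        edges = [(i, (i + d) % 12) for i in range(12) for d in (1, 2)]
        net = net_from_edges(12, edges)
        res = small_worldness(net, n_random=200, seed=7)
        assert res.sigma > 1
        assert res.meets_criterion

    def test_invariants_of_result(self):
        net = random_net(9, 14, np.random.default_rng(23))
        res = small_worldness(net, n_random=100, seed=3)
        assert res.gamma == pytest.approx(
            res.real.e_global / res.rand_e_global_mean)
        assert res.lam == pytest.approx(
            res.real.e_local_mean / res.rand_e_local_mean)
        assert res.sigma == pytest.approx(res.lam / res.gamma)
        assert res.meets_criterion == (res.sigma > 1)

    def test_determinism(self):
        net = random_net(9, 14, np.random.default_rng(24))
        a = small_worldness(net, n_random=50, seed=11)
        b = small_worldness(net, n_random=50, seed=11)
        assert a == b

    def test_degenerate_ensemble_raises(self):
        # two disjoint edges: every rewiring has zero local efficiency
        net = net_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(UndefinedRatioError):
            small_worldness(net, n_random=20, seed=0)

    def test_edgeless_network_rejected(self):
        with pytest.raises(InvalidParameterError):
            small_worldness(net_from_edges(4, []), n_random=10, seed=0)
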