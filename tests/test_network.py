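"""Topology metrics against hand evaluations and brute-force path oracles."""
import math

import networkx as nx
import pytest

from odornet import (all_pairs_shortest_paths, betweenness,
                     clustering_coefficient, network_summary, node_topology,
                     simulate_network, stress)
from odornet.network import all_node_topologies


def oracle_paths(G):
    """Independent brute force: enumerate every simple path, keep minimal
    ones; returns dist, sigma and per-node through-counts per ordered pair."""
    nodes = list(G.nodes)
    dist, sigma, through = {}, {}, {n: {} for n in nodes}
    for s in nodes:
        stack = [(s, frozenset([s]), (s,))]
        while stack:
            v, seen, path = stack.pop()
            for w in G[v]:
                if w in seen:
                    continue
                p2 = path + (w,)
                L = len(p2) - 1
                key = (s, w)
                d = dist.get(key)
                if d is None or L < d:
                    dist[key] = L
                    sigma[key] = 1
                    for n in nodes:
                        through[n].pop(key, None)
                    for n in p2[1:-1]:
                        through[n][key] = 1
                elif L == d:
                    sigma[key] += 1
                    for n in p2[1:-1]:
                        through[n][key] = through[n].get(key, 0) + 1
                stack.append((w, seen | {w}, p2))
    return dist, sigma, through


def oracle_betweenness_stress(G, n, dist, sigma, through):
    bt = st = 0.0
    nodes = [v for v in G.nodes if v != n]
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            total = sigma.get((s, t), 0)
            if total == 0:
                continue
            on_n = through[n].get((s, t), 0)
            bt += on_n / total
            st += on_n
    return bt, st


class TestShortestPaths:
    def test_path_graph(self):
        G = nx.path_graph(["a", "b", "c"])
        dist, sigma = all_pairs_shortest_paths(G)
        assert dist["a"]["c"] == 2 and sigma["a"]["c"] == 1

    def test_four_cycle_two_routes(self):
        G = nx.cycle_graph(["a", "b", "c", "d"])
        _, sigma = all_pairs_shortest_paths(G)
        assert sigma["a"]["c"] == 2

    def test_disconnected_pair_flags(self):
        G = nx.Graph([("a", "b")])
        G.add_node("c")
        dist, sigma = all_pairs_shortest_paths(G)
        assert math.isinf(dist["a"]["c"]) and sigma["a"]["c"] == 0

    def test_sigma_matches_brute_force_on_random_graphs(self):
        for seed in range(60):
            G = simulate_network(8, "erdos_renyi", 0.3, seed=seed)
            dist, sigma = all_pairs_shortest_paths(G)
            odist, osigma, _ = oracle_paths(G)
            for s in G.nodes:
                for t in G.nodes:
                    if s == t:
                        continue
                    assert dist[s][t] == odist.get((s, t), math.inf)
                    assert sigma[s][t] == osigma.get((s, t), 0)


class TestClustering:
    def test_triangle(self):
        G = nx.complete_graph(3)
        assert clustering_coefficient(G, 0) == 1.0

    def test_star_center(self):
        G = nx.star_graph(3)
        assert clustering_coefficient(G, 0) == 0.0

    def test_one_of_three_neighbor_pairs(self):
        G = nx.Graph([("n", "a"), ("n", "b"), ("n", "c"), ("a", "b")])
        assert clustering_coefficient(G, "n") == pytest.approx(1 / 3)

    def test_matches_networkx(self):
        for seed in range(20):
            G = simulate_network(10, "erdos_renyi", 0.4, seed=seed)
            ref = nx.clustering(G)
            for n in G.nodes:
                assert clustering_coefficient(G, n) == pytest.approx(ref[n])


class TestBetweennessAndStress:
    def test_path_middle_node(self):
        G = nx.path_graph(["a", "b", "c"])
        assert betweenness(G, "b") == 1.0
        assert stress(G, "b") == 1

    def test_leaves_are_zero(self):
        G = nx.random_labeled_tree(9, seed=5)
        leaves = [n for n in G.nodes if G.degree(n) == 1]
        for leaf in leaves:
            assert betweenness(G, leaf) == 0.0
            assert stress(G, leaf) == 0

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(40):
            G = simulate_network(7, "erdos_renyi", 0.35, seed=seed)
            data = oracle_paths(G)
            for n in G.nodes:
                bt, st = oracle_betweenness_stress(G, n, *data)
                assert betweenness(G, n) == pytest.approx(bt)
                assert stress(G, n) == st

    def test_matches_networkx_unnormalized(self):
        for seed in range(20):
            G = simulate_network(9, "erdos_renyi", 0.35, seed=seed)
            ref = nx.betweenness_centrality(G, normalized=False)
            for n in G.nodes:
                assert betweenness(G, n) == pytest.approx(ref[n])

    def test_tree_betweenness_sum_identity(self):
        # unique shortest paths: sum of raw betweenness = sum of (d_st - 1)
        G = nx.random_labeled_tree(10, seed=3)
        dist, _ = all_pairs_shortest_paths(G)
        nodes = list(G.nodes)
        expected = sum(dist[s][t] - 1 for i, s in enumerate(nodes)
                       for t in nodes[i + 1:])
        total = sum(betweenness(G, n) for n in G.nodes)
        assert total == pytest.approx(expected)


class TestNodeTopology:
    def test_isolated_node(self):
        G = nx.Graph()
        G.add_nodes_from(["a", "b"])
        G.add_edge("a", "b")
        G.add_node("z")
        t = node_topology(G, "z")
        assert t.eccentricity == 0 and t.stress == 0
        assert math.isnan(t.closeness)

    def test_path_hand_values(self):
        G = nx.path_graph(["a", "b", "c"])
        assert node_topology(G, "b").stress == 1
        assert node_topology(G, "a").neighborhood_connectivity == 2.0

    def test_complete_graph_symmetric_case(self):
        G = nx.complete_graph(4)
        t = node_topology(G, 0)
        assert t.closeness == 1.0 and t.clustering == 1.0
        assert t.betweenness_raw == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            node_topology(nx.path_graph(3), "missing")


class TestSummaryAndInvariants:
    def test_single_edge(self):
        s = network_summary(nx.Graph([("a", "b")]))
        assert (s.diameter, s.characteristic_path_length, s.mean_neighbors) \
            == (1, 1.0, 1.0)

    def test_path_graph_cpl(self):
        # 6 pairs at distances 1,1,1,2,2,3 -> mean 5/3
        s = network_summary(nx.path_graph(4))
        assert s.characteristic_path_length == pytest.approx(5 / 3)

    def test_handshake_identity(self):
        for seed in range(10):
            G = simulate_network(12, "erdos_renyi", 0.3, seed=seed)
            assert sum(d for _, d in G.degree()) == 2 * G.number_of_edges()

    def test_metrics_invariant_under_relabeling(self):
        G = simulate_network(8, "erdos_renyi", 0.4, seed=1)
        mapping = {n: f"g{n}" for n in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        tg, th = all_node_topologies(G), all_node_topologies(H)
        for n in G.nodes:
            assert tg[n].degree == th[mapping[n]].degree
            assert tg[n].betweenness_raw == pytest.approx(
                th[mapping[n]].betweenness_raw)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_summary(nx.Graph())
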