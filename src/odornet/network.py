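"""Topology metrics over simple undirected gene-interaction graphs.

The graph container is a networkx ``Graph``; metrics follow the Cytoscape
NetworkAnalyzer conventions for undirected networks. Betweenness and stress
are computed from explicit all-pairs shortest-path counts (sigma_st), i.e.
directly from their defining sums over unordered source-target pairs, which
keeps them transparently checkable against brute-force path enumeration.
Distance-based metrics are computed within connected components.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx


def as_network(edges, nodes=()) -> nx.Graph:
    """Build a simple undirected graph, rejecting self-loops."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        G.add_edge(a, b)
    return G


def _bfs_counts(G: nx.Graph, source):
    """Distances and numbers of distinct shortest paths from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in G[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def all_pairs_shortest_paths(G: nx.Graph):
    """(distance, sigma) for all ordered node pairs.

    distance[s][t] is math.inf and sigma[s][t] is 0 for disconnected pairs.
    """
    nodes = list(G.nodes)
    distance = {}
    sigma = {}
    for s in nodes:
        d, sg = _bfs_counts(G, s)
        distance[s] = {t: d.get(t, math.inf) for t in nodes}
        sigma[s] = {t: sg.get(t, 0) for t in nodes}
    return distance, sigma


def clustering_coefficient(G: nx.Graph, n) -> float:
    """C_n = 2 e_n / (k_n (k_n - 1)): the fraction of connected neighbor
    pairs; 0 when the node has fewer than two neighbors."""
    if n not in G:
        raise KeyError(f"unknown node {n!r}")
    neighbors = list(G[n])
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(1 for i in range(k) for j in range(i + 1, k)
            if G.has_edge(neighbors[i], neighbors[j]))
    return 2.0 * e / (k * (k - 1))


def _pair_dependency(G, n, distance=None, sigma=None):
    """Yield sigma_st(n)/sigma_st and sigma_st(n) over unordered pairs
    {s, t} with s != n != t."""
    if distance is None or sigma is None:
        distance, sigma = all_pairs_shortest_paths(G)
    nodes = [v for v in G.nodes if v != n]
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            st = sigma[s][t]
            if st == 0:
                continue
            if distance[s][n] + distance[n][t] == distance[s][t]:
                on_n = sigma[s][n] * sigma[n][t]
            else:
                on_n = 0
            yield on_n / st, on_n


def betweenness(G: nx.Graph, n, normalized: bool = False,
                _cache=None) -> float:
    """C_b(n) = sum over unordered pairs {s,t} (s != n != t) of
    sigma_st(n)/sigma_st; normalized divides by (N-1)(N-2)/2."""
    if n not in G:
        raise KeyError(f"unknown node {n!r}")
    distance, sigma = _cache if _cache else all_pairs_shortest_paths(G)
    total = sum(frac for frac, _ in _pair_dependency(G, n, distance, sigma))
    if normalized:
        N = G.number_of_nodes()
        denom = (N - 1) * (N - 2) / 2
        return total / denom if denom > 0 else 0.0
    return total


def stress(G: nx.Graph, n, _cache=None) -> int:
    """Number of shortest paths (over unordered pairs) passing through n."""
    if n not in G:
        raise KeyError(f"unknown node {n!r}")
    distance, sigma = _cache if _cache else all_pairs_shortest_paths(G)
    return int(sum(on_n for _, on_n in _pair_dependency(G, n, distance, sigma)))


@dataclass(frozen=True)
class NodeTopology:
    node: object
    degree: int
    clustering: float
    betweenness_raw: float
    betweenness_norm: float
    closeness: float            # NaN for isolated nodes
    eccentricity: int
    radiality: float            # NaN when the component is a single node
    stress: int
    neighborhood_connectivity: float
    topological_coefficient: float
    avg_shortest_path: float    # mean distance to reachable nodes


def node_topology(G: nx.Graph, n, _cache=None) -> NodeTopology:
    if n not in G:
        raise KeyError(f"unknown node {n!r}")
    cache = _cache if _cache else all_pairs_shortest_paths(G)
    distance, _ = cache
    reach = {t: d for t, d in distance[n].items() if t != n and math.isfinite(d)}
    if reach:
        mean_dist = sum(reach.values()) / len(reach)
        ecc = max(reach.values())
        closeness = 1.0 / mean_dist
        component_diameter = max(
            d for s in reach for t, d in distance[s].items() if math.isfinite(d))
        component_diameter = max(component_diameter, ecc)
        radiality = (component_diameter + 1 - mean_dist) / component_diameter
    else:
        mean_dist = 0.0
        ecc = 0
        closeness = math.nan
        radiality = math.nan

    neighbors = list(G[n])
    k = len(neighbors)
    nbr_conn = sum(G.degree(v) for v in neighbors) / k if k else 0.0

    # topological coefficient: mean over nodes m sharing >= 1 neighbor with n
    # of (shared neighbors + adjacency indicator) / k_n
    tc = 0.0
    if k:
        nbr_set = set(neighbors)
        shares = []
        for m in G.nodes:
            if m == n:
                continue
            shared = len(nbr_set & set(G[m]))
            if shared == 0:
                continue
            shares.append((shared + (1 if G.has_edge(n, m) else 0)) / k)
        if shares:
            tc = sum(shares) / len(shares)

    return NodeTopology(
        node=n, degree=k,
        clustering=clustering_coefficient(G, n),
        betweenness_raw=betweenness(G, n, normalized=False, _cache=cache),
        betweenness_norm=betweenness(G, n, normalized=True, _cache=cache),
        closeness=closeness, eccentricity=ecc, radiality=radiality,
        stress=stress(G, n, _cache=cache),
        neighborhood_connectivity=nbr_conn,
        topological_coefficient=tc,
        avg_shortest_path=mean_dist)


def all_node_topologies(G: nx.Graph) -> dict:
    cache = all_pairs_shortest_paths(G)
    return {n: node_topology(G, n, _cache=cache) for n in G.nodes}


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    diameter: int
    characteristic_path_length: float
    mean_neighbors: float
    n_components: int


def network_summary(G: nx.Graph) -> NetworkSummary:
    """Diameter (max finite distance), characteristic path length (mean over
    connected unordered pairs) and mean number of neighbors."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    distance, _ = all_pairs_shortest_paths(G)
    nodes = list(G.nodes)
    dists = [distance[s][t] for i, s in enumerate(nodes)
             for t in nodes[i + 1:] if math.isfinite(distance[s][t])]
    diameter = int(max(dists)) if dists else 0
    cpl = float(sum(dists) / len(dists)) if dists else 0.0
    return NetworkSummary(
        n_nodes=G.number_of_nodes(), n_edges=G.number_of_edges(),
        diameter=diameter, characteristic_path_length=cpl,
        mean_neighbors=2.0 * G.number_of_edges() / G.number_of_nodes(),
        n_components=nx.number_connected_components(G))
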