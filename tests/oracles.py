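"""Independent brute-force oracles for the graph analytics.

These deliberately avoid the algorithms used by the implementation:
distances and shortest-path counts come from a Floyd-Warshall dynamic
programme (vs Brandes/Dijkstra in the package), betweenness additionally
from exhaustive simple-path enumeration on tiny graphs, clustering from
triple enumeration, and PageRank from a dense linear solve.
"""

import itertools
import math

import networkx as nx
import numpy as np


def floyd_warshall(graph, length):
    """All-pairs (distance, shortest-path-count) via Floyd-Warshall DP."""
    nodes = sorted(graph)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = [[math.inf] * n for _ in range(n)]
    sigma = [[0] * n for _ in range(n)]
    for i in range(n):
        dist[i][i], sigma[i][i] = 0.0, 1
    for u, v, data in graph.edges(data=True):
        i, j = idx[u], idx[v]
        dist[i][j] = dist[j][i] = length(data)
        sigma[i][j] = sigma[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j] - 1e-12:
                    dist[i][j] = alt
                    sigma[i][j] = sigma[i][k] * sigma[k][j]
                elif abs(alt - dist[i][j]) <= 1e-12 and k not in (i, j) \
                        and math.isfinite(alt):
                    sigma[i][j] += sigma[i][k] * sigma[k][j]
    return nodes, dist, sigma


def betweenness_fw(graph):
    """Unnormalised betweenness from the Floyd-Warshall path counts."""
    nodes, dist, sigma = floyd_warshall(graph, lambda d: 1.0)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if sigma[s][t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(dist[s][v] + dist[v][t] - dist[s][t]) <= 1e-12:
                    out[nodes[v]] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return out


def betweenness_enumeration(graph):
    """Betweenness by enumerating every simple path (tiny graphs only)."""
    out = {v: 0.0 for v in graph}
    nodes = sorted(graph)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(graph, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for v in p[1:-1]:
                out[v] += 1.0 / len(geodesics)
    return out


def closeness_fw(graph):
    nodes, dist, _ = floyd_warshall(graph, lambda d: 1.0)
    out = {}
    for i, v in enumerate(nodes):
        reachable = [dist[i][j] for j in range(len(nodes))
                     if j != i and math.isfinite(dist[i][j])]
        out[v] = len(reachable) / sum(reachable) if reachable else 0.0
    return out


def clustering_triples(graph):
    """Coefficient and triangle count by enumerating neighbour pairs."""
    coeff, tri = {}, {}
    for v in graph:
        nbrs = sorted(graph.neighbors(v))
        t = sum(1 for a, b in itertools.combinations(nbrs, 2)
                if graph.has_edge(a, b))
        tri[v] = float(t)
        d = len(nbrs)
        coeff[v] = 2.0 * t / (d * (d - 1)) if d >= 2 else 0.0
    return coeff, tri


def degree_recount(graph):
    counts = {}
    for v in graph:
        d = sum(1 for _ in graph.neighbors(v))
        counts[d] = counts.get(d, 0) + 1
    return counts


def pagerank_dense(graph, damping=0.85):
    """Dense linear solve; graphs must have no edgeless vertices."""
    nodes = sorted(graph)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    p = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1))
        p[idx[u], idx[v]] = w
        p[idx[v], idx[u]] = w
    p /= p.sum(axis=1, keepdims=True)
    x = np.linalg.solve(np.eye(n) - damping * p.T,
                        np.full(n, (1 - damping) / n))
    return dict(zip(nodes, x / x.sum()))


def path_lengths_fw(graph, mode):
    def length(data):
        if mode == "hops":
            return 1.0
        return -math.log2(float(data.get("probability", 1.0)))

    nodes, dist, _ = floyd_warshall(graph, length)
    idx = {v: i for i, v in enumerate(nodes)}
    return lambda a, b: dist[idx[a]][idx[b]]


def with_edge_attrs(graph):
    """Deterministic weights/probabilities for attribute-free test graphs."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v in graph.edges():
        a, b = sorted((hash_label(u), hash_label(v)))
        g.add_edge(u, v,
                   weight=(a * 3 + b * 7) % 5 + 1,
                   probability=(0.2, 0.45, 0.7, 0.95, 1.0)[(a + 2 * b) % 5])
    return g


def hash_label(v):
    return v if isinstance(v, int) else sum(ord(c) for c in str(v))
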