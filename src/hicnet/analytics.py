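"""Graph algorithms over a single experiment subgraph.

Five algorithm families are provided: community detection (weighted Louvain),
per-gene neighbour similarity (Jaccard across experiments), centralities
(PageRank, betweenness, closeness, local clustering), path finding (hop- or
probability-weighted shortest paths) and degree statistics.

Conventions (each available behind a flag where the field knows more than
one):

* modularity uses edge weights (read counts) by default;
* betweenness is the unnormalised Brandes count, endpoints excluded, each
  unordered pair counted once;
* closeness is component-restricted, ``c(v) = (n_v - 1) / sum d(v, u)`` over
  v's component (harmonic closeness behind ``harmonic=True``);
* PageRank is plain power iteration on the undirected graph with every edge
  acting as two arcs; vertices without edges receive teleport mass only;
* probability-mode paths minimise ``-log2(p)`` edge lengths, i.e. maximise
  the product of edge probabilities; path length is reported in bits;
* all tie-breaks are deterministic, lexicographic on gene symbols.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConvergenceError, UnknownGeneError, ValidationError

METRIC_TAGS = ("degree", "pagerank", "betweenness", "closeness",
               "clustering_coefficient", "triangles")


class CentralityMap(dict):
    """gene -> value mapping that remembers which metric produced it."""

    def __init__(self, metric: str, values=()):
        super().__init__(values)
        self.metric = metric

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"gene,{self.metric}\n")
            for gene in sorted(self):
                fh.write(f"{gene},{self[gene]!r}\n")


@dataclass
class Partition:
    """Community assignment plus the modularity of that assignment."""

    membership: dict[str, int]
    modularity: float

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.membership.items():
            out.setdefault(cid, set()).add(gene)
        return [out[c] for c in sorted(out)]

    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.communities()), reverse=True)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("gene,community\n")
            for gene in sorted(self.membership):
                fh.write(f"{gene},{self.membership[gene]}\n")


@dataclass
class PathResult:
    """A shortest path: vertices in order, total length, and the mode used."""

    genes: tuple[str, ...]
    length: float
    mode: str
    reachable: bool = True


# ------------------------------------------------------------------- degree

def degree_distribution(subgraph: nx.Graph) -> dict[int, int]:
    """Histogram degree -> number of genes with that degree."""
    return dict(sorted(Counter(d for _, d in subgraph.degree()).items()))


# -------------------------------------------------------------- clustering

def clustering_attitude(subgraph: nx.Graph
                        ) -> tuple[CentralityMap, CentralityMap]:
    """Local clustering coefficient and triangle participation per gene.

    ``coefficient(v) = 2 T(v) / (deg(v) (deg(v)-1))``, defined as 0 when
    ``deg(v) < 2``.  Returns (coefficients, triangle_counts).
    """
    coeff = CentralityMap("clustering_coefficient",
                          {v: float(c) for v, c in nx.clustering(subgraph).items()})
    tri = CentralityMap("triangles",
                        {v: float(t) for v, t in nx.triangles(subgraph).items()})
    return coeff, tri


# ----------------------------------------------------------------- Louvain

def modularity(subgraph: nx.Graph, membership: dict[str, int],
               resolution: float = 1.0, weighted: bool = True) -> float:
    """Direct evaluation of weighted Newman modularity for a partition.

    Q = sum_c [ W_in(c)/m - resolution * (S(c) / 2m)^2 ] with W_in the total
    weight inside community c, S(c) the summed weighted degree of its
    vertices and m the total edge weight.
    """
    def w(d):
        return d.get("weight", 1) if weighted else 1

    m = sum(w(d) for _, _, d in subgraph.edges(data=True))
    if m == 0:
        raise ValidationError("modularity undefined on an edgeless graph")
    strength: dict[str, float] = {v: 0.0 for v in subgraph}
    w_in: dict[int, float] = {}
    for u, v, d in subgraph.edges(data=True):
        wt = w(d)
        strength[u] += wt
        strength[v] += wt
        if membership[u] == membership[v]:
            w_in[membership[u]] = w_in.get(membership[u], 0.0) + wt
    s_tot: dict[int, float] = {}
    for v, s in strength.items():
        c = membership[v]
        s_tot[c] = s_tot.get(c, 0.0) + s
    return sum(w_in.get(c, 0.0) / m - resolution * (s_tot[c] / (2.0 * m)) ** 2
               for c in s_tot)


def louvain(subgraph: nx.Graph, seed: int, resolution: float = 1.0,
            weighted: bool = True) -> Partition:
    """Two-phase greedy modularity maximisation (Louvain).

    Deterministic under a fixed seed (the seed shuffles the vertex sweep
    order).  The reported modularity is the direct formula evaluated on the
    returned membership, so it is exactly reproducible from the partition.
    """
    if subgraph.number_of_edges() == 0:
        raise ValidationError("Louvain requires a graph with at least one edge")
    weight = "weight" if weighted else None
    communities = nx.community.louvain_communities(
        subgraph, weight=weight, resolution=resolution, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    membership = {v: cid for cid, comm in enumerate(communities) for v in comm}
    q = modularity(subgraph, membership, resolution=resolution, weighted=weighted)
    return Partition(membership, q)


# ---------------------------------------------------------------- PageRank

def pagerank(subgraph: nx.Graph, damping: float = 0.85, tol: float = 1e-9,
             max_iter: int = 200) -> CentralityMap:
    """Power-iteration PageRank on the undirected graph.

    Each edge acts as two opposite arcs; a vertex distributes its rank to
    neighbours proportionally to edge weight.  Vertices with no edges pass
    nothing on and receive teleport mass only.  Iteration stops when the L1
    distance between successive iterates drops below ``tol``; the returned
    values sum to one.
    """
    nodes = sorted(subgraph)
    n = len(nodes)
    if n == 0:
        raise ValidationError("PageRank requires at least one vertex")
    index = {v: i for i, v in enumerate(nodes)}
    out_strength = np.zeros(n)
    arcs: list[tuple[int, int, float]] = []
    for u, v, d in subgraph.edges(data=True):
        wt = float(d.get("weight", 1))
        iu, iv = index[u], index[v]
        arcs.append((iu, iv, wt))
        arcs.append((iv, iu, wt))
        out_strength[iu] += wt
        out_strength[iv] += wt
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for iteration in range(1, max_iter + 1):
        new = np.full(n, teleport)
        for iu, iv, wt in arcs:
            new[iv] += damping * x[iu] * wt / out_strength[iu]
        new /= new.sum()  # mass dropped by edgeless vertices is renormalised
        delta = float(np.abs(new - x).sum())
        x = new
        if delta < tol:
            return CentralityMap("pagerank", zip(nodes, map(float, x)))
    raise ConvergenceError("PageRank power iteration did not converge",
                           n_iter=max_iter)


# ------------------------------------------------------------- betweenness

def betweenness(subgraph: nx.Graph, weighted: bool = False,
                normalized: bool = False) -> CentralityMap:
    """Brandes betweenness; unnormalised pair counts, endpoints excluded.

    ``weighted=True`` uses 1/weight as edge distance (heavier contacts are
    spatially closer).
    """
    g = subgraph
    weight = None
    if weighted:
        g = subgraph.copy()
        for u, v, d in g.edges(data=True):
            d["_distance"] = 1.0 / float(d.get("weight", 1))
        weight = "_distance"
    values = nx.betweenness_centrality(g, normalized=normalized, weight=weight)
    return CentralityMap("betweenness", {v: float(c) for v, c in values.items()})


def closeness(subgraph: nx.Graph, harmonic: bool = False) -> CentralityMap:
    """Component-restricted closeness: (n_comp - 1) / sum of distances.

    Isolated vertices score 0.  ``harmonic=True`` returns the harmonic
    variant (sum of reciprocal distances) instead.
    """
    if harmonic:
        values = nx.harmonic_centrality(subgraph)
    else:
        values = nx.closeness_centrality(subgraph, wf_improved=False)
    return CentralityMap("closeness", {v: float(c) for v, c in values.items()})


# ------------------------------------------------------------ path finding

def _edge_length(data: dict, mode: str) -> float:
    if mode == "hops":
        return 1.0
    if mode == "probability":
        p = float(data.get("probability", 1.0))
        return -math.log2(p)
    raise ValidationError(f"unknown path mode {mode!r}; use 'hops' or 'probability'")


def _dijkstra(subgraph: nx.Graph, source: str, mode: str
              ) -> tuple[dict[str, float], dict[str, tuple[str, ...]]]:
    """Single-source shortest paths with lexicographic path tie-breaking."""
    dist: dict[str, float] = {source: 0.0}
    best: dict[str, tuple[str, ...]] = {source: (source,)}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    eps = 1e-12
    while heap:
        d, path = heapq.heappop(heap)
        v = path[-1]
        if d > dist.get(v, math.inf) + eps or path != best[v]:
            continue
        for u in subgraph.neighbors(v):
            nd = d + _edge_length(subgraph[v][u], mode)
            cand = path + (u,)
            old = dist.get(u, math.inf)
            if nd < old - eps or (abs(nd - old) <= eps and cand < best[u]):
                dist[u] = nd
                best[u] = cand
                heapq.heappush(heap, (nd, cand))
    return dist, best


def shortest_path(subgraph: nx.Graph, gene_a: str, gene_b: str,
                  mode: str = "hops") -> PathResult:
    """Shortest path between two genes.

    ``mode='hops'`` counts edges; ``mode='probability'`` minimises the sum
    of ``-log2(probability)`` edge lengths, i.e. returns the most probable
    path, with the length reported in bits.  An unreachable pair yields an
    explicit unreachable result, not an error.
    """
    for g in (gene_a, gene_b):
        if g not in subgraph:
            raise UnknownGeneError(g)
    dist, best = _dijkstra(subgraph, gene_a, mode)
    if gene_b not in dist:
        return PathResult((), math.inf, mode, reachable=False)
    return PathResult(best[gene_b], dist[gene_b], mode)


def all_shortest_from(subgraph: nx.Graph, gene: str, mode: str = "hops"
                      ) -> dict[str, float]:
    """Shortest-path lengths from one gene to every reachable other gene."""
    if gene not in subgraph:
        raise UnknownGeneError(gene)
    dist, _ = _dijkstra(subgraph, gene, mode)
    return {v: d for v, d in sorted(dist.items()) if v != gene}


# ------------------------------------------------------- per-gene Jaccard

def gene_neighbor_jaccard(store, gene: str, exp_a: str, exp_b: str,
                          min_weight: float = 0) -> float:
    """Jaccard similarity of one gene's neighbour sets in two experiments.

    Both-empty neighbour sets score 1.0: identical absence of contacts is
    treated as perfect agreement.
    """
    na = store.neighbors(gene, [exp_a], min_weight)
    nb = store.neighbors(gene, [exp_b], min_weight)
    union = na | nb
    if not union:
        return 1.0
    return len(na & nb) / len(union)


# ----------------------------------------------------------- metric driver

def compute_metric(subgraph: nx.Graph, metric: str,
                   seed: int | None = None) -> CentralityMap:
    """Compute one of the named per-gene metrics (`METRIC_TAGS`)."""
    if metric == "degree":
        return CentralityMap("degree", {v: float(d) for v, d in subgraph.degree()})
    if metric == "pagerank":
        return pagerank(subgraph)
    if metric == "betweenness":
        return betweenness(subgraph)
    if metric == "closeness":
        return closeness(subgraph)
    if metric == "clustering_coefficient":
        return clustering_attitude(subgraph)[0]
    if metric == "triangles":
        return clustering_attitude(subgraph)[1]
    raise ValidationError(
        f"unknown metric {metric!r}; expected one of {', '.join(METRIC_TAGS)}")
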