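"""Per-experiment graph analytics against independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from hicnet import analytics
from hicnet.errors import ConvergenceError, UnknownGeneError, ValidationError

import oracles


def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


def two_triangles():
    g = triangle()
    g.add_edges_from([("D", "E"), ("E", "F"), ("D", "F")])
    return g


class TestDegreeDistribution:
    def test_triangle(self):
        assert analytics.degree_distribution(triangle()) == {2: 3}

    def test_empty(self):
        assert analytics.degree_distribution(nx.Graph()) == {}

    def test_random_graph_matches_recount_and_handshake(self):
        g = nx.gnp_random_graph(200, 0.05, seed=1)
        dist = analytics.degree_distribution(g)
        assert dist == oracles.degree_recount(g)
        assert sum(dist.values()) == g.number_of_nodes()
        assert sum(d * c for d, c in dist.items()) == 2 * g.number_of_edges()


class TestClusteringAttitude:
    def test_triangle_all_ones(self):
        coeff, tri = analytics.clustering_attitude(triangle())
        assert all(c == 1.0 for c in coeff.values())
        assert all(t == 1.0 for t in tri.values())

    def test_star_center_zero(self):
        coeff, _ = analytics.clustering_attitude(nx.star_graph(4))
        assert coeff[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graph_matches_triple_enumeration(self, seed):
        g = nx.gnp_random_graph(25, 0.2, seed=seed)
        coeff, tri = analytics.clustering_attitude(g)
        exp_coeff, exp_tri = oracles.clustering_triples(g)
        assert coeff == pytest.approx(exp_coeff)
        assert tri == exp_tri


class TestLouvain:
    def test_two_disjoint_triangles(self):
        part = analytics.louvain(two_triangles(), seed=1)
        assert part.sizes() == [3, 3]
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_single_community(self):
        part = analytics.louvain(nx.complete_graph(8), seed=1)
        assert part.sizes() == [8]

    def test_reported_modularity_is_direct_evaluation(self):
        g = oracles.with_edge_attrs(nx.gnp_random_graph(40, 0.1, seed=5))
        g.remove_nodes_from(list(nx.isolates(g)))
        part = analytics.louvain(g, seed=7)
        direct = analytics.modularity(g, part.membership)
        assert part.modularity == pytest.approx(direct, abs=1e-15)
        # cross-check our formula against the networkx evaluation
        nx_q = nx.community.modularity(
            g, part.communities(), weight="weight")
        assert part.modularity == pytest.approx(nx_q, abs=1e-12)

    def test_never_below_singleton_partition(self):
        g = oracles.with_edge_attrs(nx.gnp_random_graph(30, 0.15, seed=9))
        g.remove_nodes_from(list(nx.isolates(g)))
        part = analytics.louvain(g, seed=2)
        singles = {v: i for i, v in enumerate(g)}
        assert part.modularity >= analytics.modularity(g, singles) - 1e-12

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(60, 0.1, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        p1 = analytics.louvain(g, seed=42)
        p2 = analytics.louvain(g, seed=42)
        assert p1.membership == p2.membership

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            analytics.louvain(nx.Graph(), seed=1)


class TestPagerank:
    def test_cycle_is_uniform(self):
        pr = analytics.pagerank(nx.cycle_graph(7))
        assert all(v == pytest.approx(1 / 7, abs=1e-9) for v in pr.values())

    def test_star_matches_dense_linear_solve(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        pr = analytics.pagerank(g, tol=1e-12)
        expected = oracles.pagerank_dense(g)
        for v in g:
            assert pr[v] == pytest.approx(expected[v], abs=1e-9)

    def test_weighted_graph_matches_dense_solve(self):
        g = oracles.with_edge_attrs(nx.gnp_random_graph(15, 0.3, seed=2))
        g.remove_nodes_from(list(nx.isolates(g)))
        pr = analytics.pagerank(g, tol=1e-13)
        expected = oracles.pagerank_dense(g)
        for v in g:
            assert pr[v] == pytest.approx(expected[v], abs=1e-8)

    def test_sum_to_one_with_isolated_vertex(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        g.add_node("LONER")
        pr = analytics.pagerank(g)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-8)
        # edgeless vertex holds teleport-only (renormalised) mass: the
        # smallest share in the graph
        assert pr["LONER"] == min(pr.values())
        assert pr["LONER"] < 1 / 5

    def test_nonconvergence_reports_iterations(self):
        with pytest.raises(ConvergenceError, match="3"):
            analytics.pagerank(nx.path_graph(50), tol=1e-15, max_iter=3)


class TestBetweenness:
    def test_path_middle_vertex_bridges_one_pair(self):
        b = analytics.betweenness(nx.path_graph(["A", "B", "C"]))
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_complete_graph_all_zero(self):
        b = analytics.betweenness(nx.complete_graph(6))
        assert all(v == 0.0 for v in b.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_random_graphs_match_path_enumeration(self, seed):
        g = nx.gnp_random_graph(7, 0.4, seed=seed)
        b = analytics.betweenness(g)
        expected = oracles.betweenness_enumeration(g)
        assert b == pytest.approx(expected, abs=1e-9)


class TestCloseness:
    def test_path_hand_values(self):
        c = analytics.closeness(nx.path_graph(["A", "B", "C"]))
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(2 / 3)

    def test_complete_graph_all_one(self):
        c = analytics.closeness(nx.complete_graph(5))
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_disconnected_components_scored_separately(self):
        c = analytics.closeness(two_triangles())
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_isolated_vertex_zero(self):
        g = nx.path_graph(3)
        g.add_node("LONER")
        assert analytics.closeness(g)["LONER"] == 0.0

    def test_harmonic_variant_on_path(self):
        c = analytics.closeness(nx.path_graph(["A", "B", "C"]), harmonic=True)
        assert c["A"] == pytest.approx(1.5)


class TestShortestPath:
    def probability_graph(self):
        g = nx.Graph()
        g.add_edge("A", "C", weight=1, probability=0.2)
        g.add_edge("A", "B", weight=1, probability=0.5)
        g.add_edge("B", "C", weight=1, probability=0.5)
        return g

    def test_probability_mode_prefers_more_probable_two_hop(self):
        res = analytics.shortest_path(self.probability_graph(), "A", "C",
                                      mode="probability")
        assert res.genes == ("A", "B", "C")
        assert res.length == pytest.approx(2.0)  # bits; direct edge is 2.32

    def test_hops_mode_prefers_direct_edge(self):
        res = analytics.shortest_path(self.probability_graph(), "A", "C",
                                      mode="hops")
        assert res.genes == ("A", "C")
        assert res.length == 1.0

    def test_length_is_minus_log2_of_path_probability(self):
        res = analytics.shortest_path(self.probability_graph(), "A", "C",
                                      mode="probability")
        product = 0.5 * 0.5
        assert res.length == pytest.approx(-math.log2(product), abs=1e-12)

    def test_unreachable_pair_is_explicit_not_error(self):
        g = two_triangles()
        res = analytics.shortest_path(g, "A", "D")
        assert not res.reachable
        assert res.genes == ()
        assert math.isinf(res.length)

    def test_unknown_gene_raises(self):
        with pytest.raises(UnknownGeneError):
            analytics.shortest_path(triangle(), "A", "ZZ")

    def test_lexicographic_tie_break(self):
        g = nx.Graph()
        for mid in ("M", "K"):
            g.add_edge("A", mid)
            g.add_edge(mid, "Z")
        res = analytics.shortest_path(g, "A", "Z")
        assert res.genes == ("A", "K", "Z")

    def test_all_shortest_star_and_path(self):
        star = nx.star_graph(4)
        assert analytics.all_shortest_from(star, 0) == {i: 1.0 for i in range(1, 5)}
        path = nx.path_graph(5)
        assert analytics.all_shortest_from(path, 0) == \
            {i: float(i) for i in range(1, 5)}

    @pytest.mark.parametrize("mode", ["hops", "probability"])
    def test_all_shortest_matches_per_pair(self, mode):
        g = oracles.with_edge_attrs(nx.gnp_random_graph(12, 0.25, seed=4))
        src = sorted(g)[0]
        lengths = analytics.all_shortest_from(g, src, mode)
        for v in sorted(g):
            if v == src:
                continue
            res = analytics.shortest_path(g, src, v, mode)
            if res.reachable:
                assert lengths[v] == pytest.approx(res.length, abs=1e-12)
            else:
                assert v not in lengths


class TestGeneNeighborJaccard:
    def make_store(self):
        from hicnet.model import MultiExperimentGraph
        store = MultiExperimentGraph()
        for i, s in enumerate("ABCDE"):
            store.upsert_gene(s, "chr1", 100 * i, 100 * i + 50)
        for other in ("B", "C"):
            store.add_contact("exp_a", "A", other, 1, 0.5)
        for other in ("B", "D"):
            store.add_contact("exp_b", "A", other, 1, 0.5)
        return store

    def test_partial_overlap(self):
        store = self.make_store()
        assert analytics.gene_neighbor_jaccard(store, "A", "exp_a", "exp_b") \
            == pytest.approx(1 / 3)

    def test_same_experiment_is_one(self):
        store = self.make_store()
        assert analytics.gene_neighbor_jaccard(store, "A", "exp_a", "exp_a") == 1.0

    def test_both_empty_convention_is_one(self):
        store = self.make_store()
        assert analytics.gene_neighbor_jaccard(store, "E", "exp_a", "exp_b") == 1.0

    def test_unknown_gene(self):
        with pytest.raises(UnknownGeneError):
            analytics.gene_neighbor_jaccard(self.make_store(), "Z",
                                            "exp_a", "exp_b")


class TestMetricDriver:
    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError, match="unknown metric"):
            analytics.compute_metric(triangle(), "eigenvector")

    @pytest.mark.parametrize("metric", analytics.METRIC_TAGS)
    def test_all_tags_produce_finite_values(self, metric):
        cmap = analytics.compute_metric(two_triangles(), metric)
        assert set(cmap) == set("ABCDEF")
        assert all(np.isfinite(v) for v in cmap.values())
        assert cmap.metric == metric
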