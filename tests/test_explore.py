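"""Progressive exploration: sessions as the only state."""

import networkx as nx
import pytest

from hicnet import explore, synth
from hicnet.errors import UnknownExperimentError, UnknownGeneError, ValidationError

from conftest import store_from_records


@pytest.fixture
def chain_store():
    """Path A-B-C-D-E-F in exp1; extra edge B-X in exp2."""
    from hicnet.model import MultiExperimentGraph
    store = MultiExperimentGraph()
    symbols = list("ABCDEFX")
    for i, s in enumerate(symbols):
        store.upsert_gene(s, "chr1", 1000 * i, 1000 * i + 500)
    for a, b, w in [("A", "B", 1), ("B", "C", 2), ("C", "D", 3),
                    ("D", "E", 4), ("E", "F", 5)]:
        store.add_contact("exp1", a, b, w, 0.9)
    store.add_contact("exp2", "B", "X", 2, 0.5)
    store.add_contact("exp2", "A", "B", 7, 0.5)
    return store


class TestStart:
    def test_single_step_session(self, star_store):
        session = explore.start(star_store, "A", ["exp1"], 0)
        assert len(session) == 1
        assert session.steps[0].anchors == frozenset(["A"])

    def test_unknown_gene(self, star_store):
        with pytest.raises(UnknownGeneError):
            explore.start(star_store, "ZZZ", ["exp1"])

    def test_empty_experiment_selection(self, star_store):
        with pytest.raises(ValidationError):
            explore.start(star_store, "A", [])

    def test_unknown_experiment(self, star_store):
        with pytest.raises(UnknownExperimentError):
            explore.start(star_store, "A", ["nope"])


class TestResolve:
    def test_star_center_resolves_full_star(self, star_store):
        g = explore.resolve(explore.start(star_store, "A", ["exp1"]), star_store)
        assert set(g) == {"A", "B", "C", "D"}
        assert g.number_of_edges() == 3

    def test_stateless_and_deterministic(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        session = explore.expand(session, ["B"], chain_store)
        g1 = explore.resolve(session, chain_store)
        g2 = explore.resolve(session, chain_store)
        assert nx.utils.graphs_equal(g1, g2)
        assert list(g1.nodes) == list(g2.nodes)

    def test_require_all_experiments_intersects(self, chain_store):
        session = explore.start(chain_store, "B", ["exp1", "exp2"])
        union = explore.resolve(session, chain_store)
        assert set(union) == {"A", "B", "C", "X"}
        strict = explore.resolve(session, chain_store,
                                 require_all_experiments=True)
        # only A has a B-edge in each of exp1 and exp2
        assert set(strict) == {"A", "B"}

    def test_session_experiment_must_exist_in_store(self, star_store, chain_store):
        session = explore.start(chain_store, "B", ["exp2"])
        with pytest.raises(UnknownExperimentError):
            explore.resolve(session, star_store)


class TestExpandBack:
    def test_five_expansions_make_six_steps(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        for gene in "BCDEF":
            session = explore.expand(session, [gene], chain_store)
        assert len(session) == 6

    def test_expand_empty_set_is_identity(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        assert explore.expand(session, [], chain_store) is session

    def test_expand_hidden_gene_rejected(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        with pytest.raises(ValidationError, match="non-visible.*F"):
            explore.expand(session, ["F"], chain_store)

    def test_expand_does_not_mutate_original(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        explore.expand(session, ["B"], chain_store)
        assert len(session) == 1

    def test_back_undoes_expand_exactly(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        expanded = explore.expand(session, ["B"], chain_store)
        assert explore.step_back(expanded) == session
        assert nx.utils.graphs_equal(
            explore.resolve(explore.step_back(expanded), chain_store),
            explore.resolve(session, chain_store))

    def test_back_on_single_step_is_identity(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        assert explore.step_back(session) is session

    def test_monotone_growth(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        g0 = explore.resolve(session, chain_store)
        bigger = explore.expand(session, ["B"], chain_store)
        g1 = explore.resolve(bigger, chain_store)
        assert set(g0).issubset(set(g1))
        assert set(g0.edges).issubset(set(g1.edges))


class TestTruncate:
    def test_truncate_at_early_edge(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        for gene in "BCDE":
            session = explore.expand(session, [gene], chain_store)
        cut = explore.truncate_at_edge(session, "B", "C", chain_store)
        assert len(cut) == 2
        assert cut.steps == session.steps[:2]

    def test_truncate_at_last_edge_keeps_session(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        session = explore.expand(session, ["B"], chain_store)
        assert explore.truncate_at_edge(session, "C", "B", chain_store) == session

    def test_absent_edge_rejected(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        with pytest.raises(ValidationError, match="does not appear"):
            explore.truncate_at_edge(session, "E", "F", chain_store)


class TestThreshold:
    def test_monotone_in_threshold(self, star_store):
        base = explore.start(star_store, "A", ["exp1"], 0)
        low = explore.resolve(base, star_store)
        high = explore.resolve(explore.set_threshold(base, 2), star_store)
        assert set(high).issubset(set(low))
        assert set(high.edges).issubset(set(low.edges))

    def test_threshold_above_max_leaves_anchors(self, star_store):
        session = explore.set_threshold(
            explore.start(star_store, "A", ["exp1"]), 99)
        g = explore.resolve(session, star_store)
        assert set(g) == {"A"}
        assert g.number_of_edges() == 0

    def test_negative_threshold_rejected(self, star_store):
        session = explore.start(star_store, "A", ["exp1"])
        with pytest.raises(ValidationError):
            explore.set_threshold(session, -1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_monotonicity_on_synthetic_sessions(self, seed):
        records, _ = synth.generate_experiment(
            synth.SynthConfig(n_genes=40, n_chromosomes=2, seed=seed))
        store = store_from_records({"exp": records})
        anchor = sorted(store.genes)[0]
        session = explore.start(store, anchor, ["exp"], 0)
        prev_nodes, prev_edges = None, None
        for threshold in (0, 1, 2, 4, 8):
            g = explore.resolve(
                explore.set_threshold(session, threshold), store)
            if prev_nodes is not None:
                assert set(g).issubset(prev_nodes)
                assert set(g.edges).issubset(prev_edges)
            prev_nodes, prev_edges = set(g), set(g.edges)


class TestSerialisation:
    def test_render_counts_one_clause_per_step(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"])
        assert explore.render_pattern(session).count("MATCH") == 1
        for gene in "BCDEF":
            session = explore.expand(session, [gene], chain_store)
        assert explore.render_pattern(session).count("MATCH") == 6

    def test_render_distinguishes_sessions(self, chain_store):
        s1 = explore.start(chain_store, "A", ["exp1"], 0)
        s2 = explore.start(chain_store, "A", ["exp1"], 2)
        s3 = explore.start(chain_store, "B", ["exp1"], 0)
        texts = {explore.render_pattern(s) for s in (s1, s2, s3)}
        assert len(texts) == 3

    def test_json_round_trip(self, chain_store):
        session = explore.start(chain_store, "A", ["exp1"], 1)
        session = explore.expand(session, ["B"], chain_store)
        back = explore.session_from_json(explore.session_to_json(session))
        assert back == session
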