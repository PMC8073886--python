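"""Headless progressive gene-centric exploration.

A session is an immutable ordered list of expansion steps; each step names
its anchor genes, an experiment filter and a weight threshold.  The session
is the *only* state: resolving the same session against the same store is
deterministic, which makes navigation (expand, back, truncate) trivial to
implement as pure functions returning new sessions.

Resolving a session yields the display graph: per step, the anchors plus
their threshold-passing neighbours within the experiment filter, with the
qualifying anchor-neighbour edges, unioned across steps.  With
``require_all_experiments=True`` a neighbour is kept only if it has a
qualifying edge in *every* selected experiment (the stricter semantics of a
manually-sharpened query); the default unions across experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import UnknownExperimentError, ValidationError
from .io import relationship_type
from .model import MultiExperimentGraph


@dataclass(frozen=True)
class ExplorationStep:
    anchors: frozenset[str]
    experiments: frozenset[str]
    min_weight: float = 0.0

    def __post_init__(self):
        if not self.anchors:
            raise ValidationError("step must have at least one anchor gene")
        if not self.experiments:
            raise ValidationError("step must select at least one experiment")
        if self.min_weight < 0:
            raise ValidationError("min_weight must be >= 0")


@dataclass(frozen=True)
class ExplorationSession:
    steps: tuple[ExplorationStep, ...]

    def __len__(self) -> int:
        return len(self.steps)


# ------------------------------------------------------------- construction

def start(store: MultiExperimentGraph, gene: str,
          experiments: Iterable[str] | None = None,
          min_weight: float = 0.0) -> ExplorationSession:
    """Open a session anchored at one gene.

    ``experiments=None`` selects every experiment registered in the store.
    """
    store.gene(gene)  # raises UnknownGeneError
    names = frozenset(experiments) if experiments is not None \
        else frozenset(store.experiment_names)
    if not names:
        raise ValidationError("experiment selection must be non-empty")
    for name in names:
        if name not in store.experiment_names:
            raise UnknownExperimentError(name, store.experiment_names)
    step = ExplorationStep(frozenset([gene]), names, float(min_weight))
    return ExplorationSession((step,))


# ---------------------------------------------------------------- stepping

def _step_edges(store, step: ExplorationStep, require_all: bool,
                min_probability: float | None
                ) -> list[tuple[str, str, dict]]:
    """Qualifying (anchor, neighbour, attrs) edges of one step, sorted."""
    edges: dict[tuple[str, str], dict] = {}
    for anchor in sorted(step.anchors):
        per_exp: dict[str, dict[str, dict]] = {}
        for name in sorted(step.experiments):
            hits: dict[str, dict] = {}
            for c in store.contacts(name):
                if anchor not in c.pair:
                    continue
                if c.weight < step.min_weight:
                    continue
                if min_probability is not None and c.probability < min_probability:
                    continue
                other = c.gene_b if c.gene_a == anchor else c.gene_a
                hits[other] = {"weight": c.weight, "probability": c.probability,
                               "experiment": name}
            per_exp[name] = hits
        if require_all:
            keep = set.intersection(*(set(h) for h in per_exp.values()))
        else:
            keep = set().union(*(set(h) for h in per_exp.values()))
        for other in keep:
            key = tuple(sorted((anchor, other)))
            attrs = edges.setdefault(
                key, {"weight": 0, "probability": 0.0, "experiments": []})
            for name, hits in sorted(per_exp.items()):
                if other in hits:
                    h = hits[other]
                    attrs["weight"] += h["weight"]
                    attrs["probability"] = max(attrs["probability"],
                                               h["probability"])
                    if name not in attrs["experiments"]:
                        attrs["experiments"].append(name)
    return [(a, b, edges[(a, b)]) for a, b in sorted(edges)]


def resolve(session: ExplorationSession, store: MultiExperimentGraph,
            require_all_experiments: bool = False,
            min_probability: float | None = None) -> nx.Graph:
    """Materialise the display graph for a session against a store.

    Pure function of (session, store, flags); repeated calls produce
    identical graphs with deterministic node/edge insertion order.
    """
    for step in session.steps:
        for name in step.experiments:
            if name not in store.experiment_names:
                raise UnknownExperimentError(name, store.experiment_names)
    g = nx.Graph()
    for step in session.steps:
        for anchor in sorted(step.anchors):
            gene = store.gene(anchor)
            g.add_node(anchor, chromosome=gene.chromosome,
                       start=gene.start, end=gene.end)
        for a, b, attrs in _step_edges(store, step, require_all_experiments,
                                       min_probability):
            for s in (a, b):
                if s not in g:
                    gene = store.gene(s)
                    g.add_node(s, chromosome=gene.chromosome,
                               start=gene.start, end=gene.end)
            if g.has_edge(a, b):
                old = g[a][b]
                old["weight"] = max(old["weight"], attrs["weight"])
                old["probability"] = max(old["probability"], attrs["probability"])
                merged = sorted(set(old["experiments"].split(";"))
                                | set(attrs["experiments"]))
                old["experiments"] = ";".join(merged)
            else:
                g.add_edge(a, b, weight=attrs["weight"],
                           probability=attrs["probability"],
                           experiments=";".join(sorted(attrs["experiments"])))
    return g


def visible_genes(session: ExplorationSession, store: MultiExperimentGraph,
                  **flags) -> set[str]:
    return set(resolve(session, store, **flags))


def expand(session: ExplorationSession, genes_to_expand: Iterable[str],
           store: MultiExperimentGraph, min_weight: float | None = None,
           **flags) -> ExplorationSession:
    """Append an expansion step anchored at currently-visible genes.

    Expanding an empty selection returns the session unchanged.  The new
    step inherits the experiment filter and (unless overridden) the
    threshold of the latest step.  The input session is never mutated.
    """
    anchors = frozenset(genes_to_expand)
    if not anchors:
        return session
    vis = visible_genes(session, store, **flags)
    hidden = anchors - vis
    if hidden:
        raise ValidationError(
            f"cannot expand non-visible gene(s): {', '.join(sorted(hidden))}")
    last = session.steps[-1]
    step = ExplorationStep(
        anchors, last.experiments,
        last.min_weight if min_weight is None else float(min_weight))
    return ExplorationSession(session.steps + (step,))


def step_back(session: ExplorationSession) -> ExplorationSession:
    """Drop the latest step; a 1-step session steps back to itself."""
    if len(session.steps) <= 1:
        return session
    return ExplorationSession(session.steps[:-1])


def truncate_at_edge(session: ExplorationSession, gene_a: str, gene_b: str,
                     store: MultiExperimentGraph, **flags
                     ) -> ExplorationSession:
    """Rewind to the earliest step whose resolution introduces this edge."""
    key = tuple(sorted((gene_a, gene_b)))
    for k, step in enumerate(session.steps, start=1):
        require_all = flags.get("require_all_experiments", False)
        min_p = flags.get("min_probability")
        for a, b, _ in _step_edges(store, step, require_all, min_p):
            if (a, b) == key:
                return ExplorationSession(session.steps[:k])
    raise ValidationError(
        f"edge ({gene_a}, {gene_b}) does not appear on the session's path")


def set_threshold(session: ExplorationSession, min_weight: float,
                  all_steps: bool = False) -> ExplorationSession:
    """Change the weight threshold of the latest step (or of every step)."""
    if min_weight < 0:
        raise ValidationError("min_weight must be >= 0")

    def reth(step):
        return ExplorationStep(step.anchors, step.experiments, float(min_weight))

    if all_steps:
        return ExplorationSession(tuple(reth(s) for s in session.steps))
    return ExplorationSession(session.steps[:-1] + (reth(session.steps[-1]),))


# ------------------------------------------------------------ serialisation

def render_pattern(session: ExplorationSession) -> str:
    """Serialise the session as a Cypher-dialect pattern (one per step).

    Documentation-grade provenance text, not meant for execution; the
    rendering is injective on sessions up to anchor ordering.
    """
    clauses = []
    for i, step in enumerate(session.steps):
        anchors = ", ".join(f"'{a}'" for a in sorted(step.anchors))
        types = "|".join(relationship_type(e) for e in sorted(step.experiments))
        clauses.append(
            f"MATCH (n{i}:Gene)-[r{i}:{types}]-(n{i + 1}:Gene) "
            f"WHERE n{i}.symbol IN [{anchors}] AND r{i}.weight >= {step.min_weight:g}"
        )
    return "\n".join(clauses)


def session_to_json(session: ExplorationSession) -> str:
    doc = {"steps": [
        {"anchors": sorted(s.anchors), "experiments": sorted(s.experiments),
         "min_weight": s.min_weight}
        for s in session.steps]}
    return json.dumps(doc, indent=2)


def session_from_json(text: str) -> ExplorationSession:
    doc = json.loads(text)
    steps = tuple(
        ExplorationStep(frozenset(s["anchors"]), frozenset(s["experiments"]),
                        float(s.get("min_weight", 0.0)))
        for s in doc["steps"])
    if not steps:
        raise ValidationError("session document has no steps")
    return ExplorationSession(steps)
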