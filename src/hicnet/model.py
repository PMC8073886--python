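"""In-memory multi-experiment property graph of genes and Hi-C contacts.

The store keeps each gene exactly once (the symbol is the identity key) and
partitions contact edges by experiment label, so several Hi-C runs over the
same gene universe share their node set.  Contacts are undirected: the read
pairs that support a contact carry no meaningful orientation for a
gene-proximity graph, so any direction present in the input is dropped.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.

Duplicate contacts (same unordered gene pair, same experiment) aggregate by
summing their read-count weights — read support is additive evidence — and
keeping the maximum probability.  Self-contacts are rejected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CoordinateConflictError,
    UnknownExperimentError,
    UnknownGeneError,
    ValidationError,
)

Scalar = str | int | float

_STORE_FILES = ("genes.tsv", "experiments.tsv", "edges.tsv")


@dataclass(frozen=True)
class Gene:
    """A gene node: symbol plus genomic interval (0-based half-open)."""

    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        if self.start < 0:
            raise ValidationError(f"gene {self.symbol!r}: start must be >= 0")
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.symbol!r}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


@dataclass(frozen=True)
class Experiment:
    """Experiment summary: name plus counts recomputable from the store."""

    name: str
    n_genes: int
    n_edges: int


@dataclass
class Contact:
    """An undirected contact between two genes within one experiment.

    ``weight`` is the supporting read count (positive integer) and
    ``probability`` the edge score in (0, 1]; additional columns from the
    input travel in the open ``properties`` mapping.
    """

    gene_a: str
    gene_b: str
    experiment: str
    weight: int
    probability: float
    properties: dict[str, Scalar] = field(default_factory=dict)

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-contact rejected: {self.gene_a!r}")
        if self.gene_a > self.gene_b:  # normalise the unordered pair
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        _check_weight_probability(self.weight, self.probability)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _check_weight_probability(weight, probability):
    if not isinstance(weight, (int,)) or isinstance(weight, bool):
        raise ValidationError(f"weight must be an integer, got {weight!r}")
    if weight < 1:
        raise ValidationError(f"weight must be >= 1, got {weight}")
    if not (0.0 < probability <= 1.0):
        raise ValidationError(
            f"probability must be in (0, 1], got {probability}"
        )


class MultiExperimentGraph:
    """Genes shared across experiments; contact edges partitioned by label.

    Parameters
    ----------
    strict : bool
        When True, :meth:`add_contact` refuses unknown experiment names;
        by default unknown experiments auto-register on first insertion,
        which is convenient during ingest.
    """

    def __init__(self, strict: bool = False):
        self.strict = strict
        self._genes: dict[str, Gene] = {}
        # experiment -> unordered pair -> Contact
        self._edges: dict[str, dict[tuple[str, str], Contact]] = {}

    # ------------------------------------------------------------------ genes

    @property
    def genes(self) -> dict[str, Gene]:
        return dict(self._genes)

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    def gene(self, symbol: str) -> Gene:
        try:
            return self._genes[symbol]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def upsert_gene(self, symbol: str, chromosome: str, start: int, end: int) -> Gene:
        """Insert a gene or return the existing node for ``symbol``.

        The symbol is the unique key: re-inserting it with the same interval
        returns the original node object; a different interval is a hard
        error rather than a silent merge.
        """
        new = Gene(symbol, chromosome, int(start), int(end))
        existing = self._genes.get(symbol)
        if existing is not None:
            if existing.interval != new.interval:
                raise CoordinateConflictError(symbol, existing.interval, new.interval)
            return existing
        self._genes[symbol] = new
        return new

    # ------------------------------------------------------------ experiments

    def register_experiment(self, name: str) -> None:
        if not name:
            raise ValidationError("experiment name must be non-empty")
        self._edges.setdefault(name, {})

    @property
    def experiment_names(self) -> list[str]:
        return sorted(self._edges)

    def experiment(self, name: str) -> Experiment:
        edges = self._require_experiment(name)
        incident = {g for pair in edges for g in pair}
        return Experiment(name, n_genes=len(incident), n_edges=len(edges))

    @property
    def experiments(self) -> list[Experiment]:
        return [self.experiment(n) for n in self.experiment_names]

    def _require_experiment(self, name: str) -> dict[tuple[str, str], Contact]:
        try:
            return self._edges[name]
        except KeyError:
            raise UnknownExperimentError(name, self._edges) from None

    # ---------------------------------------------------------------- contacts

    def add_contact(
        self,
        experiment: str,
        symbol_a: str,
        symbol_b: str,
        weight: int,
        probability: float,
        properties: Mapping[str, Scalar] | None = None,
    ) -> Contact:
        """Add (or aggregate into) the contact between two registered genes.

        If the unordered pair already holds a contact in this experiment the
        weights are summed, the probability is replaced by the maximum of the
        two, and new properties are merged over the old ones.
        """
        for s in (symbol_a, symbol_b):
            if s not in self._genes:
                raise UnknownGeneError(s)
        if experiment not in self._edges:
            if self.strict:
                raise UnknownExperimentError(experiment, self._edges)
            self.register_experiment(experiment)
        contact = Contact(
            symbol_a, symbol_b, experiment, int(weight), float(probability),
            dict(properties or {}),
        )
        edges = self._edges[experiment]
        existing = edges.get(contact.pair)
        if existing is None:
            edges[contact.pair] = contact
            return contact
        existing.weight += contact.weight
        existing.probability = max(existing.probability, contact.probability)
        existing.properties.update(contact.properties)
        return existing

    def contacts(self, experiment: str | None = None) -> list[Contact]:
        names = [experiment] if experiment is not None else self.experiment_names
        out: list[Contact] = []
        for name in names:
            edges = self._require_experiment(name)
            out.extend(edges[pair] for pair in sorted(edges))
        return out

    @property
    def n_contacts(self) -> int:
        return sum(len(e) for e in self._edges.values())

    # ------------------------------------------------------------------ views

    def experiment_subgraph(self, name: str) -> nx.Graph:
        """Simple undirected weighted view of one experiment.

        Vertices are the genes incident to at least one contact of the
        experiment (isolated registered genes are excluded); nodes and edges
        are inserted in lexicographic symbol order so downstream output is
        reproducible.
        """
        edges = self._require_experiment(name)
        g = nx.Graph(experiment=name)
        vertices = sorted({s for pair in edges for s in pair})
        for s in vertices:
            gene = self._genes[s]
            g.add_node(s, chromosome=gene.chromosome, start=gene.start, end=gene.end)
        for pair in sorted(edges):
            c = edges[pair]
            g.add_edge(
                c.gene_a, c.gene_b,
                weight=c.weight, probability=c.probability, **c.properties,
            )
        return g

    def neighbors(
        self,
        symbol: str,
        experiments: Iterable[str] | None = None,
        min_weight: float = 0,
    ) -> set[str]:
        """Genes adjacent to ``symbol`` with weight >= ``min_weight``.

        The union is taken over the selected experiments (all by default);
        the query gene itself is never included.
        """
        self.gene(symbol)
        names = list(experiments) if experiments is not None else self.experiment_names
        if not names:
            raise ValidationError("experiment selection must be non-empty")
        out: set[str] = set()
        for name in names:
            for (a, b), c in self._require_experiment(name).items():
                if c.weight >= min_weight:
                    if a == symbol:
                        out.add(b)
                    elif b == symbol:
                        out.add(a)
        return out

    # ------------------------------------------------------------ persistence

    def save(self, directory: str | Path) -> Path:
        """Write the store as three TSV files with deterministic row order."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "genes.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["symbol", "chromosome", "start", "end"])
            for s in sorted(self._genes):
                g = self._genes[s]
                w.writerow([g.symbol, g.chromosome, g.start, g.end])
        with open(directory / "experiments.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["name", "n_genes", "n_edges"])
            for e in self.experiments:
                w.writerow([e.name, e.n_genes, e.n_edges])
        with open(directory / "edges.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["experiment", "gene_a", "gene_b", "weight", "probability",
                        "properties"])
            for name in self.experiment_names:
                edges = self._edges[name]
                for pair in sorted(edges):
                    c = edges[pair]
                    w.writerow([name, c.gene_a, c.gene_b, c.weight,
                                repr(c.probability), format_properties(c.properties)])
        return directory

    @classmethod
    def load(cls, directory: str | Path, strict: bool = False) -> "MultiExperimentGraph":
        directory = Path(directory)
        for fname in _STORE_FILES:
            if not (directory / fname).exists():
                raise ValidationError(f"store directory {directory} is missing {fname}")
        store = cls(strict=False)
        with open(directory / "genes.tsv", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.upsert_gene(row["symbol"], row["chromosome"],
                                  int(row["start"]), int(row["end"]))
        declared: dict[str, tuple[int, int]] = {}
        with open(directory / "experiments.tsv", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.register_experiment(row["name"])
                declared[row["name"]] = (int(row["n_genes"]), int(row["n_edges"]))
        with open(directory / "edges.tsv", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.add_contact(
                    row["experiment"], row["gene_a"], row["gene_b"],
                    int(row["weight"]), float(row["probability"]),
                    parse_properties(row["properties"]),
                )
        for name, (n_genes, n_edges) in declared.items():
            e = store.experiment(name)
            if (e.n_genes, e.n_edges) != (n_genes, n_edges):
                raise ValidationError(
                    f"store corrupt: experiment {name!r} declares "
                    f"({n_genes} genes, {n_edges} edges) but contains "
                    f"({e.n_genes}, {e.n_edges})"
                )
        store.strict = strict
        return store


# -------------------------------------------------------- property formatting

_FORBIDDEN = set("\t\n;=")


def format_properties(props: Mapping[str, Scalar]) -> str:
    """Serialise an open property set as ``key=value;key2=value2``."""
    parts = []
    for key in sorted(props):
        value = props[key]
        text = repr(value) if isinstance(value, float) else str(value)
        if _FORBIDDEN & (set(key) | set(text)):
            raise ValidationError(
                f"property {key!r}={value!r} contains a reserved character"
            )
        parts.append(f"{key}={text}")
    return ";".join(parts)


def parse_properties(text: str) -> dict[str, Scalar]:
    """Inverse of :func:`format_properties`; values re-typed int/float/str."""
    props: dict[str, Scalar] = {}
    if not text:
        return props
    for part in text.split(";"):
        key, _, raw = part.partition("=")
        for cast in (int, float):
            try:
                props[key] = cast(raw)
                break
            except ValueError:
                continue
        else:
            props[key] = raw
    return props


# ----------------------------------------------------- module-level operations
# Thin functional aliases over the store methods.

def upsert_gene(store, symbol, chromosome, start, end) -> Gene:
    return store.upsert_gene(symbol, chromosome, start, end)


def add_contact(store, experiment, symbol_a, symbol_b, weight, probability,
                properties=None) -> Contact:
    return store.add_contact(experiment, symbol_a, symbol_b, weight,
                             probability, properties)


def experiment_subgraph(store, experiment) -> nx.Graph:
    return store.experiment_subgraph(experiment)


def neighbors(store, symbol, experiments=None, min_weight=0) -> set[str]:
    return store.neighbors(symbol, experiments, min_weight)
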