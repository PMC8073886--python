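"""Parsers and writers for the formats around the contact store.

Canonical contact-table dialect (tab-separated, header mandatory)::

    Gene1  Chr1  Start1  End1  Gene2  Chr2  Start2  End2  Weight  Probability  [extra...]

Any extra columns are carried through as named edge properties.  Gene
annotation arrives as BED (0-based half-open; BED6 strand is ignored —
contacts are spatial proximity, strand plays no role).  Binned contact
matrices (dense or coordinate-triplet TSV plus a bin table) can be converted
to gene-pair contact records; such edges get a placeholder probability of
1.0 and the property ``source=matrix`` so probability-weighted analyses can
recognise them.

The Neo4j writer emits the bulk-import CSV dialect (see
:func:`write_neo4j_import` for the bit-exact headers).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, UnknownExperimentError, ValidationError
from .model import Gene, MultiExperimentGraph, Scalar

CONTACT_COLUMNS = ("Gene1", "Chr1", "Start1", "End1",
                   "Gene2", "Chr2", "Start2", "End2",
                   "Weight", "Probability")


@dataclass
class ContactRecord:
    """One raw contact-table row before insertion into a store."""

    gene_a: str
    chrom_a: str
    start_a: int
    end_a: int
    gene_b: str
    chrom_b: str
    start_b: int
    end_b: int
    weight: int
    probability: float
    properties: dict[str, Scalar] = field(default_factory=dict)
    line: int | None = None  # 1-based file line, for error reporting

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return (a, b)


# ----------------------------------------------------------- contact tables

def parse_contact_table(path, column_map: Mapping[str, str] | None = None
                        ) -> list[ContactRecord]:
    """Parse a gene-pair contact TSV into :class:`ContactRecord` objects.

    ``column_map`` maps canonical column names to the names actually present
    in a variant input, e.g. ``{"Weight": "reads"}``.
    """
    path = Path(path)
    colmap = {c: c for c in CONTACT_COLUMNS}
    if column_map:
        colmap.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError("empty contact table", path) from None
    missing = [c for c in CONTACT_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise ParseError(f"missing mandatory column(s): {', '.join(missing)}", path)
    extras = [c for c in df.columns if c not in set(colmap.values())]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line = i + 2  # header is line 1
        try:
            weight_raw = row[colmap["Weight"]]
            prob_raw = row[colmap["Probability"]]
            weight = int(weight_raw)
            probability = float(prob_raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric Weight/Probability: {weight_raw!r}/{prob_raw!r}",
                path, line) from None
        if weight < 1:
            raise ParseError(f"weight must be >= 1, got {weight}", path, line)
        if not (0.0 < probability <= 1.0):
            raise ParseError(
                f"probability must be in (0, 1], got {probability}", path, line)
        props: dict[str, Scalar] = {}
        for col in extras:
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            for cast in (int, float):
                try:
                    props[col] = cast(raw)
                    break
                except (TypeError, ValueError):
                    continue
            else:
                props[col] = raw
        try:
            records.append(ContactRecord(
                gene_a=row[colmap["Gene1"]], chrom_a=row[colmap["Chr1"]],
                start_a=int(row[colmap["Start1"]]), end_a=int(row[colmap["End1"]]),
                gene_b=row[colmap["Gene2"]], chrom_b=row[colmap["Chr2"]],
                start_b=int(row[colmap["Start2"]]), end_b=int(row[colmap["End2"]]),
                weight=weight, probability=probability,
                properties=props, line=line,
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed row: {exc}", path, line) from None
    return records


def write_contact_table(records: Iterable[ContactRecord], path) -> Path:
    """Write records in the canonical dialect (deterministic column order).

    Extra property columns are the sorted union of property names across
    records; rows lacking a property leave the cell empty.
    """
    records = list(records)
    extras = sorted({k for r in records for k in r.properties})
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(CONTACT_COLUMNS) + extras)
        for r in records:
            row = [r.gene_a, r.chrom_a, r.start_a, r.end_a,
                   r.gene_b, r.chrom_b, r.start_b, r.end_b,
                   r.weight, repr(r.probability)]
            for k in extras:
                v = r.properties.get(k, "")
                row.append(repr(v) if isinstance(v, float) else v)
            w.writerow(row)
    return path


def load_contacts_into_store(store: MultiExperimentGraph, experiment: str,
                             records: Iterable[ContactRecord]) -> int:
    """Insert records (registering their genes) under one experiment label."""
    n = 0
    for r in records:
        store.upsert_gene(r.gene_a, r.chrom_a, r.start_a, r.end_a)
        store.upsert_gene(r.gene_b, r.chrom_b, r.start_b, r.end_b)
        store.add_contact(experiment, r.gene_a, r.gene_b, r.weight,
                          r.probability, r.properties)
        n += 1
    return n


# -------------------------------------------------------------------- BED

def parse_gene_bed(path) -> list[Gene]:
    """Parse BED3+1 (chrom, start, end, name) gene annotation.

    Strand and any further BED6+ columns are ignored.  A duplicated name
    with the same interval collapses to one gene; with a different interval
    it is an error.
    """
    path = Path(path)
    genes: dict[str, Gene] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith(("#", "track", "browser")):
                continue
            fields = text.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"expected >= 4 BED columns, got {len(fields)}", path, lineno)
            chrom, start, end, name = fields[:4]
            try:
                gene = Gene(name, chrom, int(start), int(end))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"malformed BED line: {exc}", path, lineno) from None
            existing = genes.get(name)
            if existing is not None and existing.interval != gene.interval:
                raise ParseError(
                    f"duplicate gene {name!r} with conflicting intervals "
                    f"{existing.interval} vs {gene.interval}", path, lineno)
            genes[name] = gene
    return [genes[s] for s in genes]


def write_gene_bed(genes: Iterable[Gene], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.symbol)):
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.symbol}\n")
    return path


# -------------------------------------------------------------- bin matrices

@dataclass
class BinnedContactMatrix:
    """Symmetric binned contact map: bin intervals plus read-pair counts."""

    bins: list[tuple[str, int, int]]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match {n} bins")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValidationError("contact matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValidationError("contact matrix counts must be non-negative")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.bins:
            if start >= end:
                raise ValidationError(f"bin {chrom}:{start}-{end} is empty")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping bins on {chrom}")


def load_binned_matrix(matrix_path, bins_path, fmt: str = "dense"
                       ) -> BinnedContactMatrix:
    """Load a bin table (TSV: chrom, start, end; header) plus counts.

    ``fmt='dense'``: whitespace-separated dense square matrix, no header.
    ``fmt='coo'``: TSV with header ``i, j, count`` of 0-based bin indices;
    missing entries are zero and each triplet is mirrored.
    """
    bins_df = pd.read_csv(bins_path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in bins_df.columns:
            raise ParseError(f"bin table missing column {col!r}", bins_path)
    bins = [(str(r.chrom), int(r.start), int(r.end))
            for r in bins_df.itertuples(index=False)]
    n = len(bins)
    if fmt == "dense":
        matrix = np.loadtxt(matrix_path, dtype=float, ndmin=2)
    elif fmt == "coo":
        coo = pd.read_csv(matrix_path, sep="\t")
        matrix = np.zeros((n, n))
        for r in coo.itertuples(index=False):
            i, j = int(r.i), int(r.j)
            matrix[i, j] = r.count
            matrix[j, i] = r.count
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}")
    return BinnedContactMatrix(bins, matrix)


def matrix_to_contacts(matrix: BinnedContactMatrix, genes: Sequence[Gene],
                       min_reads: int = 1) -> list[ContactRecord]:
    """Convert a binned contact map to gene-pair contact records.

    The weight of pair (g, h) sums the counts over unordered bin pairs
    {i, j}, i != j, where one bin overlaps g and the other overlaps h; each
    unordered bin pair contributes once.  Matrices carry no edge
    probability, so records get probability 1.0 and ``source=matrix``.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    gene_bins: dict[str, list[int]] = {}
    for g in genes:
        hits = [i for i, (chrom, s, e) in enumerate(matrix.bins)
                if chrom == g.chromosome and s < g.end and g.start < e]
        if hits:
            gene_bins[g.symbol] = hits
    if not gene_bins:
        warnings.warn("no gene overlaps any bin; empty conversion result")
        return []
    by_symbol = {g.symbol: g for g in genes}
    records = []
    symbols = sorted(gene_bins)
    for ai, sa in enumerate(symbols):
        for sb in symbols[ai + 1:]:
            seen: set[tuple[int, int]] = set()
            total = 0.0
            for i in gene_bins[sa]:
                for j in gene_bins[sb]:
                    if i == j:
                        continue
                    key = (min(i, j), max(i, j))
                    if key in seen:
                        continue
                    seen.add(key)
                    total += matrix.matrix[i, j]
            weight = int(round(total))
            if weight < min_reads:
                continue
            ga, gb = by_symbol[sa], by_symbol[sb]
            records.append(ContactRecord(
                ga.symbol, ga.chromosome, ga.start, ga.end,
                gb.symbol, gb.chromosome, gb.start, gb.end,
                weight=weight, probability=1.0,
                properties={"source": "matrix"},
            ))
    return records


# ------------------------------------------------------------- Neo4j export

NEO4J_NODE_HEADER = ["symbol:ID", "chromosome", "start:int", "end:int", ":LABEL"]
NEO4J_EXPERIMENT_HEADER = ["name:ID", "n_genes:int", "n_edges:int", ":LABEL"]
NEO4J_EDGE_HEADER_FIXED = [":START_ID", ":END_ID", "weight:int", "probability:float"]


def relationship_type(experiment: str) -> str:
    """Bulk-import relationship type: uppercased, non-alphanumerics -> '_'."""
    return "".join(c if c.isalnum() else "_" for c in experiment).upper()


def write_neo4j_import(store: MultiExperimentGraph, experiment: str, outdir
                       ) -> tuple[Path, Path, Path]:
    """Write bulk-import CSVs for one experiment.

    Emits ``<exp>_experiment.csv`` (name, counts), ``<exp>_edges.csv`` (one
    relationship per contact, type = uppercased experiment name) and the
    auxiliary ``genes_nodes.csv`` keyed by symbol.  Headers, bit-exact::

        symbol:ID,chromosome,start:int,end:int,:LABEL
        name:ID,n_genes:int,n_edges:int,:LABEL
        :START_ID,:END_ID,weight:int,probability:float[,<extra>...],:TYPE

    Returns (experiment_path, edges_path, nodes_path).
    """
    exp = store.experiment(experiment)  # raises UnknownExperimentError
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = relationship_type(experiment).lower()
    rel_type = relationship_type(experiment)
    contacts = store.contacts(experiment)
    extras = sorted({k for c in contacts for k in c.properties})

    exp_path = outdir / f"{stem}_experiment.csv"
    with open(exp_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(NEO4J_EXPERIMENT_HEADER)
        w.writerow([exp.name, exp.n_genes, exp.n_edges, "Experiment"])

    edges_path = outdir / f"{stem}_edges.csv"
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(NEO4J_EDGE_HEADER_FIXED + extras + [":TYPE"])
        for c in contacts:
            row = [c.gene_a, c.gene_b, c.weight, repr(c.probability)]
            row += [c.properties.get(k, "") for k in extras]
            row.append(rel_type)
            w.writerow(row)

    nodes_path = outdir / "genes_nodes.csv"
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(NEO4J_NODE_HEADER)
        for symbol in sorted(store.genes):
            g = store.genes[symbol]
            w.writerow([g.symbol, g.chromosome, g.start, g.end, "Gene"])

    return exp_path, edges_path, nodes_path


# ----------------------------------------------------------------- GraphML

def export_graphml(graph: nx.Graph, path) -> Path:
    """Write a subgraph (weight/probability as edge attributes) as GraphML."""
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# -------------------------------------------------------------- gene values

def read_gene_values(path) -> dict[str, float]:
    """Read a gene,value CSV (header mandatory; values real, negatives OK)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("gene", "value"):
        if col not in df.columns:
            raise ParseError(f"gene-value CSV missing column {col!r}", path)
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ParseError(f"duplicate gene {dup!r} in value table", path)
    try:
        values = df["value"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric value: {exc}", path) from None
    return dict(zip(df["gene"].astype(str), values))


def write_gene_values(values: Mapping[str, float], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["gene", "value"])
        for gene in sorted(values):
            w.writerow([gene, repr(float(values[gene]))])
    return path
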