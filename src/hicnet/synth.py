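"""Synthetic gene-centric Hi-C contact networks.

Every other module is testable offline against these generators, which
emulate the structure (not the biology) of a real multi-experiment
contact-graph study:

* :func:`generate_experiment` — genes laid out sequentially along a few
  chromosomes, with contact probability decaying with linear gene distance
  inside a chromosome (``p ∝ (1+d)^-alpha``, the classic power-law contact
  decay) and a small constant rate between chromosomes; read-count weights
  are geometric (mode 1, long tail), edge probabilities uniform.
* :func:`perturb_experiment` — controlled rewiring producing pseudo-
  replicates: remove ``⌊f·E⌋`` random edges, add as many fresh pairs; the
  expected edge-set Jaccard against the base is ``(1-f)/(1+f)``.
* :func:`planted_partition_experiment` — ground-truth communities for
  community-detection recovery tests.
* :func:`gene_value_table` — per-group Gaussian gene values (e.g. mock log
  fold changes) for the omics overlay.

All generators are fully deterministic under their mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import ContactRecord
from .model import Gene


@dataclass
class SynthConfig:
    """Parameters of the contact-network generator.

    Defaults give a few hundred genes on a handful of chromosomes with a
    contact-decay exponent near 1 (the decay regime typical of real contact
    maps at gene scale) and sparse inter-chromosomal background.
    """

    n_genes: int = 250
    n_chromosomes: int = 5
    mean_gene_length: float = 20_000.0   # bp, lognormal median
    sigma_gene_length: float = 0.5       # lognormal sigma (log-space)
    gap_length: int = 5_000              # bp between consecutive genes
    alpha: float = 1.1                   # intra-chromosomal decay exponent
    intra_base: float = 0.5              # contact probability at distance 0
    inter_rate: float = 0.002            # constant inter-chromosomal rate
    weight_p: float = 0.5                # geometric parameter for weights
    seed: int = 0

    def __post_init__(self):
        for name in ("intra_base", "inter_rate", "weight_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.weight_p <= 0:
            raise ValidationError("weight_p must be > 0")
        if self.n_genes < 2 or self.n_chromosomes < 1:
            raise ValidationError("need >= 2 genes on >= 1 chromosome")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")


def _layout_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[Gene]:
    genes = []
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    mu = np.log(cfg.mean_gene_length)
    for c, idx in enumerate(per_chrom, start=1):
        pos = 0
        for i in idx:
            length = max(200, int(rng.lognormal(mu, cfg.sigma_gene_length)))
            genes.append(Gene(f"G{i:05d}", f"chr{c}", pos, pos + length))
            pos += length + cfg.gap_length
    return genes


def _record(a: Gene, b: Gene, weight: int, probability: float) -> ContactRecord:
    if a.symbol > b.symbol:
        a, b = b, a
    return ContactRecord(a.symbol, a.chromosome, a.start, a.end,
                         b.symbol, b.chromosome, b.start, b.end,
                         weight=weight, probability=probability)


def _draw_weight(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def _draw_probability(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.05, 1.0))


def generate_experiment(cfg: SynthConfig
                        ) -> tuple[list[ContactRecord], list[Gene]]:
    """Draw one synthetic experiment: (contact records, gene annotation).

    Genes are placed sequentially per chromosome.  A pair at gene-index
    distance ``d`` on the same chromosome contacts with probability
    ``intra_base * (1+d)^-alpha``; pairs on different chromosomes with
    probability ``inter_rate``.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _layout_genes(cfg, rng)
    records = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if a.chromosome == b.chromosome:
                d = abs(int(a.symbol[1:]) - int(b.symbol[1:]))
                p_edge = cfg.intra_base * (1.0 + d) ** (-cfg.alpha)
            else:
                p_edge = cfg.inter_rate
            if rng.random() < p_edge:
                records.append(_record(a, b, _draw_weight(rng, cfg.weight_p),
                                       _draw_probability(rng)))
    return records, genes


def perturb_experiment(records: list[ContactRecord], fraction: float,
                       seed: int) -> list[ContactRecord]:
    """Rewire a fraction of the edge set, preserving the edge count.

    Removes ``⌊fraction·E⌋`` edges uniformly at random and adds the same
    number of fresh gene pairs (never duplicating a base edge or each
    other) among the genes incident to the input records, with freshly
    drawn weights and probabilities.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    base_pairs = {r.pair for r in records}
    genes = sorted({g for r in records
                    for g in (Gene(r.gene_a, r.chrom_a, r.start_a, r.end_a),
                              Gene(r.gene_b, r.chrom_b, r.start_b, r.end_b))},
                   key=lambda g: g.symbol)
    n, e = len(genes), len(records)
    r = int(fraction * e)
    if n * (n - 1) // 2 - e < r:
        raise ValidationError(
            "graph too dense: not enough fresh gene pairs to add")
    keep_idx = rng.choice(e, size=e - r, replace=False) if r else np.arange(e)
    out = [records[i] for i in sorted(keep_idx)]
    added: set[tuple[str, str]] = set()
    while len(added) < r:
        i, j = rng.integers(0, n), rng.integers(0, n)
        if i == j:
            continue
        a, b = genes[i], genes[j]
        pair = tuple(sorted((a.symbol, b.symbol)))
        if pair in base_pairs or pair in added:
            continue
        added.add(pair)
        out.append(_record(a, b, _draw_weight(rng, 0.5), _draw_probability(rng)))
    return out


def planted_partition_experiment(n_genes: int, k_communities: int,
                                 p_in: float, p_out: float, seed: int
                                 ) -> tuple[list[ContactRecord], list[Gene],
                                            dict[str, int]]:
    """Planted-partition graph with recorded ground-truth labels.

    Genes are assigned to ``k_communities`` contiguous blocks; within-block
    pairs contact with probability ``p_in``, between-block pairs with
    ``p_out`` (must be strictly smaller).  Returns (records, genes, labels).
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValidationError(
            f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    rng = np.random.default_rng(seed)
    genes, labels = [], {}
    pos = 0
    blocks = np.array_split(np.arange(n_genes), k_communities)
    for cid, idx in enumerate(blocks):
        for i in idx:
            g = Gene(f"G{i:05d}", "chr1", pos, pos + 10_000)
            genes.append(g)
            labels[g.symbol] = cid
            pos += 15_000
    records = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            p_edge = p_in if labels[a.symbol] == labels[b.symbol] else p_out
            if p_edge and rng.random() < p_edge:
                records.append(_record(a, b, _draw_weight(rng, 0.5),
                                       _draw_probability(rng)))
    return records, genes, labels


def gene_value_table(labels: dict[str, int], group_means: dict[int, float],
                     sigma: float, seed: int) -> dict[str, float]:
    """Gaussian gene values with a configurable mean per planted group.

    Emulates e.g. log fold changes whose sign tracks community membership,
    so group-comparison power can be probed at a chosen effect size.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    return {g: float(rng.normal(group_means[labels[g]], sigma))
            for g in sorted(labels)}
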