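"""Experiment-level comparison.

Covers the cross-experiment views a multi-run contact store supports:
edge-set Jaccard similarity between experiments (and the full symmetric
matrix with unit diagonal), aligned degree-distribution tables suitable for
bar plotting, Louvain community profiles, partition agreement (adjusted
Rand index) and per-gene metric deltas between two experiments.

Note on naming: edge-set overlap is reported as Jaccard *similarity*
(1 = identical edge sets), the convention in which a self-comparison scores
1.0 on the diagonal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import analytics
from .errors import ValidationError
from .model import MultiExperimentGraph


def _edge_set(store: MultiExperimentGraph, experiment: str) -> set[tuple[str, str]]:
    return {c.pair for c in store.contacts(experiment)}


def experiment_edge_jaccard(store: MultiExperimentGraph, exp_a: str,
                            exp_b: str, weighted: bool = False) -> float:
    """Jaccard similarity of two experiments' unordered gene-pair edge sets.

    Weights and probabilities are ignored by default; ``weighted=True``
    scores each shared pair by min/max weight ratio instead of 1 (a soft
    overlap that penalises discordant read support).  Two empty experiments
    score 1.0.
    """
    ea, eb = _edge_set(store, exp_a), _edge_set(store, exp_b)
    union = ea | eb
    if not union:
        return 1.0
    if not weighted:
        return len(ea & eb) / len(union)
    wa = {c.pair: c.weight for c in store.contacts(exp_a)}
    wb = {c.pair: c.weight for c in store.contacts(exp_b)}
    inter = sum(min(wa[p], wb[p]) / max(wa[p], wb[p]) for p in ea & eb)
    return inter / len(union)


def jaccard_matrix(store: MultiExperimentGraph, experiments=None,
                   weighted: bool = False) -> pd.DataFrame:
    """All-pairs edge Jaccard: symmetric DataFrame with unit diagonal."""
    names = sorted(experiments) if experiments is not None \
        else store.experiment_names
    if len(names) < 2:
        raise ValidationError("need at least 2 experiments for a Jaccard matrix")
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            j = experiment_edge_jaccard(store, a, b, weighted=weighted)
            mat.loc[a, b] = mat.loc[b, a] = j
    return mat


def degree_table(store: MultiExperimentGraph, experiments=None,
                 binning: int | None = None) -> pd.DataFrame:
    """Aligned degree histogram per experiment (shared bin edges).

    ``binning=None`` uses one row per integer degree; an integer bins
    degrees into intervals of that width (row label = interval start).
    Column sums equal each experiment's gene count.
    """
    names = sorted(experiments) if experiments is not None \
        else store.experiment_names
    dists = {n: analytics.degree_distribution(store.experiment_subgraph(n))
             for n in names}
    width = binning or 1
    if width < 1:
        raise ValidationError("binning width must be >= 1")
    all_degrees = [d for dist in dists.values() for d in dist]
    max_bin = (max(all_degrees) // width) if all_degrees else 0
    index = [b * width for b in range(max_bin + 1)]
    table = pd.DataFrame(0, index=index, columns=names)
    table.index.name = "degree"
    for name, dist in dists.items():
        for degree, count in dist.items():
            table.loc[(degree // width) * width, name] += count
    return table


@dataclass
class CommunityProfile:
    """Summary of one experiment's Louvain clustering."""

    experiment: str
    sizes: list[int]            # descending community sizes; sum = n vertices
    n_communities: int
    modularity: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def community_profile(store: MultiExperimentGraph, experiment: str,
                      seed: int, resolution: float = 1.0) -> CommunityProfile:
    part = analytics.louvain(store.experiment_subgraph(experiment), seed=seed,
                             resolution=resolution)
    sizes = part.sizes()
    return CommunityProfile(experiment, sizes, len(sizes), part.modularity)


def partition_agreement(partition_a, partition_b) -> float:
    """Adjusted Rand index between two community assignments.

    Accepts :class:`hicnet.analytics.Partition` objects or plain
    gene->label mappings; partitions over different gene sets are compared
    on the intersection (with a warning).
    """
    ma = getattr(partition_a, "membership", partition_a)
    mb = getattr(partition_b, "membership", partition_b)
    shared = sorted(set(ma) & set(mb))
    if not shared:
        raise ValidationError("partitions share no genes")
    if len(shared) < len(ma) or len(shared) < len(mb):
        warnings.warn(f"partitions compared on {len(shared)} shared genes")
    return float(adjusted_rand_score([ma[g] for g in shared],
                                     [mb[g] for g in shared]))


def metric_delta(store: MultiExperimentGraph, exp_a: str, exp_b: str,
                 metric: str, seed: int | None = None) -> pd.DataFrame:
    """Per-gene metric change between two experiments.

    Inner join on genes present in both subgraphs; ``delta = value_b -
    value_a``; rows sorted by |delta| descending (symbol ascending on ties).
    """
    va = analytics.compute_metric(store.experiment_subgraph(exp_a), metric, seed)
    vb = analytics.compute_metric(store.experiment_subgraph(exp_b), metric, seed)
    shared = sorted(set(va) & set(vb))
    df = pd.DataFrame({
        "gene": shared,
        "value_a": [va[g] for g in shared],
        "value_b": [vb[g] for g in shared],
    })
    df["delta"] = df["value_b"] - df["value_a"]
    df = (df.assign(_abs=df["delta"].abs())
            .sort_values(["_abs", "gene"], ascending=[False, True])
            .drop(columns="_abs"))
    return df.reset_index(drop=True)
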