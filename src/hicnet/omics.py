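"""Overlay of expression/methylation values onto graph metrics.

Given a gene -> value table (e.g. log fold changes or differential
methylation scores), genes are split into over- and under-regulated groups
and a per-gene graph metric is compared between the groups: per-group mean,
sample variance (n-1) and standard deviation, plus a two-sample t statistic
and p-value.

Two p-value conventions are offered.  The default, ``"welch"``, is the
standard Welch unequal-variance two-sided t-test with Welch-Satterthwaite
degrees of freedom.  ``"paper_compat"`` evaluates the two-sided tail of the
t statistic against a reference t distribution with one degree of freedom
(closed form ``p = 2 (1/2 - arctan|t| / pi)``), a quirky convention that
some published group comparisons of this kind used; it is provided for
compatibility and is not recommended for new analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from . import analytics
from .errors import ValidationError
from .model import MultiExperimentGraph

P_CONVENTIONS = ("welch", "paper_compat")


@dataclass
class GeneGroups:
    """Up- vs down-regulated gene symbol sets (always disjoint)."""

    over: set[str]
    under: set[str]
    n_excluded: int = 0  # genes sitting exactly on the threshold


def classify_direction(values: Mapping[str, float],
                       threshold: float = 0.0) -> GeneGroups:
    """Split genes by sign relative to a threshold.

    ``over`` holds genes strictly above, ``under`` strictly below; genes at
    exactly the threshold are excluded and counted.  An empty side is a
    warning, not an error.
    """
    if not values:
        raise ValidationError("gene-value mapping must be non-empty")
    over = {g for g, v in values.items() if v > threshold}
    under = {g for g, v in values.items() if v < threshold}
    excluded = len(values) - len(over) - len(under)
    if not over or not under:
        warnings.warn("all genes fall on one side of the threshold")
    return GeneGroups(over, under, excluded)


def paper_compat_pvalue(t: float) -> float:
    """Two-sided tail of t against a 1-df t (Cauchy) reference."""
    return 2.0 * (0.5 - math.atan(abs(t)) / math.pi)


@dataclass
class GroupComparison:
    """One comparison row: per-group moments plus the t-test outcome."""

    experiment: str
    metric: str
    n_over: int
    n_under: int
    mean_over: float
    mean_under: float
    var_over: float
    var_under: float
    std_over: float
    std_under: float
    t: float
    p: float
    p_convention: str
    n_dropped: int = 0  # group genes absent from the experiment subgraph


def metric_by_group(store: MultiExperimentGraph, experiment: str, metric: str,
                    groups: GeneGroups, p_convention: str = "welch",
                    seed: int | None = None) -> GroupComparison:
    """Compare a per-gene metric between the over and under groups.

    The metric map is computed once for the experiment; group genes absent
    from the subgraph are dropped (their count is reported).  The t
    statistic is the Welch two-sample statistic on (over, under) — positive
    when the over group scores higher.
    """
    if p_convention not in P_CONVENTIONS:
        raise ValidationError(
            f"unknown p_convention {p_convention!r}; expected one of "
            f"{', '.join(P_CONVENTIONS)}")
    metric_map = analytics.compute_metric(
        store.experiment_subgraph(experiment), metric, seed)
    over = np.array([metric_map[g] for g in sorted(groups.over) if g in metric_map])
    under = np.array([metric_map[g] for g in sorted(groups.under) if g in metric_map])
    dropped = (len(groups.over) - len(over)) + (len(groups.under) - len(under))
    if len(over) < 2 or len(under) < 2:
        raise ValidationError(
            f"each group needs >= 2 genes present in {experiment!r} "
            f"(got {len(over)} over, {len(under)} under)")
    t, p_welch = stats.ttest_ind(over, under, equal_var=False)
    t = float(t)
    p = paper_compat_pvalue(t) if p_convention == "paper_compat" else float(p_welch)
    return GroupComparison(
        experiment=experiment, metric=metric,
        n_over=len(over), n_under=len(under),
        mean_over=float(over.mean()), mean_under=float(under.mean()),
        var_over=float(over.var(ddof=1)), var_under=float(under.var(ddof=1)),
        std_over=float(over.std(ddof=1)), std_under=float(under.std(ddof=1)),
        t=t, p=p, p_convention=p_convention, n_dropped=dropped,
    )


_TABLE_COLUMNS = ["Experiment", "Mean_Over", "Mean_Under", "Variance_Over",
                  "Variance_Under", "Stdev_Over", "Stdev_Under", "ttest",
                  "p_value"]


def comparison_table(store: MultiExperimentGraph, experiments: Iterable[str],
                     metric: str, groups: GeneGroups,
                     p_convention: str = "welch",
                     seed: int | None = None) -> list[GroupComparison]:
    """One :class:`GroupComparison` row per experiment."""
    return [metric_by_group(store, e, metric, groups, p_convention, seed)
            for e in experiments]


def comparison_table_csv(rows: Iterable[GroupComparison], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(_TABLE_COLUMNS) + "\n")
        for r in rows:
            fh.write(",".join(map(str, [
                r.experiment, r.mean_over, r.mean_under, r.var_over,
                r.var_under, r.std_over, r.std_under, r.t, r.p])) + "\n")
    return path


def export_gene_lists(obj, path, fmt: str = "txt") -> Path:
    """Export gene symbols for external enrichment services.

    Accepts a set/list of symbols, a :class:`GeneGroups` (over then under,
    tagged in the CSV variant), a :class:`~hicnet.analytics.Partition` or a
    :class:`~hicnet.analytics.CentralityMap`.  ``fmt='txt'`` writes one
    gene per line; ``fmt='csv'`` adds the value/label column.
    """
    path = Path(path)
    if isinstance(obj, GeneGroups):
        rows = [(g, "over") for g in sorted(obj.over)] + \
               [(g, "under") for g in sorted(obj.under)]
    elif isinstance(obj, analytics.Partition):
        rows = [(g, obj.membership[g]) for g in sorted(obj.membership)]
    elif isinstance(obj, Mapping):
        rows = [(g, obj[g]) for g in sorted(obj)]
    else:
        rows = [(g, "") for g in sorted(obj)]
    if not rows:
        warnings.warn(f"exporting an empty gene list to {path}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if fmt == "txt":
            for g, _ in rows:
                fh.write(f"{g}\n")
        elif fmt == "csv":
            fh.write("gene,value\n")
            for g, v in rows:
                fh.write(f"{g},{v}\n")
        else:
            raise ValidationError(f"unknown export format {fmt!r}")
    return path
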