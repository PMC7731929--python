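"""Tumor-vs-normal network perturbation statistics.

Quantifies how the tumor co-expression subnetwork differs from its
matched normal subnetwork: size collapse (node/edge fold changes),
loss of class-pair edges (e.g. transcription factor-oncogene),
per-gene centrality shifts, cross-network centrality correlation,
recurrent degree gain across cancer types, per-community degree-change
distributions, and shortest-path length perturbation.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import (
    DEFAULT_DAMPING,
    CommunityPartition,
    PathResult,
    degree,
    pagerank,
)
from .graph import DualGraph

__all__ = [
    "CATEGORIES",
    "build_centrality_table",
    "size_fold_change",
    "lost_class_edges",
    "centrality_shift_classify",
    "CrossNetworkCorrelation",
    "cross_network_centrality_correlation",
    "recurrent_degree_gain",
    "community_degree_change",
    "PathSummary",
    "path_length_change_summary",
    "DifferentialReport",
]

logger = logging.getLogger(__name__)

DECREASED = "decreased"
RELATIVE_INCREASE = "relative_increase"
ABSOLUTE_INCREASE = "absolute_increase"
UNCHANGED = "unchanged"
CATEGORIES = (DECREASED, RELATIVE_INCREASE, ABSOLUTE_INCREASE, UNCHANGED)


def build_centrality_table(
    dual: DualGraph,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-7,
    max_iter: int = 100,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene PageRank and degree in each condition.

    Rows cover the union of both subnetworks' nodes (or an explicit gene
    namespace); a gene absent from a subnetwork gets degree 0 and the
    PageRank base score ``1 - damping`` there.
    """
    namespace = sorted(set(genes) if genes is not None else dual.all_nodes)
    base = 1.0 - damping
    columns: dict[str, dict[str, float]] = {}
    for condition in ("normal", "tumor"):
        graph = dual.graph(condition)
        pr = pagerank(graph, damping=damping, tol=tol, max_iter=max_iter)
        deg = degree(graph)
        columns[f"pagerank_{condition}"] = {
            g: pr.get(g, base) for g in namespace
        }
        columns[f"degree_{condition}"] = {g: deg.get(g, 0) for g in namespace}
    table = pd.DataFrame(columns, index=namespace)
    table.index.name = "gene"
    table["degree_normal"] = table["degree_normal"].astype(int)
    table["degree_tumor"] = table["degree_tumor"].astype(int)
    return table


def size_fold_change(dual: DualGraph) -> tuple[float, float]:
    """(node_fold, edge_fold) = normal count / tumor count.

    Values above 1 mean the tumor subnetwork is smaller.  An empty tumor
    subnetwork yields infinite folds with a warning.
    """
    if dual.normal.n_nodes == 0:
        raise ValueError("normal subnetwork is empty")
    if dual.tumor.n_nodes == 0 or dual.tumor.n_edges == 0:
        warnings.warn("empty tumor subnetwork: infinite fold change", stacklevel=2)
    node_fold = (
        dual.normal.n_nodes / dual.tumor.n_nodes
        if dual.tumor.n_nodes
        else math.inf
    )
    edge_fold = (
        dual.normal.n_edges / dual.tumor.n_edges
        if dual.tumor.n_edges
        else math.inf
    )
    return float(node_fold), float(edge_fold)


def lost_class_edges(
    dual: DualGraph, class_a: str, class_b: str
) -> tuple[int, list[tuple[str, str]]]:
    """Normal-only edges linking a ``class_a`` gene with a ``class_b`` gene.

    Counts edges with one endpoint in each class that are present in the
    normal subnetwork but absent from the tumor subnetwork.  Symmetric
    in class order.
    """
    in_a = set(dual.annotations.genes_in_class(class_a))
    in_b = set(dual.annotations.genes_in_class(class_b))
    lost = []
    for key in dual.normal.edges:
        if key in dual.tumor.edges:
            continue
        a, b = key
        if (a in in_a and b in in_b) or (a in in_b and b in in_a):
            lost.append(key)
    lost.sort()
    return len(lost), lost


def centrality_shift_classify(
    table: pd.DataFrame,
) -> tuple[pd.Series, dict[str, float]]:
    """Classify each gene's tumor-vs-normal centrality shift.

    Categories (a partition of the gene set):

    * ``decreased`` - PageRank lower in tumor;
    * ``relative_increase`` - PageRank higher but degree lower (more
      central within a sparser neighborhood);
    * ``absolute_increase`` - PageRank higher and degree not lower;
    * ``unchanged`` - PageRank exactly equal.

    Returns the per-gene category series and category fractions
    (summing to 1).
    """
    required = {"pagerank_normal", "pagerank_tumor", "degree_normal", "degree_tumor"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"centrality table missing columns: {sorted(missing)}")
    pr_n = table["pagerank_normal"].to_numpy(dtype=float)
    pr_t = table["pagerank_tumor"].to_numpy(dtype=float)
    d_n = table["degree_normal"].to_numpy(dtype=float)
    d_t = table["degree_tumor"].to_numpy(dtype=float)

    cats = np.where(
        pr_t < pr_n,
        DECREASED,
        np.where(
            pr_t > pr_n,
            np.where(d_t < d_n, RELATIVE_INCREASE, ABSOLUTE_INCREASE),
            UNCHANGED,
        ),
    )
    series = pd.Series(cats, index=table.index, name="category")
    n = len(series)
    fractions = {c: float((series == c).sum()) / n for c in CATEGORIES}
    return series, fractions


@dataclass
class CrossNetworkCorrelation:
    """Within-group pairwise Pearson correlations of centrality vectors."""

    pair_r: pd.DataFrame  # columns: network_a, network_b, group, r, n_shared, excluded
    group_means: dict[str, float]
    t_statistic: float
    p_value: float


def cross_network_centrality_correlation(
    scores: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    exclusions: Iterable[tuple[str, str]] = (),
) -> CrossNetworkCorrelation:
    """Pearson correlation of per-gene scores between networks of a group.

    ``scores`` maps network name -> {gene: score}; ``groups`` maps each
    network name to its group label (e.g. ``"normal"`` / ``"tumor"``).
    Every within-group pair of networks is correlated over the genes
    they share (pairwise-complete).  A Welch two-sample t-test compares
    the two groups' correlation values, honoring an explicit list of
    excluded pairs; excluded pairs still appear in ``pair_r`` flagged
    ``excluded``.
    """
    names = sorted(scores)
    unknown = [n for n in names if n not in groups]
    if unknown:
        raise ValueError(f"networks without a group label: {unknown}")
    excluded = {frozenset(p) for p in exclusions}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if groups[a] != groups[b]:
                continue
            shared = sorted(set(scores[a]) & set(scores[b]))
            if len(shared) < 2:
                logger.warning(
                    "pair (%s, %s) shares %d genes; omitted", a, b, len(shared)
                )
                continue
            x = np.array([scores[a][g] for g in shared])
            y = np.array([scores[b][g] for g in shared])
            r = float(stats.pearsonr(x, y).statistic)
            rows.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "group": groups[a],
                    "r": r,
                    "n_shared": len(shared),
                    "excluded": frozenset((a, b)) in excluded,
                }
            )
    pair_r = pd.DataFrame(
        rows,
        columns=["network_a", "network_b", "group", "r", "n_shared", "excluded"],
    )
    kept = pair_r[~pair_r["excluded"]]
    group_labels = sorted(set(groups.values()))
    group_means = {
        g: float(kept.loc[kept["group"] == g, "r"].mean()) for g in group_labels
    }
    if len(group_labels) == 2:
        a_vals = kept.loc[kept["group"] == group_labels[0], "r"]
        b_vals = kept.loc[kept["group"] == group_labels[1], "r"]
        t_res = stats.ttest_ind(a_vals, b_vals, equal_var=False)
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
    else:
        t_stat, p_value = math.nan, math.nan
    return CrossNetworkCorrelation(pair_r, group_means, t_stat, p_value)


def recurrent_degree_gain(
    tables: Mapping[str, pd.DataFrame], min_types: int = 5
) -> list[str]:
    """Genes gaining degree (tumor > normal) in at least ``min_types`` tables.

    ``tables`` maps cancer-type name -> centrality table.  A gene absent
    from a table does not gain there.
    """
    if len(tables) < min_types:
        raise ValueError(
            f"need at least min_types={min_types} tables, got {len(tables)}"
        )
    gains: Counter[str] = Counter()
    for table in tables.values():
        gained = table.index[table["degree_tumor"] > table["degree_normal"]]
        gains.update(str(g) for g in gained)
    return sorted(g for g, c in gains.items() if c >= min_types)


def community_degree_change(
    partition: CommunityPartition,
    table: pd.DataFrame,
    min_size: int = 50,
) -> pd.DataFrame:
    """Distribution of ``degree_tumor - degree_normal`` per large community.

    Only communities with at least ``min_size`` members are reported;
    one row per community with member count, median and quartiles of the
    per-gene degree change.
    """
    rows = []
    for cid, members in sorted(partition.communities().items()):
        if len(members) < min_size:
            continue
        present = [g for g in members if g in table.index]
        delta = (
            table.loc[present, "degree_tumor"] - table.loc[present, "degree_normal"]
        ).to_numpy(dtype=float)
        q1, med, q3 = np.percentile(delta, [25, 50, 75])
        rows.append(
            {
                "community": cid,
                "n_genes": len(members),
                "median_change": float(med),
                "q1_change": float(q1),
                "q3_change": float(q3),
                "mean_change": float(delta.mean()),
            }
        )
    if not rows:
        warnings.warn(
            f"no community reaches min_size={min_size}", stacklevel=2
        )
    return pd.DataFrame(
        rows,
        columns=[
            "community", "n_genes", "median_change",
            "q1_change", "q3_change", "mean_change",
        ],
    )


@dataclass
class PathSummary:
    """Shortest-path perturbation between matched path sets."""

    mean_finite_normal: float | None
    mean_finite_tumor: float | None
    infinite_normal: int
    infinite_tumor: int
    joint_histogram: Counter  # over (length_normal, length_tumor), both finite
    modal_transition: tuple[float, float] | None
    n_pairs: int


def path_length_change_summary(
    paths_normal: Sequence[PathResult],
    paths_tumor: Sequence[PathResult],
) -> PathSummary:
    """Compare matched shortest-path sets between conditions.

    Means are taken over finite paths only; infinite paths are tallied
    separately.  The joint histogram and its modal cell consider only
    pairs finite in both conditions.  The two lists must cover the same
    pair universe.
    """
    key = lambda p: tuple(sorted((p.source, p.target)))
    normal = {key(p): p.length for p in paths_normal}
    tumor = {key(p): p.length for p in paths_tumor}
    if set(normal) != set(tumor):
        raise ValueError("path lists cover different pair universes")

    def _mean_finite(lengths: Iterable[float]) -> float | None:
        finite = [x for x in lengths if math.isfinite(x)]
        return float(np.mean(finite)) if finite else None

    hist: Counter = Counter()
    for pair, ln in normal.items():
        lt = tumor[pair]
        if math.isfinite(ln) and math.isfinite(lt):
            hist[(ln, lt)] += 1
    modal = max(hist, key=lambda cell: (hist[cell], (-cell[0], -cell[1]))) \
        if hist else None
    return PathSummary(
        mean_finite_normal=_mean_finite(normal.values()),
        mean_finite_tumor=_mean_finite(tumor.values()),
        infinite_normal=sum(1 for x in normal.values() if math.isinf(x)),
        infinite_tumor=sum(1 for x in tumor.values() if math.isinf(x)),
        joint_histogram=hist,
        modal_transition=modal,
        n_pairs=len(normal),
    )


@dataclass
class DifferentialReport:
    """All tumor-vs-normal comparison statistics for one dual graph."""

    node_fold: float
    edge_fold: float
    lost_class_edge_counts: dict[tuple[str, str], int]
    lost_class_edge_lists: dict[tuple[str, str], list[tuple[str, str]]]
    centrality_categories: pd.Series
    category_fractions: dict[str, float]
    community_degree_changes: pd.DataFrame
    path_summary: PathSummary | None

    def to_text(self) -> str:
        lines = [
            "Differential co-expression report",
            "=" * 34,
            f"node fold change (normal/tumor): {self.node_fold:.3f}",
            f"edge fold change (normal/tumor): {self.edge_fold:.3f}",
            "",
            "lost class-pair edges:",
        ]
        for pair, count in sorted(self.lost_class_edge_counts.items()):
            lines.append(f"  {pair[0]}-{pair[1]}: {count}")
        lines.append("")
        lines.append("centrality shift fractions:")
        for cat in CATEGORIES:
            lines.append(f"  {cat}: {self.category_fractions.get(cat, 0.0):.1%}")
        if self.path_summary is not None:
            s = self.path_summary
            fmt = lambda v: "NA" if v is None else f"{v:.2f}"
            lines += [
                "",
                "class-pair shortest paths:",
                f"  mean finite length normal: {fmt(s.mean_finite_normal)}",
                f"  mean finite length tumor:  {fmt(s.mean_finite_tumor)}",
                f"  infinite paths normal: {s.infinite_normal}",
                f"  infinite paths tumor:  {s.infinite_tumor}",
                f"  modal transition: {s.modal_transition}",
            ]
        return "\n".join(lines) + "\n"
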