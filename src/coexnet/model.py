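"""Model/Results facade over the differential co-expression pipeline.

:class:`DifferentialCoexpressionModel` is constructed from matched
normal/tumor expression matrices plus gene annotations; ``fit()`` builds
both soft-thresholded Spearman subnetworks, runs PageRank, Louvain and
class-pair shortest paths under the configured conventions, and returns
a :class:`DifferentialCoexpressionResults` carrying the dual graph, the
centrality table, the community partitions, and the differential report,
with ``summary()``, export and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import differential as diff
from .algorithms import (
    DEFAULT_DAMPING,
    CommunityPartition,
    class_pair_paths,
    louvain,
)
from .coexpression import (
    DISCARD_THRESHOLD,
    RETENTION_THRESHOLD,
    SOFT_POWER,
    ExpressionMatrix,
    build_network,
)
from .graph import (
    EPIGENETIC,
    ONCOGENE,
    DualGraph,
    GeneAnnotationTable,
    load_expression,
)

__all__ = ["DifferentialCoexpressionModel", "DifferentialCoexpressionResults"]


class DifferentialCoexpressionModel:
    """Differential co-expression network model for one matched cohort.

    Parameters
    ----------
    normal, tumor : ExpressionMatrix
        Matched genes x samples expression for the two conditions.
    annotations : GeneAnnotationTable
        Gene symbols with UniProt accessions, descriptions and
        regulatory-class flags.
    power, retention, discard : edge-rule parameters (rho**power weight,
        retained if above ``retention``, |rho| above ``discard``
        dropped as a near-zero-expression artifact).
    damping : PageRank damping factor (unnormalized convention with
        per-node base score ``1 - damping``).
    min_community_size : smallest community size reported in the
        community degree-change statistics.
    path_mode : ``"hops"`` (default) or ``"inverse_weight"`` costs for
        shortest paths.
    """

    def __init__(
        self,
        normal: ExpressionMatrix,
        tumor: ExpressionMatrix,
        annotations: GeneAnnotationTable,
        *,
        power: int = SOFT_POWER,
        retention: float = RETENTION_THRESHOLD,
        discard: float = DISCARD_THRESHOLD,
        damping: float = DEFAULT_DAMPING,
        min_community_size: int = 50,
        path_mode: str = "hops",
        path_classes: tuple[str, str] = (ONCOGENE, EPIGENETIC),
    ):
        if normal.condition != "normal" or tumor.condition != "tumor":
            raise ValueError("expected one 'normal' and one 'tumor' matrix")
        self.normal = normal
        self.tumor = tumor
        self.annotations = annotations
        self.power = power
        self.retention = retention
        self.discard = discard
        self.damping = damping
        self.min_community_size = min_community_size
        self.path_mode = path_mode
        self.path_classes = path_classes

    @classmethod
    def from_tsv(
        cls,
        normal_path: str | Path,
        tumor_path: str | Path,
        annotation_path: str | Path,
        **kwargs,
    ) -> "DifferentialCoexpressionModel":
        return cls(
            load_expression(normal_path, "normal"),
            load_expression(tumor_path, "tumor"),
            GeneAnnotationTable.from_tsv(annotation_path),
            **kwargs,
        )

    def fit(self, seed: int = 0) -> "DifferentialCoexpressionResults":
        """Build both subnetworks and run the full analysis."""
        normal_graph = build_network(
            self.normal, self.power, self.retention, self.discard
        )
        tumor_graph = build_network(
            self.tumor, self.power, self.retention, self.discard
        )
        dual = DualGraph(normal_graph, tumor_graph, self.annotations)

        centrality = diff.build_centrality_table(dual, damping=self.damping)
        partitions = {
            cond: louvain(dual.graph(cond), seed=seed)
            for cond in ("normal", "tumor")
            if dual.graph(cond).n_edges > 0
        }
        paths = class_pair_paths(dual, *self.path_classes, mode=self.path_mode)
        path_summary = (
            diff.path_length_change_summary(paths["normal"], paths["tumor"])
            if paths["normal"]
            else None
        )
        node_fold, edge_fold = diff.size_fold_change(dual)
        categories, fractions = diff.centrality_shift_classify(centrality)
        lost_counts, lost_lists = {}, {}
        for pair in [("TF", ONCOGENE), (EPIGENETIC, ONCOGENE)]:
            count, edges = diff.lost_class_edges(dual, *pair)
            lost_counts[pair] = count
            lost_lists[pair] = edges
        community_changes = (
            diff.community_degree_change(
                partitions["tumor"], centrality, self.min_community_size
            )
            if "tumor" in partitions
            else pd.DataFrame()
        )
        report = diff.DifferentialReport(
            node_fold=node_fold,
            edge_fold=edge_fold,
            lost_class_edge_counts=lost_counts,
            lost_class_edge_lists=lost_lists,
            centrality_categories=categories,
            category_fractions=fractions,
            community_degree_changes=community_changes,
            path_summary=path_summary,
        )
        return DifferentialCoexpressionResults(
            model=self,
            dual=dual,
            centrality=centrality,
            partitions=partitions,
            class_paths=paths,
            report=report,
            seed=seed,
        )


@dataclass
class DifferentialCoexpressionResults:
    """Fitted differential co-expression networks and their statistics."""

    model: DifferentialCoexpressionModel
    dual: DualGraph
    centrality: pd.DataFrame
    partitions: dict[str, CommunityPartition]
    class_paths: dict[str, list]
    report: diff.DifferentialReport
    seed: int

    def top_genes(self, condition: str = "normal", n: int = 10) -> pd.DataFrame:
        """Highest-PageRank genes in one condition, with both conditions' scores."""
        col = f"pagerank_{condition}"
        return self.centrality.sort_values(col, ascending=False).head(n)

    def summary(self) -> str:
        """Human-readable overview in the spirit of a model results table."""
        m = self.model
        lines = [
            "Differential Co-expression Network Results",
            "=" * 58,
            f"edge rule: weight = rho^{m.power} > {m.retention}, "
            f"|rho| <= {m.discard}",
            f"pagerank damping: {m.damping}   path mode: {m.path_mode}",
            "-" * 58,
            f"{'':24s}{'normal':>14s}{'tumor':>14s}",
            f"{'nodes':24s}{self.dual.normal.n_nodes:>14d}"
            f"{self.dual.tumor.n_nodes:>14d}",
            f"{'edges':24s}{self.dual.normal.n_edges:>14d}"
            f"{self.dual.tumor.n_edges:>14d}",
        ]
        for cond in ("normal", "tumor"):
            if cond in self.partitions:
                part = self.partitions[cond]
                lines.append(
                    f"{'communities (' + cond + ')':24s}"
                    f"{len(part.sizes()):>14d}{'Q=%.4f' % part.modularity:>14s}"
                )
        lines.append("-" * 58)
        lines.append(
            f"node fold (normal/tumor): {self.report.node_fold:.3f}   "
            f"edge fold: {self.report.edge_fold:.3f}"
        )
        lines.append("centrality shift fractions:")
        for cat in diff.CATEGORIES:
            lines.append(
                f"  {cat:20s} {self.report.category_fractions[cat]:7.1%}"
            )
        s = self.report.path_summary
        if s is not None:
            fmt = lambda v: "NA" if v is None else f"{v:.2f}"
            lines.append(
                f"class-pair paths ({'-'.join(self.model.path_classes)}): "
                f"mean finite {fmt(s.mean_finite_normal)} -> "
                f"{fmt(s.mean_finite_tumor)}, "
                f"infinite {s.infinite_normal} -> {s.infinite_tumor}"
            )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_degree_distributions(self, ax=None):
        """Log-log degree distributions of both subnetworks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cond, color in (("normal", "tab:blue"), ("tumor", "tab:red")):
            degs = self.centrality[f"degree_{cond}"]
            degs = degs[degs > 0]
            if degs.empty:
                continue
            counts = degs.value_counts().sort_index()
            ax.loglog(counts.index, counts / counts.sum(), "o",
                      label=cond, color=color, alpha=0.7)
        ax.set_xlabel("degree k")
        ax.set_ylabel("P(k)")
        ax.legend()
        return ax

    def plot_path_length_histogram(self, ax=None):
        """Histogram of finite class-pair path lengths per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cond, color in (("normal", "tab:blue"), ("tumor", "tab:red")):
            lengths = [p.length for p in self.class_paths[cond] if p.finite]
            if lengths:
                ax.hist(lengths, bins=range(0, int(max(lengths)) + 2),
                        alpha=0.5, label=cond, color=color)
        ax.set_xlabel("shortest-path length (hops)")
        ax.set_ylabel("pairs")
        ax.legend()
        return ax
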