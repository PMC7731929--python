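"""Dual normal/tumor graph model and file I/O.

Holds the weighted undirected co-expression graphs for both conditions
over a shared gene namespace, the gene annotation table (UniProt
accession, description, regulatory-class flags), and writers for
edge-list TSV, Neo4j bulk-import CSV and a Cypher loader script.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .coexpression import (
    DISCARD_THRESHOLD,
    RETENTION_THRESHOLD,
    CoexpressionEdge,
    ExpressionMatrix,
)

__all__ = [
    "TF",
    "EPIGENETIC",
    "ONCOGENE",
    "GENE_CLASSES",
    "GeneAnnotationTable",
    "ConditionGraph",
    "DualGraph",
    "load_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_neo4j_csv",
    "read_neo4j_csv",
    "write_cypher_script",
]

TF = "TF"
EPIGENETIC = "EPIGENETIC"
ONCOGENE = "ONCOGENE"
GENE_CLASSES = (TF, EPIGENETIC, ONCOGENE)

_CLASS_COLUMNS = {
    TF: "is_tf",
    EPIGENETIC: "is_epigenetic_regulator",
    ONCOGENE: "is_oncogene",
}
_ANNOTATION_COLUMNS = ["gene", "uniprot", "description"] + list(
    _CLASS_COLUMNS.values()
)


class GeneAnnotationTable:
    """Per-gene annotation: UniProt accession, description and class flags."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if frame["gene"].duplicated().any():
            dupes = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene symbols in annotation: {dupes}")
        self.frame = frame.reset_index(drop=True)
        self._classes: dict[str, frozenset[str]] = {}
        for row in self.frame.itertuples(index=False):
            labels = frozenset(
                cls for cls, col in _CLASS_COLUMNS.items()
                if int(getattr(row, col))
            )
            self._classes[str(row.gene)] = labels

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.frame["gene"]]

    def classes_of(self, gene: str) -> frozenset[str]:
        return self._classes.get(gene, frozenset())

    def genes_in_class(self, cls: str) -> list[str]:
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}; expected {GENE_CLASSES}")
        return sorted(g for g, labels in self._classes.items() if cls in labels)

    def describe(self, gene: str) -> tuple[str, str]:
        row = self.frame.loc[self.frame["gene"] == gene]
        if row.empty:
            return ("", "")
        return (str(row.iloc[0]["uniprot"]), str(row.iloc[0]["description"]))

    def __contains__(self, gene: str) -> bool:
        return gene in self._classes

    def __len__(self) -> int:
        return len(self._classes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotationTable":
        frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "uniprot": str,
                                                   "description": str})
        return cls(frame)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path


class ConditionGraph:
    """Weighted undirected co-expression graph for one condition.

    Nodes are gene symbols; edges are :class:`CoexpressionEdge` stored
    with ``gene_a < gene_b``.  Extra isolated nodes (genes retained in
    the namespace but without edges) may be supplied explicitly.
    """

    def __init__(
        self,
        condition: str,
        edges: Iterable[CoexpressionEdge] = (),
        nodes: Iterable[str] = (),
    ):
        self.condition = condition
        self.edges: dict[tuple[str, str], CoexpressionEdge] = {}
        for e in edges:
            if e.key in self.edges:
                raise ValueError(f"duplicate edge {e.key}")
            self.edges[e.key] = e
        self.nodes: set[str] = set(nodes)
        for a, b in self.edges:
            self.nodes.add(a)
            self.nodes.add(b)
        self._adjacency: dict[str, dict[str, float]] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> Mapping[str, Mapping[str, float]]:
        """gene -> {neighbor: weight}; cached."""
        if self._adjacency is None:
            adj: dict[str, dict[str, float]] = {g: {} for g in self.nodes}
            for (a, b), e in self.edges.items():
                adj[a][b] = e.weight
                adj[b][a] = e.weight
            self._adjacency = adj
        return self._adjacency

    def sorted_edges(self) -> list[CoexpressionEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConditionGraph):
            return NotImplemented
        return (
            self.condition == other.condition
            and self.nodes == other.nodes
            and self.edges.keys() == other.edges.keys()
            and all(
                abs(self.edges[k].weight - other.edges[k].weight) <= 1e-12
                and abs(self.edges[k].rho - other.edges[k].rho) <= 1e-12
                for k in self.edges
            )
        )


@dataclass
class DualGraph:
    """Matched normal and tumor subnetworks plus the annotation table."""

    normal: ConditionGraph
    tumor: ConditionGraph
    annotations: GeneAnnotationTable

    def __post_init__(self) -> None:
        if self.normal.condition != "normal" or self.tumor.condition != "tumor":
            raise ValueError(
                "DualGraph requires one 'normal' and one 'tumor' subnetwork"
            )

    @property
    def all_nodes(self) -> set[str]:
        return self.normal.nodes | self.tumor.nodes

    def graph(self, condition: str) -> ConditionGraph:
        if condition == "normal":
            return self.normal
        if condition == "tumor":
            return self.tumor
        raise ValueError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, condition: str = "normal") -> ExpressionMatrix:
    """Read an expression TSV (first column gene symbol, one column per sample).

    Raises ``ValueError`` naming the offending gene/line for duplicate
    genes, negative values or malformed headers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.name is None or frame.shape[1] == 0:
        raise ValueError(f"{path}: malformed header (expected gene column + samples)")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene row(s): {dupes}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    import numpy as np

    bad = np.argwhere(values < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: negative value at gene {frame.index[r]!r} "
            f"(row {r + 2}), sample {frame.columns[c]!r}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame, condition=condition)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = expr.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Edge-list TSV
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["gene_a", "gene_b", "rho", "weight", "condition"]


def write_edge_list(graph: ConditionGraph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in graph.sorted_edges():
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.rho!r}\t{e.weight!r}\t"
                f"{graph.condition}\n"
            )
    return path


def read_edge_list(path: str | Path) -> ConditionGraph:
    """Read an edge-list TSV back into a :class:`ConditionGraph`.

    Rows violating the edge invariants (self-loop, weight not above the
    retention threshold, |rho| above the discard threshold) are rejected
    with a ``ValueError`` naming the line.
    """
    path = Path(path)
    edges: list[CoexpressionEdge] = []
    condition: str | None = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise ValueError(f"{path}: malformed edge-list header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            a, b, rho_s, weight_s, cond = parts
            try:
                rho, weight = float(rho_s), float(weight_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric edge value") from exc
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            if not weight > RETENTION_THRESHOLD:
                raise ValueError(
                    f"{path}:{lineno}: weight {weight} not above retention "
                    f"threshold {RETENTION_THRESHOLD}"
                )
            if abs(rho) > DISCARD_THRESHOLD:
                raise ValueError(
                    f"{path}:{lineno}: |rho| {abs(rho)} above discard threshold"
                )
            if condition is None:
                condition = cond
            elif cond != condition:
                raise ValueError(f"{path}:{lineno}: mixed conditions in edge list")
            try:
                edges.append(CoexpressionEdge.from_rho(a, b, rho))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return ConditionGraph(condition or "normal", edges)


# ---------------------------------------------------------------------------
# Neo4j bulk import CSV + Cypher
# ---------------------------------------------------------------------------

_NODE_HEADER = ["geneId:ID", "name", "uniprot", "description", ":LABEL"]
_REL_HEADER = [":START_ID", ":END_ID", "weight:double", "rho:double", ":TYPE"]
_REL_TYPES = {"normal": "COEXP_NORMAL", "tumor": "COEXP_TUMOR"}


def _node_labels(annotations: GeneAnnotationTable, gene: str) -> str:
    labels = ["Gene"] + [c for c in GENE_CLASSES if c in annotations.classes_of(gene)]
    return ";".join(labels)


def write_neo4j_csv(dual: DualGraph, directory: str | Path) -> tuple[Path, Path]:
    """Emit bulk-import CSV files (nodes.csv, relationships.csv).

    One node row per gene in the union of both subnetworks; condition is
    encoded in the relationship type (COEXP_NORMAL / COEXP_TUMOR).
    RFC-4180 quoting; deterministic gene-sorted order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes_path = directory / "nodes.csv"
    rels_path = directory / "relationships.csv"

    with open(nodes_path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(_NODE_HEADER)
        for gene in sorted(dual.all_nodes):
            uniprot, description = dual.annotations.describe(gene)
            writer.writerow(
                [gene, gene, uniprot, description, _node_labels(dual.annotations, gene)]
            )

    with open(rels_path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(_REL_HEADER)
        for condition in ("normal", "tumor"):
            graph = dual.graph(condition)
            for e in graph.sorted_edges():
                writer.writerow(
                    [e.gene_a, e.gene_b, repr(e.weight), repr(e.rho),
                     _REL_TYPES[condition]]
                )
    return nodes_path, rels_path


def read_neo4j_csv(
    directory: str | Path, annotations: GeneAnnotationTable | None = None
) -> DualGraph:
    """Parse bulk-import CSVs back into a :class:`DualGraph` (round-trip check)."""
    directory = Path(directory)
    with open(directory / "nodes.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _NODE_HEADER:
            raise ValueError(f"unexpected nodes header {header}")
        rows = list(reader)
    if annotations is None:
        frame = pd.DataFrame(
            {
                "gene": [r[0] for r in rows],
                "uniprot": [r[2] for r in rows],
                "description": [r[3] for r in rows],
                "is_tf": [int(TF in r[4].split(";")) for r in rows],
                "is_epigenetic_regulator": [
                    int(EPIGENETIC in r[4].split(";")) for r in rows
                ],
                "is_oncogene": [int(ONCOGENE in r[4].split(";")) for r in rows],
            }
        )
        annotations = GeneAnnotationTable(frame)

    edges: dict[str, list[CoexpressionEdge]] = {"normal": [], "tumor": []}
    rev_types = {v: k for k, v in _REL_TYPES.items()}
    with open(directory / "relationships.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _REL_HEADER:
            raise ValueError(f"unexpected relationships header {header}")
        for a, b, weight, rho, rel_type in reader:
            condition = rev_types[rel_type]
            edges[condition].append(
                CoexpressionEdge.from_rho(a, b, float(rho))
            )
    return DualGraph(
        ConditionGraph("normal", edges["normal"]),
        ConditionGraph("tumor", edges["tumor"]),
        annotations,
    )


def _cypher_quote(text: str) -> str:
    return "'" + text.replace("\\", "\\\\").replace("'", "\\'") + "'"


def write_cypher_script(dual: DualGraph, path: str | Path) -> Path:
    """Emit a Cypher script that reconstructs the dual graph in a graph database.

    Deterministic (gene-sorted); node statements carry name/uniprot/
    description properties and class labels, relationship statements
    carry weight and rho properties typed by condition.
    """
    path = Path(path)
    lines = [
        "// Co-expression dual graph loader",
        "CREATE CONSTRAINT gene_id IF NOT EXISTS "
        "FOR (g:Gene) REQUIRE g.geneId IS UNIQUE;",
    ]
    for gene in sorted(dual.all_nodes):
        uniprot, description = dual.annotations.describe(gene)
        labels = ":".join(
            ["Gene"]
            + [c for c in GENE_CLASSES if c in dual.annotations.classes_of(gene)]
        )
        lines.append(
            f"CREATE (:{labels} {{geneId: {_cypher_quote(gene)}, "
            f"name: {_cypher_quote(gene)}, uniprot: {_cypher_quote(uniprot)}, "
            f"description: {_cypher_quote(description)}}});"
        )
    for condition in ("normal", "tumor"):
        rel = _REL_TYPES[condition]
        for e in dual.graph(condition).sorted_edges():
            lines.append(
                f"MATCH (a:Gene {{geneId: {_cypher_quote(e.gene_a)}}}), "
                f"(b:Gene {{geneId: {_cypher_quote(e.gene_b)}}}) "
                f"CREATE (a)-[:{rel} {{weight: {e.weight!r}, rho: {e.rho!r}}}]->(b);"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
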