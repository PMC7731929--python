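"""End-to-end pipeline orchestration with config, seeds and a run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .algorithms import DEFAULT_DAMPING
from .coexpression import DISCARD_THRESHOLD, RETENTION_THRESHOLD, SOFT_POWER
from .enrichment import enrich_communities, read_gmt
from .graph import (
    write_cypher_script,
    write_edge_list,
    write_neo4j_csv,
)
from .model import DifferentialCoexpressionModel
from .synthetic import SyntheticConfig, generate_dataset, write_fixture

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``synthetic`` is set (simulate a cohort) or the three input
    paths point at expression TSVs and an annotation table.  Thresholds
    default to the edge rules and scoring conventions of the analysis:
    power 6, retention 0.25, discard 0.99, damping 0.85, community
    minimum size 50.
    """

    output_dir: str | Path = "coexnet_run"
    synthetic: SyntheticConfig | None = None
    normal_path: str | None = None
    tumor_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    power: int = SOFT_POWER
    retention: float = RETENTION_THRESHOLD
    discard: float = DISCARD_THRESHOLD
    damping: float = DEFAULT_DAMPING
    min_community: int = 50
    path_mode: str = "hops"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.retention < 1) or not (0 < self.discard < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.power < 1 or int(self.power) != self.power:
            raise ValueError("power must be a positive integer")
        if self.path_mode not in ("hops", "inverse_weight"):
            raise ValueError(f"unknown path mode {self.path_mode!r}")
        if self.synthetic is None:
            for name in ("normal_path", "tumor_path", "annotation_path"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"{name} required when no synthetic config")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{name}: no such file {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        synth = payload.pop("synthetic", None)
        config = cls(**payload)
        if synth is not None:
            if "modules" in synth:
                synth["modules"] = tuple(tuple(m) for m in synth["modules"])
            if "class_fractions" in synth:
                synth["class_fractions"] = tuple(synth["class_fractions"])
            config.synthetic = SyntheticConfig(**synth)
        return config


def _config_payload(config: RunConfig) -> dict:
    payload = asdict(config)
    payload["output_dir"] = str(payload["output_dir"])
    if config.synthetic is not None:
        payload["synthetic"]["modules"] = [
            list(m) for m in config.synthetic.modules
        ]
        payload["synthetic"]["class_fractions"] = list(
            config.synthetic.class_fractions
        )
    return payload


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> build -> analyze -> compare -> enrich -> export.

    Writes every table and graph artifact under ``config.output_dir``
    plus a ``manifest.json`` recording the configuration, seed, package
    version and per-stage row counts.  Rerunning with the same config
    and seed reproduces identical artifacts (manifest timestamps aside).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_payload(config),
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "artifacts": {},
    }
    stage = "simulate" if config.synthetic is not None else "load"
    try:
        gene_sets = None
        if config.synthetic is not None:
            synth = config.synthetic
            if synth.seed != config.seed:
                synth = SyntheticConfig(**{**asdict(synth), "seed": config.seed})
            dataset = generate_dataset(synth)
            fixture_dir = outdir / "input"
            paths = write_fixture(dataset, fixture_dir)
            manifest["artifacts"]["input"] = {
                k: str(v) for k, v in paths.items()
            }
            model = DifferentialCoexpressionModel(
                dataset.normal, dataset.tumor, dataset.annotation,
                power=config.power, retention=config.retention,
                discard=config.discard, damping=config.damping,
                min_community_size=config.min_community,
                path_mode=config.path_mode,
            )
            gene_sets = dataset.gene_sets
            manifest["stages"][stage] = {
                "n_genes": dataset.normal.n_genes,
                "n_samples": dataset.normal.n_samples,
            }
        else:
            model = DifferentialCoexpressionModel.from_tsv(
                config.normal_path, config.tumor_path, config.annotation_path,
                power=config.power, retention=config.retention,
                discard=config.discard, damping=config.damping,
                min_community_size=config.min_community,
                path_mode=config.path_mode,
            )
            if config.gmt_path:
                gene_sets = read_gmt(
                    config.gmt_path, universe=model.annotations.genes
                )
            manifest["stages"][stage] = {
                "n_genes": model.normal.n_genes,
                "n_samples": model.normal.n_samples,
            }

        stage = "build"
        results = model.fit(seed=config.seed)
        dual = results.dual
        for cond in ("normal", "tumor"):
            path = outdir / f"edges_{cond}.tsv"
            write_edge_list(dual.graph(cond), path)
            manifest["artifacts"][f"edges_{cond}"] = str(path)
        manifest["stages"]["build"] = {
            "nodes_normal": dual.normal.n_nodes,
            "edges_normal": dual.normal.n_edges,
            "nodes_tumor": dual.tumor.n_nodes,
            "edges_tumor": dual.tumor.n_edges,
        }

        stage = "analyze"
        centrality_path = outdir / "centrality.tsv"
        results.centrality.to_csv(centrality_path, sep="\t", float_format="%.10g")
        manifest["artifacts"]["centrality"] = str(centrality_path)
        community_rows = []
        for cond, part in results.partitions.items():
            for gene, cid in sorted(part.assignment.items()):
                community_rows.append(
                    {"gene": gene, "community": cid, "condition": cond}
                )
        communities_path = outdir / "communities.tsv"
        pd.DataFrame(
            community_rows, columns=["gene", "community", "condition"]
        ).to_csv(communities_path, sep="\t", index=False)
        manifest["artifacts"]["communities"] = str(communities_path)
        paths_path = outdir / "class_paths.tsv"
        with open(paths_path, "w") as fh:
            fh.write("source\ttarget\tcondition\tlength\n")
            for cond in ("normal", "tumor"):
                for p in results.class_paths[cond]:
                    length = "inf" if not p.finite else f"{p.length:g}"
                    fh.write(f"{p.source}\t{p.target}\t{cond}\t{length}\n")
        manifest["artifacts"]["class_paths"] = str(paths_path)
        manifest["stages"]["analyze"] = {
            "centrality_rows": len(results.centrality),
            "communities": {
                cond: len(part.sizes())
                for cond, part in results.partitions.items()
            },
            "class_pairs": len(results.class_paths["normal"]),
        }

        stage = "compare"
        report_path = outdir / "differential_report.txt"
        report_path.write_text(results.report.to_text())
        manifest["artifacts"]["differential_report"] = str(report_path)
        changes_path = outdir / "community_degree_change.tsv"
        results.report.community_degree_changes.to_csv(
            changes_path, sep="\t", index=False
        )
        manifest["artifacts"]["community_degree_change"] = str(changes_path)
        manifest["stages"]["compare"] = {
            "node_fold": results.report.node_fold,
            "edge_fold": results.report.edge_fold,
        }

        stage = "enrich"
        if gene_sets is not None and "tumor" in results.partitions:
            enr = enrich_communities(
                results.partitions["tumor"], gene_sets,
                universe=model.annotations.genes,
                min_size=config.min_community,
            )
            enr_path = outdir / "enrichment.tsv"
            enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
            manifest["artifacts"]["enrichment"] = str(enr_path)
            manifest["stages"]["enrich"] = {"rows": len(enr)}
        else:
            manifest["stages"]["enrich"] = {"skipped": True}

        stage = "export"
        nodes_path, rels_path = write_neo4j_csv(dual, outdir / "neo4j")
        cypher_path = write_cypher_script(dual, outdir / "load_graph.cypher")
        manifest["artifacts"]["neo4j_nodes"] = str(nodes_path)
        manifest["artifacts"]["neo4j_relationships"] = str(rels_path)
        manifest["artifacts"]["cypher"] = str(cypher_path)
        manifest["stages"]["export"] = {
            "node_rows": len(dual.all_nodes),
            "relationship_rows": dual.normal.n_edges + dual.tumor.n_edges,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
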