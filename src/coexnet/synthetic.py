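"""Synthetic matched normal/tumor expression data with planted structure.

Emulates paired-cohort bulk RNA-seq expression matrices (FPKM-like,
non-negative, right-skewed) in which co-expression modules, regulatory
gene classes, and tumor-specific network perturbations are all known by
construction, so every downstream stage of the pipeline can be tested
for parameter recovery without external data.

Generative model
----------------
Expression is log-normal around a latent-factor structure.  A gene ``g``
in module ``m`` with loading ``a`` has

    log x[g, s] = a * f_m[s] + (1 - a) * noise_sd * eps[g, s]

with the module factor ``f_m`` and idiosyncratic noise ``eps`` drawn as
independent standard normals per sample.  Background genes are pure
noise.  Because Spearman correlation is invariant to the exponential
transform, the within-module rank correlation is analytically
controlled by ``a`` and ``noise_sd``.

The tumor matrix redraws all latent variables and applies three planted
perturbations mirroring the phenomena observed in tumor co-expression
networks: *module dissolution* (a fraction of modules become background
noise, collapsing nodes and edges), *rewiring* (a fraction of intact-
module genes follow a different module's factor), and *gained hubs*
(background genes acquire tumor-only connectivity through a shared
tumor-specific expression program with graded activation, producing a
connected band-like tumor-only subnetwork).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .enrichment import GeneSetCollection, read_gmt, write_gmt
from .graph import (
    EPIGENETIC,
    ONCOGENE,
    TF,
    GeneAnnotationTable,
    load_expression,
    write_expression,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_fixture",
    "read_fixture",
]

_DEFAULT_MODULES = ((40, 0.92),) * 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a matched normal/tumor cohort at desk scale:
    2,000 genes x 60 paired samples with five 40-gene co-expression
    modules at loading 0.92 (within-module Spearman ~0.97, inside the
    soft-threshold retention band), of which 40% dissolve in the tumor;
    10% of intact-module genes rewire and 30 background genes become
    tumor-only hubs.  Class fractions enrich regulatory classes relative
    to the genome so class-pair statistics are well populated at this
    gene count.
    """

    n_genes: int = 2000
    n_samples: int = 60
    modules: tuple[tuple[int, float], ...] = _DEFAULT_MODULES
    dissolve_fraction: float = 0.4
    rewire_fraction: float = 0.1
    gained_hub_count: int = 30
    class_fractions: tuple[float, float, float] = (0.08, 0.10, 0.10)
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("invalid config: n_genes must be positive")
        if self.n_samples < 3:
            raise ValueError("invalid config: n_samples must be at least 3")
        total = sum(size for size, _ in self.modules)
        if total > self.n_genes:
            raise ValueError(
                "invalid config: sum of module sizes exceeds n_genes "
                f"({total} > {self.n_genes})"
            )
        for size, loading in self.modules:
            if size < 2:
                raise ValueError("invalid config: module size must be >= 2")
            if not 0.0 <= loading < 1.0:
                raise ValueError(
                    "invalid config: loading must lie in [0, 1) "
                    "(loading = 1 would force |rho| > 0.99 and every module "
                    "edge would be discarded)"
                )
        for name in ("dissolve_fraction", "rewire_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"invalid config: {name} must lie in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.class_fractions):
            raise ValueError("invalid config: class fractions must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("invalid config: noise_sd must be positive")
        if self.gained_hub_count < 0:
            raise ValueError("invalid config: gained_hub_count must be >= 0")
        n_background = self.n_genes - total
        if self.gained_hub_count > n_background:
            raise ValueError(
                "invalid config: gained_hub_count exceeds background gene count "
                f"({self.gained_hub_count} > {n_background})"
            )

    @property
    def module_sizes(self) -> list[int]:
        return [size for size, _ in self.modules]

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    @property
    def background_fraction(self) -> float:
        return self.n_background / self.n_genes


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    module_assignment: dict[str, int | None]  # gene -> module id or None
    dissolved_modules: frozenset[int]
    rewired_genes: frozenset[str]
    rewire_targets: dict[str, int]  # rewired gene -> tumor module id
    gained_hubs: tuple[str, ...]  # in gradient order
    class_labels: dict[str, frozenset[str]]

    def module_genes(self, module_id: int) -> list[str]:
        return sorted(
            g for g, m in self.module_assignment.items() if m == module_id
        )

    @property
    def intact_modules(self) -> frozenset[int]:
        modules = {m for m in self.module_assignment.values() if m is not None}
        return frozenset(modules - self.dissolved_modules)


@dataclass
class SyntheticDataset:
    normal: ExpressionMatrix
    tumor: ExpressionMatrix
    annotation: GeneAnnotationTable
    truth: SyntheticTruth
    gene_sets: GeneSetCollection
    config: SyntheticConfig


def _largest_remainder(total: int, sizes: Sequence[int]) -> list[int]:
    """Allocate ``total`` across strata proportionally to ``sizes``."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.sum() == 0:
        return [0] * len(sizes)
    raw = total * sizes / sizes.sum()
    alloc = np.floor(raw).astype(int)
    remainder = total - alloc.sum()
    order = np.argsort(-(raw - alloc), kind="stable")
    for i in range(remainder):
        alloc[order[i]] += 1
    return [int(min(a, s)) for a, s in zip(alloc, sizes.astype(int))]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate matched normal/tumor matrices, annotations and gene sets.

    Deterministic given ``config.seed``: identical configs yield
    byte-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    genes = [f"GENE{i:05d}" for i in range(G)]
    samples = [f"S{j:04d}" for j in range(S)]

    # --- planted structure ------------------------------------------------
    perm = rng.permutation(G)
    module_of = np.full(G, -1, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_of[perm[pos:pos + size]] = m
        pos += size
    background_idx = perm[pos:]

    n_modules = len(config.modules)
    n_dissolved = int(round(config.dissolve_fraction * n_modules))
    dissolved = (
        frozenset(
            int(m) for m in rng.choice(n_modules, size=n_dissolved, replace=False)
        )
        if n_dissolved
        else frozenset()
    )
    intact = sorted(set(range(n_modules)) - dissolved)

    intact_gene_idx = np.array(
        [i for i in range(G) if module_of[i] in intact], dtype=int
    )
    rewired_idx: np.ndarray = np.array([], dtype=int)
    rewire_target: dict[int, int] = {}
    if len(intact) >= 2 and config.rewire_fraction > 0:
        n_rew = int(round(config.rewire_fraction * len(intact_gene_idx)))
        if n_rew:
            rewired_idx = rng.choice(intact_gene_idx, size=n_rew, replace=False)
            intact_pos = {m: k for k, m in enumerate(intact)}
            for i in rewired_idx:
                src = int(module_of[i])
                tgt = intact[(intact_pos[src] + 1) % len(intact)]
                rewire_target[int(i)] = tgt

    hubs_idx = (
        rng.choice(background_idx, size=config.gained_hub_count, replace=False)
        if config.gained_hub_count
        else np.array([], dtype=int)
    )

    # --- class labels: stratified largest-remainder allocation ------------
    strata = [np.sort(perm[sum(config.module_sizes[:m]):
                           sum(config.module_sizes[:m + 1])])
              for m in range(n_modules)]
    strata.append(np.sort(background_idx))
    strata_sizes = [len(s) for s in strata]
    class_labels: dict[str, set[str]] = {g: set() for g in genes}
    for cls, fraction in zip((TF, EPIGENETIC, ONCOGENE), config.class_fractions):
        total = int(round(fraction * G))
        for stratum, quota in zip(strata, _largest_remainder(total, strata_sizes)):
            if quota:
                chosen = rng.choice(stratum, size=quota, replace=False)
                for i in chosen:
                    class_labels[genes[int(i)]].add(cls)

    # --- expression matrices ----------------------------------------------
    loadings = np.array([a for _, a in config.modules], dtype=float)
    hub_loading = float(loadings.mean()) if len(loadings) else 0.9
    sd = config.noise_sd

    def _matrix(condition: str) -> np.ndarray:
        factors = rng.standard_normal((max(n_modules, 1), S))
        eps = rng.standard_normal((G, S))
        log_x = np.empty((G, S))
        if condition == "normal":
            for i in range(G):
                m = module_of[i]
                if m >= 0:
                    a = loadings[m]
                    log_x[i] = a * factors[m] + (1 - a) * sd * eps[i]
                else:
                    log_x[i] = eps[i]
        else:
            h = rng.standard_normal((2, S))  # tumor-only program factors
            hub_rank = {int(i): r for r, i in enumerate(hubs_idx)}
            n_hubs = len(hubs_idx)
            for i in range(G):
                m = module_of[i]
                if i in hub_rank:
                    theta = (
                        np.pi * hub_rank[i] / (n_hubs - 1) if n_hubs > 1 else 0.0
                    )
                    program = np.cos(theta) * h[0] + np.sin(theta) * h[1]
                    log_x[i] = (
                        hub_loading * program + (1 - hub_loading) * sd * eps[i]
                    )
                elif int(i) in rewire_target:
                    tgt = rewire_target[int(i)]
                    a = loadings[tgt]
                    log_x[i] = a * factors[tgt] + (1 - a) * sd * eps[i]
                elif m >= 0 and m not in dissolved:
                    a = loadings[m]
                    log_x[i] = a * factors[m] + (1 - a) * sd * eps[i]
                else:  # background or dissolved-module gene: pure noise
                    log_x[i] = eps[i]
        return np.exp(log_x)

    normal = ExpressionMatrix(
        pd.DataFrame(_matrix("normal"), index=genes, columns=samples), "normal"
    )
    tumor = ExpressionMatrix(
        pd.DataFrame(_matrix("tumor"), index=genes, columns=samples), "tumor"
    )

    # --- annotation table ---------------------------------------------------
    frame = pd.DataFrame(
        {
            "gene": genes,
            "uniprot": [f"P{i:05d}" for i in range(G)],
            "description": [
                f"synthetic gene {i}, "
                + (f"module {module_of[i]}" if module_of[i] >= 0 else "background")
                for i in range(G)
            ],
            "is_tf": [int(TF in class_labels[g]) for g in genes],
            "is_epigenetic_regulator": [
                int(EPIGENETIC in class_labels[g]) for g in genes
            ],
            "is_oncogene": [int(ONCOGENE in class_labels[g]) for g in genes],
        }
    )
    annotation = GeneAnnotationTable(frame)

    truth = SyntheticTruth(
        module_assignment={
            genes[i]: (int(module_of[i]) if module_of[i] >= 0 else None)
            for i in range(G)
        },
        dissolved_modules=dissolved,
        rewired_genes=frozenset(genes[int(i)] for i in rewired_idx),
        rewire_targets={genes[i]: t for i, t in rewire_target.items()},
        gained_hubs=tuple(genes[int(i)] for i in hubs_idx),
        class_labels={g: frozenset(v) for g, v in class_labels.items()},
    )

    # --- gene sets: one per planted module plus random decoys ---------------
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for m in range(n_modules):
        sets[f"MODULE_{m:02d}"] = (
            f"planted co-expression module {m}",
            frozenset(truth.module_genes(m)),
        )
    decoy_size = int(np.median(config.module_sizes)) if n_modules else 40
    decoy_size = min(decoy_size, G)
    for d in range(10):
        members = rng.choice(G, size=decoy_size, replace=False)
        sets[f"DECOY_{d:02d}"] = (
            f"random decoy set {d}",
            frozenset(genes[int(i)] for i in members),
        )
    gene_sets = GeneSetCollection(sets, frozenset(genes))

    return SyntheticDataset(normal, tumor, annotation, truth, gene_sets, config)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write all dataset artifacts to ``directory``; returns the paths.

    Emits expression TSVs, the annotation table, a GMT collection (one
    set per planted module plus decoys) and a JSON ground-truth file.
    Re-reading with :func:`read_fixture` reproduces the dataset exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "normal": write_expression(dataset.normal, directory / "expression_normal.tsv"),
        "tumor": write_expression(dataset.tumor, directory / "expression_tumor.tsv"),
        "annotation": dataset.annotation.to_tsv(directory / "annotation.tsv"),
        "gene_sets": write_gmt(dataset.gene_sets, directory / "gene_sets.gmt"),
    }
    truth = dataset.truth
    payload = {
        "module_assignment": {
            g: m for g, m in sorted(truth.module_assignment.items())
        },
        "dissolved_modules": sorted(truth.dissolved_modules),
        "rewired_genes": sorted(truth.rewired_genes),
        "rewire_targets": dict(sorted(truth.rewire_targets.items())),
        "gained_hubs": list(truth.gained_hubs),
        "class_labels": {
            g: sorted(v) for g, v in sorted(truth.class_labels.items())
        },
        "config": {
            "n_genes": dataset.config.n_genes,
            "n_samples": dataset.config.n_samples,
            "modules": [list(m) for m in dataset.config.modules],
            "dissolve_fraction": dataset.config.dissolve_fraction,
            "rewire_fraction": dataset.config.rewire_fraction,
            "gained_hub_count": dataset.config.gained_hub_count,
            "class_fractions": list(dataset.config.class_fractions),
            "noise_sd": dataset.config.noise_sd,
            "seed": dataset.config.seed,
        },
    }
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Load a dataset previously written by :func:`write_fixture`."""
    directory = Path(directory)
    payload = json.loads((directory / "truth.json").read_text())
    cfg = payload["config"]
    config = SyntheticConfig(
        n_genes=cfg["n_genes"],
        n_samples=cfg["n_samples"],
        modules=tuple((int(s), float(a)) for s, a in cfg["modules"]),
        dissolve_fraction=cfg["dissolve_fraction"],
        rewire_fraction=cfg["rewire_fraction"],
        gained_hub_count=cfg["gained_hub_count"],
        class_fractions=tuple(cfg["class_fractions"]),
        noise_sd=cfg["noise_sd"],
        seed=cfg["seed"],
    )
    truth = SyntheticTruth(
        module_assignment={
            g: (int(m) if m is not None else None)
            for g, m in payload["module_assignment"].items()
        },
        dissolved_modules=frozenset(payload["dissolved_modules"]),
        rewired_genes=frozenset(payload["rewired_genes"]),
        rewire_targets={g: int(t) for g, t in payload["rewire_targets"].items()},
        gained_hubs=tuple(payload["gained_hubs"]),
        class_labels={
            g: frozenset(v) for g, v in payload["class_labels"].items()
        },
    )
    annotation = GeneAnnotationTable.from_tsv(directory / "annotation.tsv")
    gene_sets = read_gmt(directory / "gene_sets.gmt", universe=annotation.genes)
    return SyntheticDataset(
        normal=load_expression(directory / "expression_normal.tsv", "normal"),
        tumor=load_expression(directory / "expression_tumor.tsv", "tumor"),
        annotation=annotation,
        truth=truth,
        gene_sets=gene_sets,
        config=config,
    )
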