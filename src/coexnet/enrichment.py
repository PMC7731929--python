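"""Hypergeometric over-representation of gene sets with BH correction.

Communities (or arbitrary gene lists) are tested for over-representation
of each gene set in a GMT collection.  Community membership is unranked,
so the statistic is the upper-tail hypergeometric probability
``P(X >= k)`` of drawing ``k`` set members in a query of size ``n`` from
a universe of ``N`` genes containing ``K`` set members.  P-values are
adjusted per query with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .algorithms import CommunityPartition

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "bh_adjust",
    "enrich_gene_list",
    "enrich_communities",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are defined over."""

    sets: dict[str, tuple[str, frozenset[str]]]  # name -> (description, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        members = set().union(*(m for _, m in self.sets.values())) \
            if self.sets else set()
        if not members <= self.universe:
            self.universe = frozenset(self.universe | members)

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect all sets and the universe with an analysis namespace."""
        uni = frozenset(universe) & self.universe
        sets = {
            name: (desc, members & uni)
            for name, (desc, members) in self.sets.items()
        }
        return GeneSetCollection(sets, uni)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (per line: set name, description, member genes).

    Duplicate members within a line are stored once.  ``universe``
    optionally widens the collection universe beyond the union of set
    members (e.g. to the full measured gene namespace).
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (description, frozenset(m for m in members if m))
    uni = frozenset(universe) if universe is not None else frozenset()
    return GeneSetCollection(sets, uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            description, members = collection.sets[name]
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts set members among ``n`` query genes drawn without
    replacement from a universe of ``N`` genes of which ``K`` belong to
    the set.  Requires ``0 <= k <= min(n, K) <= N``.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_RESULT_COLUMNS = [
    "query", "set", "k", "n", "K", "N", "p_value", "q_value",
]


def enrich_gene_list(
    name: str,
    genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of every collection set in one gene list.

    The effective universe is the intersection of the analysis namespace
    (``universe``, defaulting to the collection universe) with the
    collection universe; query and sets are restricted to it.  BH
    adjustment is applied across the collection's sets.
    """
    restricted = (
        collection.restricted(universe) if universe is not None else collection
    )
    uni = restricted.universe
    if not uni:
        raise ValueError("empty universe intersection")
    query = frozenset(genes) & uni
    rows = []
    for set_name in sorted(restricted.sets):
        _, members = restricted.sets[set_name]
        rows.append(
            {
                "query": name,
                "set": set_name,
                "k": len(query & members),
                "n": len(query),
                "K": len(members),
                "N": len(uni),
            }
        )
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS[:-2])
    frame["p_value"] = [
        hypergeometric_test(r.k, r.n, r.K, r.N) for r in frame.itertuples()
    ]
    frame["q_value"] = bh_adjust(frame["p_value"]) if len(frame) else []
    return frame.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)


def enrich_communities(
    partition: CommunityPartition,
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_size: int = 50,
) -> pd.DataFrame:
    """Over-representation analysis for every community of ``min_size`` genes.

    Each sufficiently large community is tested against every set in the
    collection; BH correction is applied per community across sets.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    frames = []
    for cid, members in sorted(partition.communities().items()):
        if len(members) < min_size:
            continue
        frames.append(
            enrich_gene_list(f"community_{cid}", members, collection, universe)
        )
    if not frames:
        return pd.DataFrame(columns=_RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
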