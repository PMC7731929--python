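"""Pairwise Spearman co-expression and soft-threshold edge construction.

Edges of the co-expression graph connect gene pairs whose expression
profiles are monotonically associated across samples.  The pipeline

1. computes the Spearman rank correlation ``rho`` for every unordered
   gene pair,
2. discards coefficients with ``|rho| > 0.99`` (in FPKM-like data these
   are artifacts of near-zero expression of both genes in nearly all
   samples),
3. soft-thresholds the survivors by raising them to the sixth power and
   keeping the pair as an edge only if ``rho**6 > 0.25``.

The retained weight ``w = rho**6`` lies in ``(0.25, 0.99**6]`` and the
even power makes strong negative correlations count as strong edges.
Algebraically an edge survives iff ``0.25**(1/6) < |rho| <= 0.99``,
i.e. ``|rho|`` in roughly ``(0.7937, 0.99]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SOFT_POWER",
    "RETENTION_THRESHOLD",
    "DISCARD_THRESHOLD",
    "ExpressionMatrix",
    "CoexpressionEdge",
    "spearman_rho",
    "soft_threshold_edge",
    "build_network",
]

logger = logging.getLogger(__name__)

#: Soft-thresholding power applied to Spearman coefficients.
SOFT_POWER = 6
#: Minimum (exclusive) powered weight for an edge to be retained.
RETENTION_THRESHOLD = 0.25
#: Maximum (inclusive) |rho|; larger magnitudes are near-zero-expression artifacts.
DISCARD_THRESHOLD = 0.99

CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values for one condition.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by unique sample
        identifiers; all values finite and non-negative (FPKM-like).
    condition : str
        Either ``"normal"`` or ``"tumor"``.
    """

    data: pd.DataFrame
    condition: str = "normal"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite (no missing values)")
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CoexpressionEdge:
    """One retained co-expression edge.

    ``gene_a < gene_b`` lexicographically; ``weight == rho**6`` lies in
    ``(0.25, 1]`` and ``|rho| <= 0.99``.  The signed coefficient is kept
    alongside the (always positive) weight.
    """

    gene_a: str
    gene_b: str
    rho: float
    weight: float
    power: int = SOFT_POWER

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop edge on {self.gene_a!r}")
        if not self.gene_a < self.gene_b:
            raise ValueError(
                f"edge endpoints must satisfy gene_a < gene_b: "
                f"{self.gene_a!r}, {self.gene_b!r}"
            )
        if abs(self.rho) > DISCARD_THRESHOLD:
            raise ValueError(f"|rho|={abs(self.rho)} exceeds discard threshold")
        if not self.weight > 0:
            raise ValueError(f"edge weight must be positive, got {self.weight}")
        if abs(self.weight - self.rho**self.power) > 1e-9:
            raise ValueError(f"weight must equal rho**{self.power}")

    @classmethod
    def from_rho(
        cls, gene_a: str, gene_b: str, rho: float, power: int = SOFT_POWER
    ) -> "CoexpressionEdge":
        a, b = sorted((gene_a, gene_b))
        return cls(a, b, float(rho), float(rho) ** power, power)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> float:
    """Spearman rank correlation of two sample vectors.

    Computed as the Pearson correlation of average (fractional) ranks,
    so ties receive their mean rank.  Returns ``nan`` for a constant
    input vector (undefined correlation; such genes are excluded
    upstream rather than raising here).

    Parameters
    ----------
    x, y : array-like
        Equal-length vectors with at least 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("at least 3 samples are required for correlation")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0.0:
        return float("nan")
    return float((sx @ sy) / denom)


def soft_threshold_edge(
    rho: float,
    power: int = SOFT_POWER,
    retention: float = RETENTION_THRESHOLD,
    discard: float = DISCARD_THRESHOLD,
) -> float | None:
    """Apply the discard and soft-threshold retention rules to one coefficient.

    Returns the edge weight ``rho**power`` if the pair is retained, else
    ``None``.  Both comparisons are strict ("above"): reject if
    ``|rho| > discard``; retain iff ``rho**power > retention``.
    """
    if not np.isfinite(rho) or abs(rho) > 1.0:
        raise ValueError(f"rho must be finite in [-1, 1], got {rho}")
    if abs(rho) > discard:
        return None
    weight = float(rho) ** power
    if weight > retention:
        return weight
    return None


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Full gene-by-gene Spearman correlation matrix.

    Genes with zero variance across samples produce ``nan`` rows/columns.
    Computed by ranking each gene's profile and taking the Pearson
    correlation of the rank matrix, which is O(G^2 * n) after ranking.
    """
    if expr.n_samples < 3:
        raise ValueError("at least 3 samples are required to build a network")
    ranks = rankdata(expr.values, axis=1).astype(float)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return pd.DataFrame(corr, index=expr.data.index, columns=expr.data.index)


def build_network(
    expr: ExpressionMatrix,
    power: int = SOFT_POWER,
    retention: float = RETENTION_THRESHOLD,
    discard: float = DISCARD_THRESHOLD,
):
    """Construct the weighted co-expression graph for one condition.

    Applies :func:`spearman_rho` to all unordered gene pairs and
    :func:`soft_threshold_edge` to each coefficient.  Genes retaining no
    edge (including constant genes, whose correlation is undefined) are
    absent from the resulting node set, matching the convention that
    only genes with at least one significant correlation count as nodes.

    Returns
    -------
    ConditionGraph
    """
    from .graph import ConditionGraph

    genes = np.array(expr.gene_ids)
    corr = correlation_matrix(expr).to_numpy()

    n_const = int(np.isnan(np.diag(corr)).sum())
    if n_const:
        logger.info(
            "excluding %d constant gene(s) with undefined correlation", n_const
        )

    absrho = np.abs(corr)
    with np.errstate(invalid="ignore"):
        mask = (absrho <= discard) & (absrho**power > retention)
    mask &= np.isfinite(corr)
    iu = np.triu_indices(len(genes), k=1)
    keep = mask[iu]
    ia, ib = iu[0][keep], iu[1][keep]

    edges = []
    for i, j in zip(ia, ib):
        a, b = genes[i], genes[j]
        rho = float(corr[i, j])
        if a > b:
            a, b = b, a
        edges.append(CoexpressionEdge(a, b, rho, rho**power, power))
    return ConditionGraph(expr.condition, edges)
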