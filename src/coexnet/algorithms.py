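"""Graph algorithms under the scoring conventions of a Neo4j-style engine.

Native implementations of the three algorithms applied to the
co-expression subnetworks:

* **PageRank** in the unnormalized per-node formulation: the fixed point
  of ``score(n) = (1 - d) + d * sum_m score(m) * w(m, n) / S(m)`` where
  ``S(m)`` is the total edge weight incident to ``m`` and each undirected
  edge acts as two directed edges.  Scores are not normalized to a
  probability distribution: an isolated node scores exactly ``1 - d``
  (0.15 at the default damping 0.85) and, absent isolated nodes, scores
  sum to the node count.
* **Louvain** two-phase weighted modularity maximization (resolution 1),
  with seeded sweep order.
* **Dijkstra** shortest paths, by default with unit cost per edge (path
  length = hop count); ``mode="inverse_weight"`` uses cost ``1/w`` so
  strong co-expression is cheap to traverse.

Plus weighted/unweighted degree and the scale-free topology diagnostic
(log-log linear fit of the binned degree distribution).
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import linregress

from .graph import ConditionGraph, DualGraph

__all__ = [
    "DEFAULT_DAMPING",
    "PathResult",
    "CommunityPartition",
    "pagerank",
    "degree",
    "modularity",
    "louvain",
    "shortest_path",
    "single_source_lengths",
    "class_pair_paths",
    "scale_free_fit",
]

logger = logging.getLogger(__name__)

DEFAULT_DAMPING = 0.85


# ---------------------------------------------------------------------------
# PageRank
# ---------------------------------------------------------------------------

def pagerank(
    graph: ConditionGraph,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> dict[str, float]:
    """Weighted PageRank, unnormalized per-node base-term convention.

    Iterates ``s <- (1 - d) + d * M s`` from the all-ones start, where
    ``M[i, j] = w(j, i) / S(j)`` distributes node ``j``'s score over its
    neighbors in proportion to edge weight.  Stops when the maximum
    absolute per-node change drops below ``tol`` or after ``max_iter``
    iterations.  Isolated nodes propagate nothing and receive exactly
    ``1 - d``.

    Returns a dict gene -> score over ``graph.nodes``.
    """
    if not 0 < damping < 1:
        raise ValueError(f"damping must lie in (0, 1), got {damping}")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    index = {g: i for i, g in enumerate(nodes)}

    rows, cols, vals = [], [], []
    strength = np.zeros(n)
    for (a, b), e in graph.edges.items():
        if not e.weight > 0:
            raise ValueError(f"non-positive edge weight on {(a, b)}")
        ia, ib = index[a], index[b]
        strength[ia] += e.weight
        strength[ib] += e.weight
        rows.extend((ia, ib))
        cols.extend((ib, ia))
        vals.extend((e.weight, e.weight))
    # column-stochastic over non-isolated source nodes
    vals = [w / strength[j] for w, j in zip(vals, cols)]
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    base = 1.0 - damping
    scores = np.ones(n)
    for _ in range(max_iter):
        new = base + damping * (M @ scores)
        delta = np.abs(new - scores).max()
        scores = new
        if delta < tol:
            break
    return {g: float(scores[i]) for g, i in index.items()}


def degree(graph: ConditionGraph, genes: Sequence[str] | None = None) -> dict[str, int]:
    """Count of incident retained edges per gene.

    ``genes`` extends the namespace: genes absent from the subnetwork
    get degree 0.
    """
    adj = graph.adjacency()
    counts = {g: len(neigh) for g, neigh in adj.items()}
    if genes is not None:
        for g in genes:
            counts.setdefault(g, 0)
    return counts


# ---------------------------------------------------------------------------
# Modularity and Louvain
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    """Gene -> community assignment with its recomputed modularity."""

    condition: str
    assignment: dict[str, int]
    modularity: float

    def communities(self) -> dict[int, list[str]]:
        groups: dict[int, list[str]] = {}
        for gene, cid in self.assignment.items():
            groups.setdefault(cid, []).append(gene)
        return {cid: sorted(members) for cid, members in groups.items()}

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.communities().items()}


def modularity(graph: ConditionGraph, assignment: Mapping[str, int]) -> float:
    """Weighted Newman modularity Q of an assignment.

    ``Q = (1/2W) * sum_ij [w_ij - k_i k_j / 2W] * delta(c_i, c_j)`` with
    weighted degrees ``k`` and total edge weight ``W``.  Requires the
    assignment to cover every node and the graph to have edges.
    """
    missing = graph.nodes - set(assignment)
    if missing:
        raise ValueError(
            f"assignment does not cover nodes: {sorted(missing)[:5]} ..."
            if len(missing) > 5
            else f"assignment does not cover nodes: {sorted(missing)}"
        )
    two_w = 0.0
    k: dict[str, float] = {g: 0.0 for g in graph.nodes}
    for (a, b), e in graph.edges.items():
        k[a] += e.weight
        k[b] += e.weight
        two_w += 2 * e.weight
    if two_w == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    intra = 0.0
    for (a, b), e in graph.edges.items():
        if assignment[a] == assignment[b]:
            intra += 2 * e.weight
    tot: dict[int, float] = {}
    for g, cid in assignment.items():
        if g in k:
            tot[cid] = tot.get(cid, 0.0) + k[g]
    return intra / two_w - sum((t / two_w) ** 2 for t in tot.values())


def _local_move(
    adj: list[dict[int, float]],
    self_w: list[float],
    two_w: float,
    rng: np.random.Generator,
    resolution: float,
    init: list[int] | None = None,
) -> list[int]:
    """One level of Louvain local moves; returns the community of each node.

    ``init`` seeds the starting partition (defaults to singletons),
    which allows node-level refinement of an aggregated solution.
    """
    n = len(adj)
    comm = list(range(n)) if init is None else list(init)
    k = [sum(adj[i].values()) + 2 * self_w[i] for i in range(n)]
    comm_tot = [0.0] * n
    members = [0] * n
    for i in range(n):
        comm_tot[comm[i]] += k[i]
        members[comm[i]] += 1
    free_ids = [c for c in range(n) if members[c] == 0]
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            i = int(i)
            ci = comm[i]
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + w
            comm_tot[ci] -= k[i]
            members[ci] -= 1
            best_c = ci
            best_gain = links.get(ci, 0.0) - resolution * k[i] * comm_tot[ci] / two_w
            # deterministic candidate order; strict improvement beyond fp noise
            for c in sorted(links):
                if c == ci:
                    continue
                gain = links[c] - resolution * k[i] * comm_tot[c] / two_w
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            # splitting off into a fresh singleton community has gain 0
            if best_gain < -1e-12 and members[ci] > 0 and free_ids:
                best_c = free_ids.pop()
            comm_tot[best_c] += k[i]
            members[best_c] += 1
            if best_c != ci:
                if members[ci] == 0:
                    free_ids.append(ci)
                comm[i] = best_c
                moved = True
    return comm


def _kl_pass(
    adj: list[dict[int, float]],
    two_w: float,
    resolution: float,
    comm: list[int],
) -> tuple[list[int], bool]:
    """One Kernighan-Lin escape pass over single-node moves.

    Applies a sequence of best single-node moves, allowing temporarily
    negative modularity gains (each node moved at most once), then keeps
    the best prefix of the sequence.  Escapes local optima that require
    relocating several nodes jointly.
    """
    n = len(adj)
    comm = list(comm)
    k = [sum(adj[i].values()) for i in range(n)]
    comm_tot: dict[int, float] = {}
    for i in range(n):
        comm_tot[comm[i]] = comm_tot.get(comm[i], 0.0) + k[i]
    fresh = max(comm_tot) + 1
    frozen = [False] * n
    moves: list[tuple[int, int, int]] = []
    gain_total = 0.0
    best_total, best_step = 0.0, -1
    patience = 30  # stop after this many steps without a new best prefix
    for step in range(n):
        if step - best_step > patience:
            break
        best_move, best_delta = None, -math.inf
        for i in range(n):
            if frozen[i]:
                continue
            ci = comm[i]
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            base = links.get(ci, 0.0) - resolution * k[i] * (
                comm_tot[ci] - k[i]
            ) / two_w
            candidates = [c for c in sorted(links) if c != ci]
            candidates.append(fresh)  # split off as a singleton
            for c in candidates:
                gain = links.get(c, 0.0) - resolution * k[i] * comm_tot.get(
                    c, 0.0
                ) / two_w - base
                if gain > best_delta + 1e-15:
                    best_move, best_delta = (i, ci, c), gain
        if best_move is None:
            break
        i, ci, c = best_move
        comm_tot[ci] -= k[i]
        comm_tot[c] = comm_tot.get(c, 0.0) + k[i]
        comm[i] = c
        if c == fresh:
            fresh += 1
        frozen[i] = True
        moves.append(best_move)
        gain_total += best_delta
        if gain_total > best_total + 1e-12:
            best_total, best_step = gain_total, step
    for i, ci, c in reversed(moves[best_step + 1:]):
        comm[i] = ci
    return comm, best_step >= 0


def louvain(
    graph: ConditionGraph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 8,
) -> CommunityPartition:
    """Two-phase Louvain community detection on edge weights.

    Local modularity-gain moves over a seeded shuffled node order
    (best-gain move, ties toward the lowest community id), followed by
    community aggregation; repeated until no move improves modularity.
    Because the greedy sweep can stall in a local optimum, the search is
    restarted ``restarts`` times: the first start is the classic
    all-singletons initialization, subsequent starts use random initial
    partitions (all derived deterministically from ``seed``), and the
    best-modularity partition is returned.  The returned Q is recomputed
    from scratch on the final assignment.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: CommunityPartition | None = None
    for r in range(restarts):
        part = _louvain_once(graph, seed + r, resolution, random_init=r > 0)
        if best is None or part.modularity > best.modularity + 1e-15:
            best = part
    return best


def _louvain_once(
    graph: ConditionGraph,
    seed: int,
    resolution: float,
    random_init: bool = False,
) -> CommunityPartition:
    if graph.n_edges == 0:
        raise ValueError("louvain requires a graph with at least one edge")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n0 = len(nodes)

    adj0: list[dict[int, float]] = [{} for _ in nodes]
    for (a, b), e in graph.edges.items():
        ia, ib = index[a], index[b]
        adj0[ia][ib] = e.weight
        adj0[ib][ia] = e.weight
    self0 = [0.0] * n0
    two_w = sum(sum(d.values()) for d in adj0)

    def _normalize(comm: list[int]) -> list[int]:
        relabel: dict[int, int] = {}
        out = []
        for c in comm:
            if c not in relabel:
                relabel[c] = len(relabel)
            out.append(relabel[c])
        return out

    if random_init:
        flat = [int(c) for c in rng.integers(0, n0, size=n0)]
        flat = [flat[i] for i in range(n0)]
    else:
        flat = list(range(n0))  # original node -> community
    while True:
        moved_any = False
        # node-level moves (initial pass / refinement of the coarse solution)
        refined = _local_move(adj0, self0, two_w, rng, resolution, init=flat)
        if refined != flat:
            moved_any = True
        flat = _normalize(refined)

        # aggregate communities into super-nodes and move those
        n_agg = max(flat) + 1
        agg_adj: list[dict[int, float]] = [{} for _ in range(n_agg)]
        agg_self = [0.0] * n_agg
        for i, d in enumerate(adj0):
            ci = flat[i]
            for j, w in d.items():
                cj = flat[j]
                if ci == cj:
                    if i < j:
                        agg_self[ci] += w
                else:
                    agg_adj[ci][cj] = agg_adj[ci].get(cj, 0.0) + w
        comm_agg = _local_move(agg_adj, agg_self, two_w, rng, resolution)
        if len(set(comm_agg)) < n_agg:
            moved_any = True
            flat = _normalize([comm_agg[c] for c in flat])
        if not moved_any:
            # escape one-move local optima before accepting convergence
            if n0 <= 2000:
                refined, improved = _kl_pass(adj0, two_w, resolution, flat)
                if improved:
                    flat = _normalize(refined)
                    continue
            break

    # renumber communities deterministically by their smallest member gene
    groups: dict[int, list[str]] = {}
    for g, m in zip(nodes, flat):
        groups.setdefault(m, []).append(g)
    order = sorted(groups, key=lambda c: min(groups[c]))
    relabel = {c: i for i, c in enumerate(order)}
    assignment = {g: relabel[m] for g, m in zip(nodes, flat)}
    q = modularity(graph, assignment)
    return CommunityPartition(graph.condition, assignment, q)


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathResult:
    """Shortest-path query result; ``length`` is ``inf`` when unreachable."""

    source: str
    target: str
    length: float
    path: tuple[str, ...] | None = None

    @property
    def finite(self) -> bool:
        return math.isfinite(self.length)


def _edge_cost(weight: float, mode: str) -> float:
    if mode == "hops":
        return 1.0
    if mode == "inverse_weight":
        return 1.0 / weight
    raise ValueError(f"unknown path mode {mode!r}")


def single_source_lengths(
    graph: ConditionGraph, source: str, mode: str = "hops"
) -> dict[str, float]:
    """Dijkstra distances from ``source`` to every reachable node."""
    adj = graph.adjacency()
    if source not in adj:
        return {}
    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v in sorted(adj[u]):
            nd = d + _edge_cost(adj[u][v], mode)
            if v not in dist or nd < dist[v] - 1e-12:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def shortest_path(
    graph: ConditionGraph, source: str, target: str, mode: str = "hops"
) -> PathResult:
    """Shortest path between two genes (which may be absent from the graph).

    Unreachable or absent endpoints yield infinite length.  Among equal-
    cost shortest paths the walk from the source greedily prefers the
    lexicographically smallest next gene, so the returned path is
    deterministic.
    """
    adj = graph.adjacency()
    if source not in adj or target not in adj:
        return PathResult(source, target, math.inf)
    if source == target:
        return PathResult(source, target, 0.0, (source,))
    from_source = single_source_lengths(graph, source, mode)
    if target not in from_source:
        return PathResult(source, target, math.inf)
    to_target = single_source_lengths(graph, target, mode)
    total = from_source[target]
    path = [source]
    u = source
    while u != target:
        nxt = None
        for v in sorted(adj[u]):
            if v not in to_target:
                continue
            cost = _edge_cost(adj[u][v], mode)
            if abs(from_source[u] + cost + to_target[v] - total) <= 1e-9:
                nxt = v
                break
        assert nxt is not None, "path reconstruction failed"
        path.append(nxt)
        u = nxt
    length = float(len(path) - 1) if mode == "hops" else total
    return PathResult(source, target, length, tuple(path))


def class_pair_paths(
    dual: DualGraph,
    class_a: str,
    class_b: str,
    mode: str = "hops",
) -> dict[str, list[PathResult]]:
    """Shortest paths between all cross-class gene pairs, per condition.

    Pairs one gene of ``class_a`` with one gene of ``class_b`` (distinct
    genes, unordered pairs deduplicated) drawn from the annotation
    namespace, and evaluates each pair in both subnetworks; absent or
    disconnected endpoints produce infinite lengths.
    """
    genes_a = dual.annotations.genes_in_class(class_a)
    genes_b = dual.annotations.genes_in_class(class_b)
    if not genes_a or not genes_b:
        logger.warning(
            "empty gene class (%s: %d genes, %s: %d genes)",
            class_a, len(genes_a), class_b, len(genes_b),
        )
        return {"normal": [], "tumor": []}
    pairs = sorted({tuple(sorted((a, b))) for a in genes_a for b in genes_b if a != b})
    sources = sorted({p[0] for p in pairs})
    results: dict[str, list[PathResult]] = {}
    for condition in ("normal", "tumor"):
        graph = dual.graph(condition)
        dist_cache = {
            s: single_source_lengths(graph, s, mode) for s in sources
        }
        out = []
        for a, b in pairs:
            d = dist_cache[a].get(b, math.inf)
            out.append(PathResult(a, b, float(d)))
        results[condition] = out
    return results


# ---------------------------------------------------------------------------
# Scale-free topology diagnostic
# ---------------------------------------------------------------------------

def scale_free_fit(graph: ConditionGraph, n_bins: int = 10) -> tuple[float, float]:
    """Log-log linear fit of the logarithmically binned degree distribution.

    Returns ``(r_squared, slope)``; a scale-free network shows high R^2
    with a negative slope.  Requires at least 5 distinct positive degree
    values.
    """
    degs = np.array([d for d in degree(graph).values() if d > 0], dtype=float)
    if np.unique(degs).size < 5:
        raise ValueError(
            "scale-free fit requires >= 5 distinct degree values, got "
            f"{np.unique(degs).size}"
        )
    edges = np.logspace(np.log10(degs.min()), np.log10(degs.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-9
    counts, _ = np.histogram(degs, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    density = counts[keep] / (widths[keep] * degs.size)
    fit = linregress(np.log10(centers[keep]), np.log10(density))
    return float(fit.rvalue**2), float(fit.slope)
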