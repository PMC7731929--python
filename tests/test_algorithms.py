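"""PageRank, Louvain/modularity, Dijkstra and the scale-free diagnostic."""

import itertools
import math

import numpy as np
import pytest

from coexnet import (
    class_pair_paths,
    degree,
    louvain,
    modularity,
    pagerank,
    scale_free_fit,
    shortest_path,
)
from coexnet.algorithms import single_source_lengths
from coexnet.graph import ConditionGraph, DualGraph

from conftest import make_annotation, make_edge, make_graph


def random_weighted_graph(rng, n, p=0.3, condition="normal"):
    """Random graph whose weights lie in the valid edge band."""
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                rho = float(rng.uniform(0.80, 0.99))
                edges.append(make_edge(f"n{i:02d}", f"n{j:02d}", rho))
    nodes = [f"n{i:02d}" for i in range(n)]
    return ConditionGraph(condition, edges, nodes=nodes)


def pagerank_linear_system(graph, damping=0.85):
    """Oracle: solve the fixed point (I - d M) s = (1 - d) 1 directly."""
    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    strength = np.zeros(n)
    for (a, b), e in graph.edges.items():
        strength[index[a]] += e.weight
        strength[index[b]] += e.weight
    for (a, b), e in graph.edges.items():
        ia, ib = index[a], index[b]
        M[ib, ia] = e.weight / strength[ia]
        M[ia, ib] = e.weight / strength[ib]
    s = np.linalg.solve(np.eye(n) - damping * M, (1 - damping) * np.ones(n))
    return {g: s[i] for g, i in index.items()}


class TestPageRank:
    def test_isolated_node_scores_base(self):
        graph = make_graph("normal", [("a", "b")], nodes=["z"])
        scores = pagerank(graph, damping=0.85)
        assert scores["z"] == pytest.approx(0.15, abs=1e-12)

    def test_single_edge_symmetric_fixed_point(self):
        graph = make_graph("normal", [("a", "b")], rho=0.9)
        scores = pagerank(graph)
        assert scores["a"] == pytest.approx(1.0, abs=1e-6)
        assert scores["b"] == pytest.approx(1.0, abs=1e-6)

    def test_three_node_path_fixed_point(self):
        # solving the 3x3 system at d=0.85: ends 0.770270..., center 1.459459...
        graph = make_graph("normal", [("a", "b"), ("b", "c")], rho=0.9)
        scores = pagerank(graph, tol=1e-12, max_iter=500)
        assert scores["a"] == pytest.approx(0.21375 / 0.2775, abs=1e-9)
        assert scores["c"] == pytest.approx(scores["a"], abs=1e-12)
        assert scores["b"] == pytest.approx(0.15 + 1.7 * scores["a"], abs=1e-9)
        assert sum(scores.values()) == pytest.approx(3.0, abs=1e-8)

    def test_matches_linear_system_oracle(self, rng):
        for _ in range(10):
            graph = random_weighted_graph(rng, int(rng.integers(5, 30)))
            scores = pagerank(graph, tol=1e-12, max_iter=1000)
            oracle = pagerank_linear_system(graph)
            for g in graph.nodes:
                assert scores[g] == pytest.approx(oracle[g], abs=1e-6)

    def test_scores_floor_and_conservation(self, rng):
        graph = random_weighted_graph(rng, 25, p=0.5)
        scores = pagerank(graph, tol=1e-10, max_iter=1000)
        assert all(s >= 0.15 - 1e-12 for s in scores.values())
        if all(len(graph.adjacency()[g]) > 0 for g in graph.nodes):
            assert sum(scores.values()) == pytest.approx(
                graph.n_nodes, rel=1e-6
            )

    def test_invalid_damping(self):
        with pytest.raises(ValueError):
            pagerank(make_graph("normal", [("a", "b")]), damping=1.0)


class TestDegree:
    def test_triangle(self):
        graph = make_graph("normal", [("a", "b"), ("b", "c"), ("a", "c")])
        assert degree(graph) == {"a": 2, "b": 2, "c": 2}

    def test_absent_gene_zero(self):
        graph = make_graph("normal", [("a", "b")])
        assert degree(graph, genes=["a", "b", "zz"])["zz"] == 0

    def test_star(self):
        graph = make_graph("normal", [("hub", leaf) for leaf in "abcde"])
        deg = degree(graph)
        assert deg["hub"] == 5
        assert all(deg[l] == 1 for l in "abcde")


def set_partitions(items):
    """All partitions of a list (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1:]
        yield [[first]] + partition


def best_partition_bruteforce(graph):
    best_q, best = -math.inf, None
    nodes = sorted(graph.nodes)
    for partition in set_partitions(nodes):
        assignment = {g: i for i, block in enumerate(partition) for g in block}
        q = modularity(graph, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return best_q, best


class TestModularity:
    def test_two_node_singletons(self):
        graph = make_graph("normal", [("a", "b")], rho=0.9)
        # W equals the single weight; singleton partition: Q = -1/2
        assert modularity(graph, {"a": 0, "b": 1}) == pytest.approx(-0.5)

    def test_two_triangles_with_bridge(self):
        graph = make_graph(
            "normal",
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")],
            rho=0.9,
        )
        part = {g: 0 if g in "abc" else 1 for g in "abcdef"}
        expected = 2 * (3 / 7 - (7 / 14) ** 2)
        assert modularity(graph, part) == pytest.approx(expected, abs=1e-12)

    def test_incomplete_assignment_raises(self):
        graph = make_graph("normal", [("a", "b")])
        with pytest.raises(ValueError):
            modularity(graph, {"a": 0})

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            modularity(ConditionGraph("normal", [], nodes=["a"]), {"a": 0})


class TestLouvain:
    def test_disjoint_triangles_found(self):
        graph = make_graph(
            "normal",
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f")],
        )
        part = louvain(graph, seed=3)
        assert len(part.sizes()) == 2
        communities = {frozenset(m) for m in part.communities().values()}
        assert communities == {frozenset("abc"), frozenset("def")}

    def test_bridged_triangles_partition_and_q(self):
        graph = make_graph(
            "normal",
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")],
            rho=0.9,
        )
        part = louvain(graph, seed=0)
        assert {frozenset(m) for m in part.communities().values()} == {
            frozenset("abc"), frozenset("def")
        }
        assert part.modularity == pytest.approx(2 * (3 / 7 - 0.25), abs=1e-12)

    def test_single_clique_stays_together(self):
        pairs = list(itertools.combinations("abcde", 2))
        graph = make_graph("normal", pairs)
        part = louvain(graph, seed=1)
        assert len(part.sizes()) == 1
        # exhaustive search confirms no split improves Q
        q_opt, _ = best_partition_bruteforce(graph)
        assert part.modularity == pytest.approx(q_opt, abs=1e-12)

    def test_q_equals_recomputed_modularity(self, rng):
        for _ in range(5):
            graph = random_weighted_graph(rng, 15, p=0.3)
            if graph.n_edges == 0:
                continue
            part = louvain(graph, seed=9)
            assert part.modularity == modularity(graph, part.assignment)

    def test_planted_cliques_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        edges = []
        truth = {}
        for c, names in enumerate(("abcdefg", "hijklmn")):
            for g in names:
                truth[g] = c
            edges += [(a, b) for a, b in itertools.combinations(names, 2)]
        edges.append(("g", "h"))  # single bridge
        part = louvain(make_graph("normal", edges), seed=4)
        genes = sorted(truth)
        ari = adjusted_rand_score(
            [truth[g] for g in genes], [part.assignment[g] for g in genes]
        )
        assert ari == 1.0

    def test_no_edges_raises(self):
        with pytest.raises(ValueError):
            louvain(ConditionGraph("normal", [], nodes=["a"]))

    def test_deterministic_given_seed(self, rng):
        graph = random_weighted_graph(rng, 20, p=0.3)
        p1 = louvain(graph, seed=11)
        p2 = louvain(graph, seed=11)
        assert p1.assignment == p2.assignment


def enumerate_shortest(graph, source, target, mode="hops"):
    """Oracle: exhaustive simple-path enumeration."""
    adj = graph.adjacency()
    if source not in adj or target not in adj:
        return math.inf
    best = math.inf

    def walk(u, cost, visited):
        nonlocal best
        if u == target:
            best = min(best, cost)
            return
        for v, w in adj[u].items():
            if v not in visited:
                step = 1.0 if mode == "hops" else 1.0 / w
                if cost + step < best:
                    walk(v, cost + step, visited | {v})

    walk(source, 0.0, {source})
    return best


class TestDijkstra:
    def test_source_equals_target(self):
        graph = make_graph("normal", [("a", "b")])
        result = shortest_path(graph, "a", "a")
        assert result.length == 0 and result.path == ("a",)

    def test_disconnected_pair_infinite(self):
        graph = make_graph("normal", [("a", "b"), ("c", "d")])
        assert math.isinf(shortest_path(graph, "a", "c").length)

    def test_absent_endpoint_infinite(self):
        graph = make_graph("normal", [("a", "b")])
        assert math.isinf(shortest_path(graph, "a", "zz").length)

    def test_prefers_shorter_route(self):
        # 2-hop route a-c-e beats the 3-hop route a-b-d-e
        graph = make_graph(
            "normal",
            [("a", "c"), ("c", "e"), ("a", "b"), ("b", "d"), ("d", "e")],
        )
        result = shortest_path(graph, "a", "e")
        assert result.length == 2
        assert result.path == ("a", "c", "e")
        assert enumerate_shortest(graph, "a", "e") == 2

    def test_lexicographic_tie_break(self):
        # two 2-hop routes a-b-z and a-c-z: path goes through b
        graph = make_graph("normal", [("a", "b"), ("b", "z"),
                                      ("a", "c"), ("c", "z")])
        assert shortest_path(graph, "a", "z").path == ("a", "b", "z")

    @pytest.mark.parametrize("mode", ["hops", "inverse_weight"])
    def test_matches_enumeration_oracle(self, mode, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            graph = random_weighted_graph(rng, n, p=0.35)
            nodes = sorted(graph.nodes)
            src, tgt = rng.choice(nodes, size=2, replace=False)
            result = shortest_path(graph, str(src), str(tgt), mode=mode)
            expected = enumerate_shortest(graph, str(src), str(tgt), mode)
            if math.isinf(expected):
                assert math.isinf(result.length)
            else:
                assert result.length == pytest.approx(expected, abs=1e-9)
                # path is consistent with its length
                if mode == "hops":
                    assert len(result.path) - 1 == result.length

    def test_single_source_matches_pairwise(self, rng):
        graph = random_weighted_graph(rng, 12, p=0.3)
        nodes = sorted(graph.nodes)
        lengths = single_source_lengths(graph, nodes[0])
        for tgt in nodes[1:]:
            expected = shortest_path(graph, nodes[0], tgt).length
            got = lengths.get(tgt, math.inf)
            assert got == expected or (math.isinf(got) and math.isinf(expected))


class TestClassPairPaths:
    def test_adjacent_pair_length_one(self):
        normal = make_graph("normal", [("onc", "epi")])
        tumor = make_graph("tumor", [("onc", "epi")])
        ann = make_annotation(["onc", "epi"], oncogene=("onc",),
                              epigenetic=("epi",))
        dual = DualGraph(normal, tumor, ann)
        paths = class_pair_paths(dual, "ONCOGENE", "EPIGENETIC")
        assert len(paths["normal"]) == 1
        assert paths["normal"][0].length == 1

    def test_node_loss_makes_tumor_infinite(self, small_dual):
        # oncogene 'f' has its only edge in normal; absent from tumor
        paths = class_pair_paths(small_dual, "TF", "ONCOGENE")
        by_pair_t = {(p.source, p.target): p.length for p in paths["tumor"]}
        by_pair_n = {(p.source, p.target): p.length for p in paths["normal"]}
        assert by_pair_n[("e", "f")] == 1
        assert math.isinf(by_pair_t[("e", "f")])

    def test_empty_class_warns_and_returns_empty(self, small_dual, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            paths = class_pair_paths(small_dual, "TF", "TF")
        assert paths == {"normal": [], "tumor": []}


class TestScaleFreeFit:
    def _from_networkx(self, g):
        edges = [make_edge(f"v{a:04d}", f"v{b:04d}", 0.9) for a, b in g.edges]
        return ConditionGraph("normal", edges)

    def test_preferential_attachment_fits_power_law(self):
        import networkx as nx

        graph = self._from_networkx(nx.barabasi_albert_graph(1000, 3, seed=5))
        r2, slope = scale_free_fit(graph)
        assert r2 > 0.8
        assert slope < 0

    def test_erdos_renyi_fits_worse(self):
        import networkx as nx

        ba = self._from_networkx(nx.barabasi_albert_graph(1000, 3, seed=5))
        er = self._from_networkx(
            nx.gnm_random_graph(1000, ba.n_edges, seed=5)
        )
        assert scale_free_fit(er)[0] < scale_free_fit(ba)[0]

    def test_regular_graph_rejected(self):
        pairs = [(f"a{i}", f"a{(i + 1) % 8}") for i in range(8)]
        pairs = [tuple(sorted(p)) for p in pairs]
        graph = make_graph("normal", pairs)
        with pytest.raises(ValueError):
            scale_free_fit(graph)
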