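import numpy as np
import pytest

from coexnet import (
    CoexpressionEdge,
    ConditionGraph,
    DualGraph,
    GeneAnnotationTable,
)
import pandas as pd


def make_edge(a, b, rho=0.9):
    return CoexpressionEdge.from_rho(a, b, rho)


def make_graph(condition, pairs, rho=0.9, nodes=()):
    """Graph from (a, b) pairs, all with the same rho unless given per-pair."""
    edges = []
    for pair in pairs:
        if len(pair) == 3:
            a, b, r = pair
        else:
            a, b = pair
            r = rho
        edges.append(make_edge(a, b, r))
    return ConditionGraph(condition, edges, nodes=nodes)


def make_annotation(genes, tf=(), epigenetic=(), oncogene=()):
    frame = pd.DataFrame(
        {
            "gene": list(genes),
            "uniprot": [f"P{i:05d}" for i in range(len(genes))],
            "description": [f"gene {g}" for g in genes],
            "is_tf": [int(g in tf) for g in genes],
            "is_epigenetic_regulator": [int(g in epigenetic) for g in genes],
            "is_oncogene": [int(g in oncogene) for g in genes],
        }
    )
    return GeneAnnotationTable(frame)


@pytest.fixture
def small_dual():
    """Normal: path a-b-c-d plus TF-oncogene edge e-f; tumor: only a-b."""
    genes = ["a", "b", "c", "d", "e", "f"]
    normal = make_graph("normal", [("a", "b"), ("b", "c"), ("c", "d"), ("e", "f")])
    tumor = make_graph("tumor", [("a", "b")])
    ann = make_annotation(genes, tf=("e",), epigenetic=("c",), oncogene=("a", "f"))
    return DualGraph(normal, tumor, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
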