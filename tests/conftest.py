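import itertools

import networkx as nx
import pandas as pd
import pytest

from ctxgsa import GeneSet, Network, PathwayLibrary


@pytest.fixture
def small_library():
    return PathwayLibrary(
        name="toy",
        sets={
            "pathway a": [f"A{i}" for i in range(20)],
            "pathway b": [f"B{i}" for i in range(25)],
            "pathway c": [f"C{i}" for i in range(30)],
        },
    )


@pytest.fixture
def two_cliques_net():
    """Two K4 cliques joined by a single bridge edge."""
    g = nx.Graph()
    left = ["A", "B", "C", "D"]
    right = ["E", "F", "G", "H"]
    for grp in (left, right):
        g.add_edges_from(
            (u, v, {"confidence": 0.9}) for u, v in itertools.combinations(grp, 2)
        )
    g.add_edge("D", "E", confidence=0.9)
    return Network(graph=g)


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


@pytest.fixture
def gene_set_factory():
    def make(genes, name="test"):
        return GeneSet(name=name, genes=list(genes))

    return make
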