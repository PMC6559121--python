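from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def random_connected_graph(n: int, m: int, rng: np.random.Generator) -> nx.Graph:
    """Small random graph patched to connectivity with a random spanning chain."""
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    order = list(rng.permutation(nodes))
    for a, b in zip(order, order[1:]):
        g.add_edge(a, b)
    m = min(m, n * (n - 1) // 2)
    while g.number_of_edges() < m:
        u, v = rng.choice(nodes, size=2)
        if u != v:
            g.add_edge(u, v)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_graph() -> nx.Graph:
    """8-node graph used across connectivity tests."""
    g = nx.Graph()
    g.add_edges_from(
        [("1", "3"), ("2", "3"), ("4", "1"), ("4", "3"), ("5", "6"), ("3", "5"),
         ("6", "7"), ("7", "8"), ("8", "1")]
    )
    return g
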