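import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cna import Interactome


@pytest.fixture
def triangle() -> Interactome:
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A")])
    return Interactome(g, "triangle")


@pytest.fixture
def star3() -> Interactome:
    """3-leaf star with center 'H'."""
    g = nx.star_graph(3)
    g = nx.relabel_nodes(g, {0: "H", 1: "L1", 2: "L2", 3: "L3"})
    return Interactome(g, "star3")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_connected_interactome(rng: np.random.Generator, n: int) -> Interactome:
    """Erdős–Rényi draw conditioned on connectedness (regenerate until so)."""
    p = min(1.0, 2.5 * np.log(n) / n)
    for _ in range(200):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return Interactome(nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes}))
    raise RuntimeError("failed to draw a connected graph")


def positive_expression(rng: np.random.Generator, inter: Interactome) -> pd.Series:
    nodes = sorted(inter.nodes)
    return pd.Series(np.exp(rng.standard_normal(len(nodes))), index=nodes)
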