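import networkx as nx
import numpy as np
import pytest

from allonet import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def graph_from_adjacency(adj: np.ndarray) -> nx.Graph:
    """Build a graph on integer-labelled nodes from an adjacency matrix."""
    n = adj.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                g.add_edge(i, j)
    return g


def random_adjacency(rng: np.random.Generator, n: int, p_edge: float) -> np.ndarray:
    upper = rng.random((n, n)) < p_edge
    adj = np.triu(upper, 1)
    adj = (adj | adj.T).astype(int)
    return adj
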