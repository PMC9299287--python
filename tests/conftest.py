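import numpy as np
import pytest

from ebsbm import Graph, Partition


@pytest.fixture
def four_node_graph():
    """4 nodes, Z = (1,1,2,2), edges {0,1}, {0,2}, {2,3} (0-based)."""
    a = np.zeros((4, 4), dtype=np.int8)
    for i, j in [(0, 1), (0, 2), (2, 3)]:
        a[i, j] = a[j, i] = 1
    return Graph(a), Partition(np.array([1, 1, 2, 2]), K=2)


@pytest.fixture
def two_cliques():
    """Two disjoint 5-cliques."""
    a = np.zeros((10, 10), dtype=np.int8)
    a[:5, :5] = 1
    a[5:, 5:] = 1
    np.fill_diagonal(a, 0)
    return Graph(a), Partition(np.array([1] * 5 + [2] * 5), K=2)


def random_graph(n: int, p: float, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    a[iu] = (rng.random(iu[0].size) < p).astype(np.int8)
    a += a.T
    return Graph(a)
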