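import numpy as np
import pytest

from pgfold import Graph, complete_graph, path_graph


@pytest.fixture
def p2():
    return path_graph(2)


@pytest.fixture
def p3():
    return path_graph(3)


@pytest.fixture
def k3():
    return complete_graph(3)


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.3) -> Graph:
    """Erdos-Renyi graph made connected by overlaying a random spanning path."""
    w = (rng.random((n, n)) < p).astype(float)
    w = np.triu(w, k=1)
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        w[min(a, b), max(a, b)] = 1.0
    w = w + w.T
    return Graph(w)


def random_tree(rng: np.random.Generator, n: int) -> Graph:
    """Uniform-ish random tree: attach each vertex to a random earlier one."""
    w = np.zeros((n, n))
    for i in range(1, n):
        j = int(rng.integers(0, i))
        w[i, j] = w[j, i] = 1.0
    return Graph(w)


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)
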