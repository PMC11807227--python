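import pytest

from revent import (
    MolecularGraph,
    graph_from_edge_list,
    haptx_partition,
    random_connected_graph,
)


@pytest.fixture
def p3() -> MolecularGraph:
    return graph_from_edge_list([("a", "b"), ("b", "c")])


@pytest.fixture
def c4() -> MolecularGraph:
    return graph_from_edge_list([("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")])


@pytest.fixture
def star3() -> MolecularGraph:
    return graph_from_edge_list([("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture(scope="session")
def haptx():
    return haptx_partition()


def graph_batch(count: int):
    """Deterministic batch of seeded random connected graphs, n <= 30."""
    graphs = []
    for seed in range(count):
        n = 2 + (seed * 7) % 29
        max_extra = n * (n - 1) // 2 - (n - 1)
        extra = min(seed % 4, max_extra)
        graphs.append(random_connected_graph(n, extra_edges=extra, seed=seed))
    return graphs


@pytest.fixture(scope="session")
def small_graph_batch():
    return graph_batch(30)
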