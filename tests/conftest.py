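import numpy as np
import pytest

from herbnet.phenonet import HierarchyEdge, build_network, weight_edges


@pytest.fixture
def chain_net():
    """R -> A -> B."""
    return weight_edges(build_network([HierarchyEdge("R", "A"), HierarchyEdge("A", "B")]))


@pytest.fixture
def diamond_net():
    """R -> {A, B}; {A, B} -> C."""
    edges = [
        HierarchyEdge("R", "A"),
        HierarchyEdge("R", "B"),
        HierarchyEdge("A", "C"),
        HierarchyEdge("B", "C"),
    ]
    return weight_edges(build_network(edges))


def random_dag_edges(rng: np.random.Generator, n_nodes: int, extra_edge_prob: float = 0.05):
    """Random rooted DAG: a spanning tree plus forward cross-edges."""
    ids = [f"N{i:03d}" for i in range(n_nodes)]
    edges = [
        HierarchyEdge(ids[int(rng.integers(0, i))], ids[i]) for i in range(1, n_nodes)
    ]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < extra_edge_prob and (ids[i], ids[j]) not in {
                (e.parent, e.child) for e in edges
            }:
                edges.append(HierarchyEdge(ids[i], ids[j]))
    return edges


@pytest.fixture
def random_dag_factory():
    def make(seed: int, n_nodes: int = 50, extra_edge_prob: float = 0.05):
        rng = np.random.default_rng(seed)
        return weight_edges(build_network(random_dag_edges(rng, n_nodes, extra_edge_prob)))

    return make
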