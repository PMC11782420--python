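import numpy as np
import pytest

import glycokin as gk


@pytest.fixture(scope="session")
def toy_net():
    return gk.make_toy_grn()


@pytest.fixture(scope="session")
def toy_entities():
    return gk.default_entities()


@pytest.fixture(scope="session")
def toy_params(toy_entities):
    return gk.default_parameters(toy_entities)


@pytest.fixture(scope="session")
def toy_model(toy_net, toy_entities):
    return gk.assemble_golgi_model(toy_net, toy_entities)


@pytest.fixture(scope="session")
def toy_result(toy_model, toy_params):
    return gk.simulate_golgi(toy_model, toy_params)


def random_dag(rng: np.random.Generator, n_nodes: int, p: float = 0.35):
    """Random rooted DAG on nodes 0..n-1; every node reachable from node 0."""
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(range(n_nodes))
    for j in range(1, n_nodes):
        graph.add_edge(int(rng.integers(0, j)), j)  # spanning arborescence
        for i in range(j):
            if rng.random() < p:
                graph.add_edge(i, j)
    return graph
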