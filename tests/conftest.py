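import random

import pytest

from frlink.graph_core import Network
from frlink.synthetic import fig3_graphs, fig4_graph, gen_planted_weak_clique


@pytest.fixture(scope="session")
def fig4():
    return fig4_graph()


@pytest.fixture(scope="session")
def fig3():
    return fig3_graphs()


@pytest.fixture(scope="session")
def planted():
    """The frozen planted-weak-clique benchmark network."""
    return gen_planted_weak_clique(seed=1)


def random_graph(rng: random.Random, max_nodes: int = 12) -> Network:
    """Small random graph for oracle cross-checks (size and density vary)."""
    n = rng.randint(3, max_nodes)
    p = rng.uniform(0.1, 0.9)
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Network(edges, nodes=nodes)
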