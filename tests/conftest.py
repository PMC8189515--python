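import networkx as nx
import numpy as np
import pytest

from hierspread.layered import LayeredGraph
from hierspread.network_gen import SyntheticConfig, build_synthetic_hierarchy


@pytest.fixture(scope="session")
def small_hierarchy():
    """A modest two-layer synthetic hierarchy shared across tests."""
    cfg = SyntheticConfig(n_staff=300, k_avg=20.0, rng_seed=11)
    graph, partition = build_synthetic_hierarchy(cfg)
    return graph, partition


@pytest.fixture(scope="session")
def manager_staff_pair():
    """Two nodes, one edge: an infected layer-2 manager above a staff node."""
    g = nx.Graph()
    g.add_node(0, layer=1)
    g.add_node(1, layer=2)
    g.add_edge(0, 1)
    return LayeredGraph(g)


@pytest.fixture(scope="session")
def path3():
    """Three-node path on a single layer."""
    g = nx.path_graph(3)
    nx.set_node_attributes(g, 1, "layer")
    return LayeredGraph(g)


def single_layer(g: nx.Graph) -> LayeredGraph:
    nx.set_node_attributes(g, 1, "layer")
    return LayeredGraph(g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
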