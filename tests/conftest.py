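import networkx as nx
import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # hypothesis is optional
    pass


def random_pcst_instance(rng, n_min=3, n_max=11, p=0.4,
                         prize_hi=3.0, cost_hi=2.0) -> nx.Graph:
    """Random connected graph with uniform prizes and costs, for
    oracle-vs-heuristic comparisons."""
    n = int(rng.integers(n_min, n_max))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for v in g.nodes:
        g.nodes[v]["prize"] = float(rng.uniform(0, prize_hi))
    for u, v in g.edges:
        g.edges[u, v]["cost"] = float(rng.uniform(0, cost_hi))
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def tiny_two_node():
    """Two nodes, prizes 5/5, one edge of cost 1."""
    g = nx.Graph()
    g.add_node("a", prize=5.0)
    g.add_node("b", prize=5.0)
    g.add_edge("a", "b", cost=1.0)
    return g
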