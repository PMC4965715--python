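import networkx as nx
import pytest

from gacomplex import PPINetwork, PlantedSpec, generate


def net_from(graph: nx.Graph) -> PPINetwork:
    return PPINetwork.from_networkx(graph)


def gnp_net(n: int, p: float, seed: int) -> PPINetwork:
    return net_from(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def path4() -> PPINetwork:
    """Path a-b-c-d."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def two_k4() -> PPINetwork:
    """Two disjoint K4s: nodes a0..a3 and b0..b3."""
    g = nx.Graph()
    g.add_edges_from(nx.complete_graph([f"a{i}" for i in range(4)]).edges)
    g.add_edges_from(nx.complete_graph([f"b{i}" for i in range(4)]).edges)
    return net_from(g)


@pytest.fixture
def clique_fixture():
    """Six disjoint 10-cliques with ground truth (p_in=1, p_out=0)."""
    return generate(PlantedSpec(p_in=1.0, p_out=0.0, seed=0))


@pytest.fixture
def planted_fixture():
    """Standard recovery conditions: 6 complexes of 10, p_in=.8, p_out=.02."""
    return generate(PlantedSpec(seed=0))
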