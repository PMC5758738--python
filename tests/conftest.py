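import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


def relabel(g: nx.Graph) -> nx.Graph:
    """Integer-labelled graph -> symbol-labelled graph."""
    return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})


@pytest.fixture
def path3() -> nx.Graph:
    g = nx.path_graph(3)
    return nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})


@pytest.fixture
def cycle4() -> nx.Graph:
    g = nx.cycle_graph(4)
    return nx.relabel_nodes(g, {i: "ABCD"[i] for i in range(4)})


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study replica (seed 42), generated once."""
    from hubpanel.synthetic import SyntheticSpec, make_bundle

    return make_bundle(SyntheticSpec(rng_seed=42))


def random_connected_graph(rng, n_max: int = 8, n_min: int = 3) -> nx.Graph:
    """A random connected symbol-labelled graph with <= n_max nodes."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.25, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return relabel(g)
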