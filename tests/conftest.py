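import networkx as nx
import pytest

from multicent.centrality import centrality_table
from multicent.datasets import toy_hub_tree
from multicent.hubdetect import detect_hubs
from multicent.synthetic import SyntheticSpec, generate_network


@pytest.fixture(scope="session")
def toy():
    """The 9-node worked-example tree (hub b; branches g1..g3; leaves w1..w5)."""
    return toy_hub_tree()


@pytest.fixture(scope="session")
def toy_table(toy):
    return centrality_table(toy)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced planted-hub scenario shared across clustering tests.

    400 proteins, 60 seed analogs, 10 planted hubs: large enough to exhibit
    the sparse-bulk/central-cloud geometry, small enough to cluster in
    seconds.
    """
    spec = SyntheticSpec(n_total=400, n_seed=60, n_hubs=10, seed=3)
    net, truth = generate_network(spec)
    table = centrality_table(net)
    return spec, net, truth, table


@pytest.fixture(scope="session")
def small_hub_result(small_scenario):
    _, _, _, table = small_scenario
    return detect_hubs(table, seed=3)


def random_connected_graph(rng, n_min=5, n_max=40):
    """A random connected simple graph: G(n, p) conditioned on connectivity
    by keeping its giant component."""
    n = int(rng.integers(n_min, n_max + 1))
    p = min(1.0, float(rng.uniform(1.2, 3.0)) / n + 0.05)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    giant = max(nx.connected_components(g), key=len)
    g = g.subgraph(giant).copy()
    return nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
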