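import networkx as nx
import numpy as np
import pytest

import dignifi as dg


@pytest.fixture(scope="session")
def toys() -> dict[str, dg.Network]:
    """The curated pathological graphs, keyed by description."""
    return {desc: net for net, desc in dg.degenerate_cases()}


@pytest.fixture(scope="session")
def reference_bundle() -> dg.FixtureBundle:
    """The reference synthetic benchmark (500 background genes, 20 planted
    modules of size 6, seed 42)."""
    return dg.generate(dg.FixtureSpec())


def random_connected_network(rng: np.random.Generator, n_max: int = 50) -> dg.Network:
    """A random connected graph with 4..n_max nodes, unit weights."""
    n = int(rng.integers(4, n_max + 1))
    p = min(1.0, 2.0 * np.log(n) / n)
    while True:
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_edges() > 0 and nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return dg.Network(g)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
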