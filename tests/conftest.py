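import numpy as np
import pytest

from dyncomplex import synthetic
from dyncomplex.io import PPINetwork


@pytest.fixture(scope="session")
def toy():
    """Hand-crafted 12-protein fixture: two planted cliques + background."""
    return synthetic.make_toy_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_network(rng, n_max=30, p=0.3):
    """A random undirected network on a random number of nodes."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"N{i:03d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork.from_edges(edges, nodes=nodes)
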