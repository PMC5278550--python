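import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ba_small():
    """100-node scale-free network, mean degree ~4."""
    from robustcoop import generate_ba

    return generate_ba(100, 2, seed=7)


def random_connected_graph(n: int, m: int, seed: int) -> nx.Graph:
    """Small random connected test instance (not via the package generators)."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(g):
            return g
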