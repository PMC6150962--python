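import warnings

import networkx as nx
import numpy as np
import pytest

from ppicomplex import Node2VecParams, SynthConfig, generate
from ppicomplex.embedding import embed_network


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # Modules warn liberally (skipped lines, zero-vector fallbacks); tests
    # assert on behavior and opt in to pytest.warns where the warning itself
    # is the contract.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_fixture():
    """A compact planted-complex network shared by the slower tests."""
    config = SynthConfig(n_background_nodes=150, n_complexes=6, size_min=5,
                         size_max=8, p_within=0.85, p_background=0.02,
                         seed=42)
    net, gold, mid = generate(config)
    return net, gold, mid


@pytest.fixture(scope="session")
def small_embedding(small_fixture):
    net, _, _ = small_fixture
    params = Node2VecParams(d=32, r=5, l=10, k=5)
    return embed_network(net, params, seed=42)


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded Erdos-Renyi helper with string node IDs."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes()})


def rng_of(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
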