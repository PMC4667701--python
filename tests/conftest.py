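import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from dkseries import GeneratorSpec, figure1_graph, generate_synthetic


@pytest.fixture
def fig1():
    """The 4-node worked example: triangle a-b-c with pendant d on c."""
    return figure1_graph()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def medium_graph():
    """A 500-node heavy-tailed synthetic graph shared by chain tests."""
    return generate_synthetic(GeneratorSpec(n_nodes=500, degree_exponent=2.3, seed=5))


def random_small_graphs(n_graphs: int, max_n: int = 8, seed: int = 0):
    """Erdos-Renyi-ish small graphs of varying size/density for oracle tests."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.15, 0.85))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        out.append(g)
    return out
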