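import numpy as np
import pytest

from ppicomplex.ppi_io import WeightedPPINetwork
from ppicomplex.simulate import FixtureSpec, gce_window_fixture, generate


@pytest.fixture
def triangle():
    """Isolated unit-weight triangle a-b-c."""
    return WeightedPPINetwork.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
    )


@pytest.fixture
def path_abc():
    """Unit-weight path a-b-c."""
    return WeightedPPINetwork.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])


def random_weighted_network(rng: np.random.Generator, max_nodes: int = 12):
    """Small random weighted graph for oracle comparisons."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"p{i}" for i in range(n)]
    p = rng.uniform(0.2, 0.7)
    net = WeightedPPINetwork()
    for node in names:
        net.graph.add_node(node)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p:
                net.add_edge(names[i], names[j], float(rng.uniform(0.05, 1.0)))
    return net, names


@pytest.fixture(scope="session")
def default_fixture():
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """Smaller planted fixture for optimizer-loop tests."""
    return generate(FixtureSpec(n_complexes=4, n_background=8, seed=7))


@pytest.fixture(scope="session")
def window_fixture():
    return gce_window_fixture(seed=1)
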