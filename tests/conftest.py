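import numpy as np
import pytest

from essrank import PPINetwork, ProteinRegistry, SynthSpec, simulate, toy_pdi


@pytest.fixture(scope="session")
def toy():
    """The 5-protein / 4-domain worked-example bipartite network."""
    net, expected = toy_pdi()
    return net, expected


@pytest.fixture(scope="session")
def small_dataset():
    """One default-effect synthetic dataset, shared across tests."""
    return simulate(SynthSpec(n_proteins=120, n_domains=60, seed=11))


@pytest.fixture()
def triangle_ppi():
    """K3 plus a pendant node: triangle (a,b,c), pendant d on a."""
    reg = ProteinRegistry(["a", "b", "c", "d"])
    net = PPINetwork(reg)
    for u, v in [(0, 1), (0, 2), (1, 2), (0, 3)]:
        net.add_edge(u, v)
    return net


def random_bipartite(rng: np.random.Generator, max_side: int = 8) -> np.ndarray:
    """Random binary bipartite adjacency with 1..max_side rows/columns."""
    n = rng.integers(1, max_side + 1)
    m = rng.integers(1, max_side + 1)
    return (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
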