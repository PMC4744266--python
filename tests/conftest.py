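import numpy as np
import pytest

from multisbm import MultiNetwork, Partition
from multisbm._rng import substream
from multisbm.fixtures import two_clique_network


def random_multinetwork(N: int, T: int, seed: int, density: float = 0.5) -> MultiNetwork:
    """Erdos-Renyi-style multi-network for oracle comparisons."""
    rng = substream(seed, "test-net")
    adj = []
    for _ in range(T):
        A = np.zeros((N, N))
        iu, ju = np.triu_indices(N, k=1)
        hit = rng.random(iu.size) < density
        A[iu[hit], ju[hit]] = 1.0
        A += A.T
        adj.append(A)
    return MultiNetwork(adj, [f"n{i}" for i in range(N)])


def random_state(N: int, K: int, T: int, seed: int):
    """A consistent random variational state over a random multi-network."""
    from multisbm import Hyperparameters, init_state, refine, FitOptions

    net = random_multinetwork(N, T, seed)
    hyper = Hyperparameters.default(K)
    state = init_state(net, hyper, seed=seed)
    return net, hyper, state


@pytest.fixture
def two_cliques():
    return two_clique_network(clique_size=4, T=2)


@pytest.fixture
def two_cliques_single():
    return two_clique_network(clique_size=4, T=1)


def assert_monotone_trace(trace, rel=1e-8):
    for a, b in zip(trace, trace[1:]):
        assert b <= a + rel * abs(a), f"free energy increased: {a} -> {b}"
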