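import numpy as np
import pytest

from cosplice.network import NetworkTensor


def random_tensor(n: int, m: int, seed: int, low: float = 0.0, high: float = 1.0) -> NetworkTensor:
    """i.i.d. symmetric U(low, high) weights with zero diagonal."""
    rng = np.random.default_rng(seed)
    weights = np.empty((m, n, n))
    for k in range(m):
        upper = np.triu(rng.uniform(low, high, size=(n, n)), 1)
        weights[k] = upper + upper.T
    return NetworkTensor(
        [f"e{i:03d}" for i in range(n)], [f"n{k:02d}" for k in range(m)], weights
    )


def planted_clique_tensor(
    n: int = 12,
    m: int = 3,
    clique: tuple[int, ...] = (0, 1, 2, 3, 4),
    networks: tuple[int, ...] = (0, 1),
    weight: float = 0.9,
    background: float = 0.0,
    seed: int = 0,
) -> NetworkTensor:
    """A single planted clique over an otherwise constant background."""
    t = random_tensor(n, m, seed, low=background, high=background)
    idx = np.array(clique)
    for k in networks:
        block = np.full((len(idx), len(idx)), weight)
        np.fill_diagonal(block, 0.0)
        t.weights[np.ix_([k], idx, idx)] = block
    return t


@pytest.fixture
def clique_tensor() -> NetworkTensor:
    return planted_clique_tensor()
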