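import numpy as np
import pytest
import scipy.sparse as sp

from barrelabc import BarrelConfig, Connectome


@pytest.fixture(scope="session")
def small_config() -> BarrelConfig:
    return BarrelConfig().scaled(300)


@pytest.fixture(scope="session")
def mid_config() -> BarrelConfig:
    return BarrelConfig().scaled(500)


def make_connectome(edges, types, positions=None, weights=None):
    """Build a connectome from (pre, post) edge pairs and +-1 type labels."""
    types = np.asarray(types, dtype=np.int8)
    n = len(types)
    rows = np.array([post for _, post in edges], dtype=int)
    cols = np.array([pre for pre, _ in edges], dtype=int)
    if weights is None:
        data = types[cols].astype(np.int8)
        binary = True
    else:
        data = np.asarray(weights, dtype=float) * types[cols]
        binary = bool(np.all(np.abs(data) == 1))
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    return Connectome(adj, types, positions, binary=binary)


@pytest.fixture
def tiny_reciprocal():
    # two excitatory neurons connected both ways
    return make_connectome([(0, 1), (1, 0)], [1, 1])


def random_signed_digraph(rng, n, p=0.4, n_inh=None):
    """Random signed digraph with at least one neuron of each type."""
    n_inh = n_inh if n_inh is not None else max(1, n // 3)
    types = np.array([1] * (n - n_inh) + [-1] * n_inh, dtype=np.int8)
    support = rng.random((n, n)) < p
    np.fill_diagonal(support, False)
    signed = support.astype(np.int8) * types[np.newaxis, :]
    return Connectome(sp.csr_matrix(signed), types, binary=True)
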