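import numpy as np
import pytest

from mvgsc import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """60 cells, 3 well-separated planted populations."""
    spec = SyntheticSpec(n_cells=60, n_genes=120, n_clusters=3, separation=8, seed=7)
    return generate(spec)


@pytest.fixture
def two_block_graph():
    """Row-stochastic graph with two disjoint 4-cell blocks."""
    n = 8
    S = np.zeros((n, n))
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            others = [j for j in block if j != i]
            S[i, others] = 1.0 / len(others)
    return S


def union_find_components(W: np.ndarray, threshold: float = 1e-10) -> int:
    """Independent union-find oracle for connected-component counting."""
    n = W.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sym = (W + W.T) / 2.0
    for i in range(n):
        for j in range(i + 1, n):
            if sym[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})
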