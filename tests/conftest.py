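import numpy as np
import pytest

from mcpnet import WeightMatrix, make_planted_weights


@pytest.fixture
def w3():
    """Three-gene toy network: W12=0.9, W23=0.8, W13=0.1."""
    return WeightMatrix.gcn(
        ["g1", "g2", "g3"],
        [[0.0, 0.9, 0.1], [0.9, 0.0, 0.8], [0.1, 0.8, 0.0]],
    )


@pytest.fixture
def planted():
    return make_planted_weights(40, 60, 0.5, 0.05, seed=7)


def random_gcn(n, seed):
    """Random symmetric zero-diagonal weight matrix on n genes."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 1, size=(n, n))
    values = np.maximum(values, values.T)
    np.fill_diagonal(values, 0.0)
    return WeightMatrix.gcn([f"g{i}" for i in range(n)], values)
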