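import numpy as np
import pytest

from moranfix import Game, ModelParams, canonical_games


@pytest.fixture
def games():
    return canonical_games()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_params():
    return ModelParams(N=10, beta=0.0)


def dense_transition_matrix(kernel):
    """Dense (N+1)x(N+1) transition matrix, assembled independently of the
    banded code path; oracle for small-N solves."""
    N = kernel.N
    T = np.zeros((N + 1, N + 1))
    for i in range(N + 1):
        T[i, i] = kernel.stay[i]
        if i < N:
            T[i, i + 1] = kernel.up[i]
        if i > 0:
            T[i, i - 1] = kernel.down[i]
    return T
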