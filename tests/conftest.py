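import numpy as np
import pytest
from hypothesis import settings

from hmmpca import TimeSeriesDataset, generate_scenario1

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Two correlated sessions, 6 regions — generic input for fast fits."""
    n, L = 6, 150
    B = rng.standard_normal((n, 2))
    vals = rng.standard_normal((2 * L, 2)) @ B.T + 0.3 * rng.standard_normal((2 * L, n))
    return TimeSeriesDataset(vals, [1, L + 1])


@pytest.fixture(scope="session")
def scenario1_small():
    """A small scenario-1 draw shared by fit tests (2 sessions x 300)."""
    return generate_scenario1(p0=2, sessions=2, session_length=300, seed=7)


def brute_force_forward_backward(logB, Theta, pi, session_starts=None):
    """Enumerate all state paths; the independent oracle for forward-backward.

    Handles session boundaries by re-drawing the initial state from pi.
    Returns (gamma, xi, log_evidence).
    """
    import itertools

    T, K = logB.shape
    starts0 = set(s - 1 for s in (session_starts or [1]))
    B = np.exp(logB)
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    Z = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = 1.0
        for t, k in enumerate(path):
            prior = pi[k] if t in starts0 else Theta[path[t - 1], k]
            p *= prior * B[t, k]
        Z += p
        for t, k in enumerate(path):
            gamma[t, k] += p
        for t in range(1, T):
            if t not in starts0:
                xi[path[t - 1], path[t]] += p
    return gamma / Z, xi / Z, np.log(Z)
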