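import numpy as np
import pytest

from gcbold.graphs import DirectedNetwork, sample_uniform_digraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_node_net():
    """Single directed edge 0 -> 1."""
    return DirectedNetwork(2, frozenset({(0, 1)}))


@pytest.fixture
def net20(rng):
    """20-node network at the benchmark density 0.05."""
    return sample_uniform_digraph(20, 19, rng)


def simulate_var(coefs: np.ndarray, n_obs: int, rng: np.random.Generator,
                 burn: int = 200, noise_cov: np.ndarray | None = None) -> np.ndarray:
    """Simulate a stable VAR process; ``coefs`` is (order, dim, dim)."""
    order, dim, _ = coefs.shape
    if noise_cov is None:
        chol = np.eye(dim)
    else:
        chol = np.linalg.cholesky(noise_cov)
    total = n_obs + burn
    e = rng.standard_normal((total, dim)) @ chol.T
    x = np.zeros((total, dim))
    for t in range(order, total):
        acc = e[t].copy()
        for k in range(order):
            acc += coefs[k] @ x[t - k - 1]
        x[t] = acc
    return x[burn:]


def population_gc_bivariate(coefs: np.ndarray, target: int, order: int) -> float:
    """Population MVGC for a bivariate VAR(1) via Yule–Walker equations.

    Solves the discrete Lyapunov equation for the process autocovariances,
    forms the order-``order`` autoregression of the target channel alone
    (Toeplitz system in its autocovariances) and returns the log ratio of
    restricted to unrestricted residual variance.  Independent of the
    package's estimators.
    """
    from scipy.linalg import solve_discrete_lyapunov, solve_toeplitz

    A = coefs[0]
    s0 = solve_discrete_lyapunov(A, np.eye(A.shape[0]))
    # autocovariance sequence of the full process: S_k = A^k S_0
    autocov = [s0]
    for _ in range(order):
        autocov.append(A @ autocov[-1])
    c = np.array([s[target, target] for s in autocov])  # target channel lags 0..P
    phi = solve_toeplitz(c[:order], c[1:order + 1])
    var_restricted = c[0] - phi @ c[1:order + 1]
    return float(np.log(var_restricted / 1.0))  # unit innovation variance
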