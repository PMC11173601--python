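import numpy as np
import pytest

from gzigpfa import ScenarioSpec, ZigpRegressionProblem, generate, phi_from_lambda, zigp_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regression(n=400, K=2, beta=(0.8, 0.6), tau=1.2, alpha=0.2, seed=0, offset=None):
    """A ZIGP regression problem simulated from the model itself."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(0, 0.5, n) for _ in range(K - 1)])
    beta = np.asarray(beta, dtype=float)
    offset_log = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    eta = X @ beta
    lam = np.exp(eta)
    mu = np.exp(eta + offset_log)
    phi = phi_from_lambda(lam, tau)
    y = zigp_sample(phi, mu, alpha, rng=rng)
    return ZigpRegressionProblem(y=y, X=X, offset_log=offset_log), beta, tau, alpha


def make_stacked(n=100, n_blocks=4, tau=1.2, alpha=0.2, seed=0):
    """Several ZIGP regressions sharing one design matrix and (tau, alpha)."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(0, 0.5, n)])
    problems = []
    for _ in range(n_blocks):
        beta = np.array([rng.uniform(0.5, 1.2), rng.uniform(-0.8, 0.8)])
        lam = np.exp(X @ beta)
        phi = phi_from_lambda(lam, tau)
        y = zigp_sample(phi, lam, alpha, rng=rng)
        problems.append(ZigpRegressionProblem(y=y, X=X))
    return problems


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-size model-link dataset (rank 3, light zero inflation)."""
    return generate(ScenarioSpec(scenario=1, zero_target=0.2, n=60, m=30, seed=3))


@pytest.fixture(scope="session")
def scenario1_dataset():
    """One canonical-size dataset under the model link at 20% zeros."""
    return generate(ScenarioSpec(scenario=1, zero_target=0.2, seed=11))
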