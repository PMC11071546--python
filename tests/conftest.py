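import numpy as np
import pytest

from adaloo.models import GaussianPrior, LogisticRegression, ReluNet1Hidden
from adaloo.sample_io import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lr_problem(rng):
    """Small logistic-regression problem: model, dataset, one draw batch."""
    p, n, s = 5, 8, 40
    model = LogisticRegression(p, prior=GaussianPrior(1.0))
    X = rng.standard_normal((n, p))
    y = (rng.uniform(size=n) < 0.5).astype(int)
    data = Dataset(X, y)
    draws = rng.standard_normal((s, p)) * 0.6
    return model, data, draws


@pytest.fixture
def relu_problem(rng):
    """Small 1-hidden ReLU problem (d=3, p_x=4)."""
    d, p_x, n, s = 3, 4, 6, 30
    model = ReluNet1Hidden(d, p_x, prior=GaussianPrior(1.0))
    X = rng.standard_normal((n, p_x))
    y = (rng.uniform(size=n) < 0.5).astype(int)
    data = Dataset(X, y)
    draws = rng.standard_normal((s, model.n_params)) * 0.7
    return model, data, draws


def fd_grad(f, theta, eps=1e-6):
    """Central finite-difference gradient of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    g = np.empty_like(theta)
    for a in range(theta.size):
        e = np.zeros_like(theta)
        e[a] = eps
        g[a] = (f(theta + e) - f(theta - e)) / (2 * eps)
    return g


def fd_jacobian_logdet(T, theta, eps=1e-6):
    """Log |det| of the dense finite-difference Jacobian of a map T."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    J = np.empty((p, p))
    for a in range(p):
        e = np.zeros(p)
        e[a] = eps
        J[:, a] = (T(theta + e) - T(theta - e)) / (2 * eps)
    sign, logdet = np.linalg.slogdet(J)
    assert sign != 0
    return logdet
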