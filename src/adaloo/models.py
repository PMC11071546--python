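"""Sigmoidal classification models and priors.

Both model families predict ``P(y=1 | x) = sigmoid(mu(theta, x))``:

* logistic regression, ``mu = x' beta``;
* a one-hidden-layer ReLU network, ``mu = W2 relu(W1 x) + b2`` with the
  first-layer bias absorbed into ``W1`` via a unit covariate component.

The module supplies everything the stabilizing transformations consume:
``mu`` and its parameter gradient, the Bernoulli log-likelihood, the
unnormalized log posterior and its gradient, and — for the ReLU net —
the closed-form eigenstructure of the (sparse) Hessian of ``mu``.

Parameter flattening for the ReLU net is fixed as
``[W1 row-major (d*p_x), W2 (d), b2 (1)]`` so that draw columns map
deterministically onto network weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sample_io import Dataset

__all__ = [
    "GaussianPrior",
    "StudentTPrior",
    "LogisticRegression",
    "ReluNet1Hidden",
    "log_sigmoid",
    "sigmoid",
]


def sigmoid(m):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(m, dtype=float)))


def log_sigmoid(m):
    """Numerically stable ``log(sigmoid(m))`` (no overflow for large |m|)."""
    return -np.logaddexp(0.0, -np.asarray(m, dtype=float))


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class GaussianPrior:
    """Independent N(0, tau^2) prior on every parameter component."""

    tau: float = 1.0

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        p = th.shape[-1]
        return (
            -0.5 * np.sum(th * th, axis=-1) / self.tau**2
            - p * np.log(self.tau)
            - 0.5 * p * np.log(2 * np.pi)
        )

    def grad_log_density(self, theta: np.ndarray) -> np.ndarray:
        return -np.asarray(theta, dtype=float) / self.tau**2


@dataclass(frozen=True)
class StudentTPrior:
    """Independent Student-t prior: a heavy-tailed shrinkage prior.

    The Student-t marginal concentrates mass near zero while leaving
    heavy tails for the few large effects — a simplified stand-in for
    hierarchical shrinkage priors whose latent scales are not carried in
    the draw matrix.
    """

    df: float = 3.0
    scale: float = 1.0

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        return stats.t.logpdf(th, df=self.df, scale=self.scale).sum(axis=-1)

    def grad_log_density(self, theta: np.ndarray) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        return -(self.df + 1.0) * th / (self.df * self.scale**2 + th * th)


# ---------------------------------------------------------------------------
# models


class _SigmoidalModel:
    """Shared likelihood/posterior machinery for sigmoidal classifiers."""

    kind: str
    n_params: int

    # --- per-point mean function -----------------------------------
    def mu(self, theta: np.ndarray, x: np.ndarray) -> float:
        raise NotImplementedError

    def grad_mu(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # --- batched over draws and observations ------------------------
    def mu_all(self, draws: np.ndarray, X: np.ndarray) -> np.ndarray:
        """``(s, n)`` matrix of mean-function values."""
        raise NotImplementedError

    def grad_mu_all(self, draws: np.ndarray, x: np.ndarray) -> np.ndarray:
        """``(s, p)`` gradients of ``mu(., x)`` at every draw."""
        raise NotImplementedError

    # --- likelihood and posterior -----------------------------------
    def log_likelihood(self, theta, x, y) -> float:
        if y not in (0, 1):
            raise ValueError("y must be 0 or 1")
        m = self.mu(theta, x)
        return float(log_sigmoid((2 * y - 1) * m))

    def loglik_all(self, draws: np.ndarray, data: Dataset) -> np.ndarray:
        """``(s, n)`` Bernoulli log-likelihoods for every draw and point."""
        m = self.mu_all(np.atleast_2d(draws), data.X)
        sign = 2.0 * data.y - 1.0
        return log_sigmoid(sign[None, :] * m)

    def log_posterior(self, draws: np.ndarray, data: Dataset | None) -> np.ndarray:
        """Unnormalized log posterior per draw (normalizer never computed)."""
        th = np.atleast_2d(np.asarray(draws, dtype=float))
        lp = self.prior.log_density(th)
        if data is not None and data.n_obs > 0:
            lp = lp + self.loglik_all(th, data).sum(axis=1)
        return lp

    def grad_log_posterior(self, draws: np.ndarray, data: Dataset | None) -> np.ndarray:
        """Gradient of the unnormalized log posterior, per draw.

        The per-point coefficient is the residual ``y_j - sigmoid(mu_j)``
        (the algebraically simplified likelihood-score coefficient).
        """
        th = np.atleast_2d(np.asarray(draws, dtype=float))
        g = self.prior.grad_log_density(th)
        if data is not None and data.n_obs > 0:
            m = self.mu_all(th, data.X)  # (s, n)
            resid = data.y[None, :] - sigmoid(m)
            g = g + self._accumulate_score(th, data.X, resid)
        return g

    def _accumulate_score(self, draws, X, resid) -> np.ndarray:
        """``sum_j resid[:, j] * grad_mu(theta, x_j)`` per draw."""
        raise NotImplementedError


class LogisticRegression(_SigmoidalModel):
    """Bayesian logistic regression: ``mu = x' beta``."""

    kind = "logistic_regression"

    def __init__(self, n_params: int, prior=None):
        self.n_params = int(n_params)
        self.prior = prior if prior is not None else GaussianPrior(1.0)

    def mu(self, theta, x):
        theta = np.asarray(theta, dtype=float)
        x = np.asarray(x, dtype=float)
        if theta.shape[-1] != x.shape[-1]:
            raise ValueError("theta/x dimension mismatch")
        return float(theta @ x)

    def grad_mu(self, theta, x):
        return np.asarray(x, dtype=float).copy()

    def mu_all(self, draws, X):
        return np.atleast_2d(draws) @ np.asarray(X, dtype=float).T

    def grad_mu_all(self, draws, x):
        s = np.atleast_2d(draws).shape[0]
        return np.broadcast_to(np.asarray(x, dtype=float), (s, x.shape[-1]))

    def _accumulate_score(self, draws, X, resid):
        return resid @ X

    def hessian_mu(self, theta, x):
        return np.zeros((self.n_params, self.n_params))


class ReluNet1Hidden(_SigmoidalModel):
    """One-hidden-layer ReLU network with a sigmoid output.

    ``mu = W2 relu(W1 x) + b2`` with ``W1 in R^{d x p_x}``,
    ``W2 in R^{1 x d}``, ``b2 in R``.  The ReLU derivative at exactly 0
    is taken to be 0 (left-continuous step convention).
    """

    kind = "relu_net_1hidden"

    def __init__(self, d: int, p_x: int, prior=None):
        self.d = int(d)
        self.p_x = int(p_x)
        self.n_params = self.d * self.p_x + self.d + 1
        self.prior = prior if prior is not None else GaussianPrior(1.0)

    # parameter flattening: [W1 row-major, W2, b2]
    def unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        d, p_x = self.d, self.p_x
        W1 = theta[..., : d * p_x].reshape(*theta.shape[:-1], d, p_x)
        W2 = theta[..., d * p_x : d * p_x + d]
        b2 = theta[..., -1]
        return W1, W2, b2

    def pack(self, W1, W2, b2) -> np.ndarray:
        return np.concatenate(
            [np.ravel(W1), np.ravel(W2), np.atleast_1d(float(b2))]
        )

    def mu(self, theta, x):
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.p_x:
            raise ValueError("x dimension mismatch")
        W1, W2, b2 = self.unpack(theta)
        z1 = W1 @ x
        return float(W2 @ np.maximum(z1, 0.0) + b2)

    def grad_mu(self, theta, x):
        x = np.asarray(x, dtype=float)
        W1, W2, b2 = self.unpack(theta)
        z1 = W1 @ x
        act = np.maximum(z1, 0.0)
        step = (z1 > 0).astype(float)
        gW1 = (W2 * step)[:, None] * x[None, :]
        return np.concatenate([gW1.ravel(), act, [1.0]])

    def mu_all(self, draws, X):
        th = np.atleast_2d(draws)
        X = np.asarray(X, dtype=float)
        W1, W2, b2 = self.unpack(th)  # (s,d,p), (s,d), (s,)
        z1 = np.einsum("sdp,np->snd", W1, X)
        a = np.maximum(z1, 0.0)
        return np.einsum("snd,sd->sn", a, W2) + b2[:, None]

    def grad_mu_all(self, draws, x):
        th = np.atleast_2d(draws)
        s = th.shape[0]
        x = np.asarray(x, dtype=float)
        W1, W2, b2 = self.unpack(th)
        z1 = W1 @ x  # (s, d)
        act = np.maximum(z1, 0.0)
        step = (z1 > 0).astype(float)
        gW1 = (W2 * step)[:, :, None] * x[None, None, :]  # (s,d,p_x)
        return np.concatenate(
            [gW1.reshape(s, -1), act, np.ones((s, 1))], axis=1
        )

    def _accumulate_score(self, draws, X, resid):
        th = np.atleast_2d(draws)
        s = th.shape[0]
        X = np.asarray(X, dtype=float)
        W1, W2, b2 = self.unpack(th)
        z1 = np.einsum("sdp,np->snd", W1, X)
        a = np.maximum(z1, 0.0)
        step = (z1 > 0).astype(float)
        gW1 = np.einsum("sn,sd,snd,np->sdp", resid, W2, step, X)
        gW2 = np.einsum("sn,snd->sd", resid, a)
        gb2 = resid.sum(axis=1, keepdims=True)
        return np.concatenate([gW1.reshape(s, -1), gW2, gb2], axis=1)

    # --- Hessian structure ------------------------------------------
    def hessian_mu(self, theta, x):
        """Dense ``(p, p)`` Hessian of mu (only W1/W2 mixed partials)."""
        x = np.asarray(x, dtype=float)
        W1, W2, b2 = self.unpack(theta)
        z1 = W1 @ x
        step = (z1 > 0).astype(float)
        p = self.n_params
        H = np.zeros((p, p))
        d, p_x = self.d, self.p_x
        for k in range(d):
            u = step[k] * x  # d mu / d W1[k,:] d W2[k]
            rows = slice(k * p_x, (k + 1) * p_x)
            col = d * p_x + k
            H[rows, col] = u
            H[col, rows] = u
        return H

    def hessian_mu_eigs(self, theta, x):
        """The 2d structured eigenpairs of the Hessian of mu.

        Hidden unit ``k`` couples W1 row ``k`` with (W2)_k through
        ``u_k = step(z1_k) * x``, giving the eigenvalue pair
        ``+-|u_k| = +-[step(z1_k) * sum_j x_j^2]^(1/2)`` with
        eigenvectors ``(u_k/(sqrt(2)|u_k|)) in the W1-row slot combined
        with ``+-e_k/sqrt(2)`` in the W2 slot.  Dead units contribute
        eigenvalue 0 (their eigenvectors are returned as zero vectors);
        all remaining Hessian eigenvalues are 0.
        """
        x = np.asarray(x, dtype=float)
        W1, W2, b2 = self.unpack(theta)
        z1 = W1 @ x
        step = (z1 > 0).astype(float)
        d, p_x, p = self.d, self.p_x, self.n_params
        xnorm = np.linalg.norm(x)
        pairs = []
        for k in range(d):
            lam = step[k] * xnorm  # sqrt(step * sum x^2); step in {0,1}
            for sign in (+1.0, -1.0):
                v = np.zeros(p)
                if lam > 0:
                    u = step[k] * x
                    v[k * p_x : (k + 1) * p_x] = u / (np.sqrt(2) * np.linalg.norm(u))
                    v[d * p_x + k] = sign / np.sqrt(2)
                pairs.append((sign * lam, v))
        return pairs


def relu_hessian_eigs(model, theta, x):
    """Eigenpairs of the mean-function Hessian (ReLU net only)."""
    if not isinstance(model, ReluNet1Hidden):
        raise ValueError("Hessian eigenstructure requires a 1-hidden ReLU net")
    return model.hessian_mu_eigs(theta, x)
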