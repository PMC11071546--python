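"""Stabilizing transformations of posterior draws and their Jacobians.

Each transformation is a perturbative bijection ``T(theta) = theta +
h * Q(theta)`` that nudges the full-data posterior sample toward the
leave-one-out posterior of a single observation:

* ``PMM1`` / ``PMM2`` — partial moment matching: shift (and rescale)
  the draws a fraction ``hbar`` of the way toward the importance-weighted
  mean (and variance).  ``MM1`` / ``MM2`` are the ``hbar = 1`` special
  cases (implemented by delegation).
* ``KL`` / ``Var`` — single forward-Euler steps along gradient flows
  minimizing, respectively, the KL divergence to the LOO target and the
  variance of the importance-sampling estimator of the complement
  outcome probability.  For sigmoidal models both reduce to
  ``Q = (-1)^y * posterior(theta) * exp(c*mu*(1-2y)) * grad(mu)`` with
  ``c = 1`` (KL) or ``c = 2`` (Var).
* ``LL`` — a comparison baseline stepping down the left-out point's
  log-likelihood gradient, ``Q = (sigmoid(mu) - y) * grad(mu)``.

``Q`` is carried as a (sign, log-magnitude, direction) decomposition
because the unnormalized posterior density factor overflows double
precision on misclassified points; the step-size rule and the realized
step ``h*Q`` are formed in log space and exponentiated last.  The
unknown posterior normalizer is absorbed into the step size, so all
outputs are invariant to adding a constant to the log posterior.

The step-size rule caps the move at ``hbar`` posterior standard
deviations in every parameter component:
``h = hbar * min_{k,alpha} sd[alpha] / |Q(theta_k)[alpha]|``.

Log-Jacobian determinants come from (a) a generic first-order rule
``log|1 + h div(Q)|``, (b) the exact rank-one formula for logistic
regression, or (c) an exact small-dense-matrix computation in the
(<= 2d+2)-dimensional subspace spanned by the ReLU Hessian eigenvectors
and the two rank-one factor vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import LogisticRegression, ReluNet1Hidden, log_sigmoid, sigmoid
from .sample_io import Dataset, PosteriorDraws

__all__ = [
    "TransformResult",
    "DegenerateTransformError",
    "pmm1",
    "pmm2",
    "mm1",
    "mm2",
    "q_kl",
    "q_var",
    "q_ll",
    "step_size",
    "apply_gradient_transform",
    "jac_logdet_first_order",
    "jac_logdet_lr_exact",
    "jac_logdet_relu_exact",
    "divergence_q",
]

GRADIENT_METHODS = ("KL", "Var", "LL")
MOMENT_METHODS = ("PMM1", "PMM2", "MM1", "MM2")
METHOD_LABELS = MOMENT_METHODS + GRADIENT_METHODS + ("identity",)

#: exponent multiplier c in the sigmoidal closed forms
_C = {"KL": 1.0, "Var": 2.0}


class DegenerateTransformError(ValueError):
    """The map is not bijective at the requested step size."""


@dataclass(frozen=True)
class TransformResult:
    """Transformed draws ``phi = T(theta)`` with per-draw log-Jacobians."""

    phi: np.ndarray
    log_jac: np.ndarray
    method: str
    h: float
    hbar: float
    observation: int = -1

    def __post_init__(self):
        if self.method not in METHOD_LABELS:
            raise ValueError(f"unknown method label {self.method!r}")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("transformed draws contain non-finite values")
        if not np.all(np.isfinite(self.log_jac)):
            raise ValueError("log-Jacobians contain non-finite values")


def _draws_matrix(draws) -> np.ndarray:
    return draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)


def identity_result(draws, observation: int = -1, method: str = "identity"):
    theta = _draws_matrix(draws)
    return TransformResult(
        phi=theta,
        log_jac=np.zeros(theta.shape[0]),
        method=method,
        h=0.0,
        hbar=0.0,
        observation=observation,
    )


# ---------------------------------------------------------------------------
# partial moment matching


def _weighted_moments(theta: np.ndarray, nu: np.ndarray):
    nu = np.asarray(nu, dtype=float)
    if abs(nu.sum() - 1.0) > 1e-8 or np.any(nu < 0):
        raise ValueError("nu must be a self-normalized weight vector")
    mean = theta.mean(axis=0)
    wmean = nu @ theta
    centered = theta - mean
    var = np.mean(centered * centered, axis=0)
    wvar = nu @ (centered * centered)
    return mean, wmean, var, wvar


def pmm1(draws, nu, hbar: float, observation: int = -1) -> TransformResult:
    """Partial first-moment match: shift all draws ``hbar`` of the way
    from the plain mean to the importance-weighted mean.  A pure
    translation, so the log-Jacobian is 0 for every draw."""
    theta = _draws_matrix(draws)
    mean, wmean, _, _ = _weighted_moments(theta, nu)
    phi = theta + hbar * (wmean - mean)
    return TransformResult(
        phi=phi,
        log_jac=np.zeros(theta.shape[0]),
        method="PMM1",
        h=float(hbar),
        hbar=float(hbar),
        observation=observation,
    )


def pmm2(draws, nu, hbar: float, observation: int = -1) -> TransformResult:
    """Partial first-and-second-moment match.

    ``phi = theta + hbar*(sqrt(vw/v) o (theta - mean) + wmean - theta)``
    with elementwise variance ratio; a diagonal affine map whose
    log-Jacobian ``sum_a log|1 + hbar*(sqrt(vw_a/v_a) - 1)|`` is the
    same for every draw.  Zero-variance components pass through
    unchanged.  ``hbar = 1`` makes the transformed sample's plain mean
    and per-component variance equal the weighted targets.
    """
    theta = _draws_matrix(draws)
    mean, wmean, var, wvar = _weighted_moments(theta, nu)
    active = var > 0
    ratio = np.ones_like(var)
    ratio[active] = np.sqrt(wvar[active] / var[active])
    diag = 1.0 + hbar * (ratio - 1.0)
    if np.any(diag[active] <= 0):
        raise DegenerateTransformError(
            "transformation not bijective: non-positive diagonal factor"
        )
    phi = theta.copy()
    phi[:, active] = (
        mean[active]
        + hbar * (wmean[active] - mean[active])
        + diag[active] * (theta[:, active] - mean[active])
    )
    log_jac = float(np.sum(np.log(diag[active])))
    return TransformResult(
        phi=phi,
        log_jac=np.full(theta.shape[0], log_jac),
        method="PMM2",
        h=float(hbar),
        hbar=float(hbar),
        observation=observation,
    )


def mm1(draws, nu, observation: int = -1) -> TransformResult:
    """Full first-moment match (the ``hbar = 1`` case of PMM1)."""
    res = pmm1(draws, nu, 1.0, observation)
    return TransformResult(res.phi, res.log_jac, "MM1", 1.0, 1.0, observation)


def mm2(draws, nu, observation: int = -1) -> TransformResult:
    """Full two-moment match (the ``hbar = 1`` case of PMM2)."""
    res = pmm2(draws, nu, 1.0, observation)
    return TransformResult(res.phi, res.log_jac, "MM2", 1.0, 1.0, observation)


# ---------------------------------------------------------------------------
# gradient-flow Q terms, in sign / log-magnitude / direction form


@dataclass(frozen=True)
class QTerm:
    """``Q = sign * exp(log_mag) * direction`` (per draw or batched)."""

    sign: np.ndarray
    log_mag: np.ndarray
    direction: np.ndarray

    def dense(self) -> np.ndarray:
        coef = self.sign * np.exp(self.log_mag)
        return np.atleast_1d(coef)[..., None] * np.atleast_2d(self.direction)


def _q_terms(model, theta_batch, x, y, data, method) -> QTerm:
    theta_batch = np.atleast_2d(theta_batch)
    mu = model.mu_all(theta_batch, np.atleast_2d(x))[:, 0]
    direction = np.array(model.grad_mu_all(theta_batch, np.asarray(x, float)))
    sgn = np.full(theta_batch.shape[0], (-1.0) ** int(y))
    if method in _C:
        c = _C[method]
        log_mag = model.log_posterior(theta_batch, data) + c * mu * (1 - 2 * y)
    elif method == "LL":
        # |sigmoid(mu) - y| = sigmoid((1-2y) mu); sign(sigma-y) = (-1)^y
        log_mag = log_sigmoid((1 - 2 * y) * mu)
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    return QTerm(sgn, log_mag, direction)


def q_kl(model, theta, observation, data: Dataset) -> QTerm:
    """KL-descent term ``Q = (-1)^y pi(theta|D) e^{mu(1-2y)} grad(mu)``."""
    x, y = observation
    return _q_terms(model, theta, x, y, data, "KL")


def q_var(model, theta, observation, data: Dataset) -> QTerm:
    """Variance-descent term (KL form with the exponent doubled)."""
    x, y = observation
    return _q_terms(model, theta, x, y, data, "Var")


def q_ll(model, theta, observation) -> QTerm:
    """Negative log-likelihood gradient of the left-out point."""
    x, y = observation
    return _q_terms(model, theta, x, y, None, "LL")


# ---------------------------------------------------------------------------
# step size


def step_size(Q_all: np.ndarray, posterior_sd: np.ndarray, hbar: float) -> float:
    """Step size capping moves at ``hbar`` posterior sd per component.

    ``h = hbar * min over draws k and components a of sd[a]/|Q[k,a]|``,
    with zero-variance components and zero Q entries excluded.  Returns
    ``nan`` (the "identity step" sentinel) when every Q entry is zero.
    """
    Q = np.atleast_2d(np.asarray(Q_all, dtype=float))
    sd = np.asarray(posterior_sd, dtype=float)
    mask = (np.abs(Q) > 0) & (sd[None, :] > 0)
    if not mask.any():
        return float("nan")
    ratios = np.where(mask, sd[None, :] / np.abs(Q), np.inf)
    return float(hbar * ratios.min())


def _log_step(log_mag, direction, sd):
    """Log-space step-size search.  Returns (L, r_max, valid) where
    ``L[k,a] = log|Q[k,a]|`` and ``r_max = max (L - log sd)``."""
    with np.errstate(divide="ignore"):
        log_absdir = np.log(np.abs(direction))
        log_sd = np.log(sd)
    L = log_mag[:, None] + log_absdir
    valid = np.isfinite(L) & (sd[None, :] > 0)
    if not valid.any():
        return L, None, valid
    r = np.where(valid, L - log_sd[None, :], -np.inf)
    return L, float(r.max()), valid


# ---------------------------------------------------------------------------
# log-Jacobian determinants


def _log_abs_1p_signed_exp(sign, t):
    """``log|1 + sign * exp(t)|``, overflow-safe and cancellation-safe."""
    t = np.asarray(t, dtype=float)
    sign = np.broadcast_to(np.asarray(sign, dtype=float), t.shape)
    out = np.empty_like(t)
    pos = sign >= 0
    out[pos] = np.logaddexp(0.0, t[pos])
    tn = t[~pos]
    with np.errstate(divide="ignore", over="ignore"):
        val = np.where(tn > 50.0, tn, np.log(np.abs(np.expm1(np.minimum(tn, 50.0)))))
    out[~pos] = val
    return out


def jac_logdet_first_order(divergence: float, h: float) -> float:
    """First-order log-Jacobian ``log|1 + h * div(Q)|`` (error O(h^2))."""
    arg = 1.0 + h * divergence
    if arg == 0.0:
        raise DegenerateTransformError(
            "degenerate first-order Jacobian; reduce h"
        )
    return float(np.log(np.abs(arg)))


def divergence_q(model, theta, observation, data, method: str) -> float:
    """Divergence of Q at one draw (the models' mean functions have
    identically zero Laplacian, so only the rank-one term contributes)."""
    x, y = observation
    x = np.asarray(x, dtype=float)
    term = _q_terms(model, theta, x, y, data, method)
    g = term.direction[0]
    if method in _C:
        w = model.grad_log_posterior(theta, data)[0] + _C[method] * (1 - 2 * y) * g
        dot = float(w @ g)
        return float(term.sign[0] * np.exp(term.log_mag[0]) * dot)
    # LL: grad Q = sigmoid'(mu) g g' + (sigma - y) Hess(mu); tr Hess = 0
    mu = model.mu_all(np.atleast_2d(theta), np.atleast_2d(x))[0, 0]
    sp = sigmoid(mu) * (1.0 - sigmoid(mu))
    return float(sp * (g @ g))


def _rank_one_logdet(signs, log_mag, log_h, dots):
    """Batched ``log|1 + h*A*(w'g)|`` for rank-one Jacobians.

    ``dots[k] = w_k' g_k`` carries its own sign; ``h*A_k`` is carried as
    ``signs[k] * exp(log_h + log_mag[k])``.
    """
    with np.errstate(divide="ignore"):
        t = log_h + log_mag + np.log(np.abs(dots))
    total_sign = signs * np.sign(dots)
    out = np.where(np.isfinite(t), _log_abs_1p_signed_exp(total_sign, t), 0.0)
    if np.any(np.isneginf(out)):
        raise DegenerateTransformError("degenerate Jacobian; reduce h")
    return out


def jac_logdet_lr_exact(model, theta, observation, data, h, method) -> float:
    """Exact log-Jacobian for logistic regression (rank-one structure).

    ``log|1 + h (-1)^y pi(theta|D) e^{c mu (1-2y)} x'[grad log pi(theta|D)
    + c (1-2y) x]|`` with ``c = 1`` (KL) or ``2`` (Var); the LL baseline
    uses ``log|1 + h sigmoid'(mu) x'x|``.  The density is unnormalized;
    the same constant-absorption convention as the step-size rule
    applies (``h`` is the realized step).
    """
    if not isinstance(model, LogisticRegression):
        raise ValueError("exact LR Jacobian requires a logistic regression model")
    if h == 0.0:
        return 0.0
    x, y = observation
    x = np.asarray(x, dtype=float)
    theta2 = np.atleast_2d(theta)
    if method in _C:
        c = _C[method]
        v = model.grad_log_posterior(theta2, data)[0] + c * (1 - 2 * y) * x
        dot = float(x @ v)
        log_mag = float(
            model.log_posterior(theta2, data)[0]
            + c * model.mu(np.asarray(theta, float), x) * (1 - 2 * y)
        )
        sgn = (-1.0) ** int(y)
    elif method == "LL":
        mu = model.mu(np.asarray(theta, float), x)
        log_mag = float(log_sigmoid(mu) + log_sigmoid(-mu))  # log sigmoid'(mu)
        dot = float(x @ x)
        sgn = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    out = _rank_one_logdet(
        np.array([sgn]), np.array([log_mag]), float(np.log(h)), np.array([dot])
    )
    return float(out[0])


def jac_logdet_relu_exact(model, theta, observation, data, h, method) -> float:
    """Exact log-Jacobian for the one-hidden-layer ReLU net.

    ``I + h*(a*Hess(mu) + g b')`` acts as the identity on the orthogonal
    complement of ``S = span(Hessian eigenvectors, g, b)``, so the
    determinant is computed from the dense restriction to ``S``
    (dimension at most ``2d + 2``).
    """
    if not isinstance(model, ReluNet1Hidden):
        raise ValueError("exact ReLU Jacobian requires a 1-hidden ReLU net")
    if h == 0.0:
        return 0.0
    x, y = observation
    theta = np.asarray(theta, dtype=float)
    term = _q_terms(model, theta, np.asarray(x, float), y, data, method)
    g = term.direction[0]
    if method in _C:
        kappa = float(term.sign[0] * np.exp(np.log(h) + term.log_mag[0]))
        w = model.grad_log_posterior(theta, data)[0] + _C[method] * (1 - 2 * y) * g
        hb = kappa * w  # h * b
        ha = kappa  # h * a  (coefficient of the Hessian)
    else:  # LL
        mu = model.mu(theta, np.asarray(x, float))
        s = sigmoid(mu)
        ha = h * float(s - y)
        hb = h * s * (1 - s) * g
    eigs = model.hessian_mu_eigs(theta, np.asarray(x, float))
    return _subspace_logdet(eigs, g, ha, hb)


def _subspace_logdet(eigs, g, ha, hb) -> float:
    cols = [v for lam, v in eigs if lam != 0.0]
    cols.append(np.asarray(g, dtype=float))
    cols.append(np.asarray(hb, dtype=float))
    B = np.column_stack(cols)
    Uq, R = np.linalg.qr(B)
    keep = np.abs(np.diag(R)) > 1e-12 * max(1.0, np.abs(np.diag(R)).max())
    U = Uq[:, keep]
    m = U.shape[1]
    if m == 0:
        return 0.0
    M = np.zeros((m, m))
    for lam, v in eigs:
        if lam != 0.0:
            uv = U.T @ v
            M += (ha * lam) * np.outer(uv, uv)
    M += np.outer(U.T @ g, U.T @ hb)
    sgn, logdet = np.linalg.slogdet(np.eye(m) + M)
    if sgn == 0:
        raise DegenerateTransformError("degenerate Jacobian; reduce h")
    return float(logdet)


# ---------------------------------------------------------------------------
# full gradient-transform application


def apply_gradient_transform(
    draws, model, data: Dataset, observation: int, method: str, hbar: float
) -> TransformResult:
    """Apply one gradient transformation (KL/Var/LL) to all draws.

    Computes Q for every draw, the step size via the at-most-``hbar``-sd
    rule, ``phi = theta + h Q``, and the best available log-Jacobian
    (exact for logistic regression and 1-hidden ReLU nets, first-order
    rank-one otherwise).  If every Q entry is zero the identity result
    is returned with ``method='identity'``.
    """
    if method not in GRADIENT_METHODS:
        raise ValueError(f"not a gradient method: {method!r}")
    theta = _draws_matrix(draws)
    x = data.X[observation]
    y = int(data.y[observation])
    term = _q_terms(model, theta, x, y, data, method)
    sd = theta.std(axis=0, ddof=1)
    L, r_max, valid = _log_step(term.log_mag, term.direction, sd)
    if r_max is None or not np.isfinite(r_max):
        return identity_result(theta, observation)
    log_h = float(np.log(hbar) - r_max)
    with np.errstate(over="ignore"):
        step = (
            term.sign[:, None]
            * np.sign(term.direction)
            * hbar
            * np.exp(L - r_max)
        )
    step[:, sd == 0] = 0.0  # zero-variance components pass through
    phi = theta + step
    log_jac = _gradient_log_jac(model, theta, term, data, x, y, log_h, method)
    return TransformResult(
        phi=phi,
        log_jac=log_jac,
        method=method,
        h=float(np.exp(log_h)),
        hbar=float(hbar),
        observation=observation,
    )


def _gradient_log_jac(model, theta, term, data, x, y, log_h, method):
    """Per-draw log-Jacobians for a batch, choosing the best rule."""
    if isinstance(model, ReluNet1Hidden):
        h = float(np.exp(log_h))
        return np.array(
            [
                jac_logdet_relu_exact(model, theta[k], (x, y), data, h, method)
                for k in range(theta.shape[0])
            ]
        )
    # logistic regression (exact) and generic models (first-order) share
    # the rank-one formula because the mean-function Laplacian vanishes
    g = term.direction
    if method in _C:
        w = model.grad_log_posterior(theta, data) + _C[method] * (1 - 2 * y) * g
        dots = np.einsum("kp,kp->k", g, w)
        return _rank_one_logdet(term.sign, term.log_mag, log_h, dots)
    # LL: h * sigmoid'(mu) * |g|^2, always positive
    mu = model.mu_all(theta, np.atleast_2d(x))[:, 0]
    log_sp = log_sigmoid(mu) + log_sigmoid(-mu)
    dots = np.einsum("kp,kp->k", g, g)
    return _rank_one_logdet(np.ones(theta.shape[0]), log_sp, log_h, dots)
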