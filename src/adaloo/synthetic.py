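"""Synthetic classification problems, lightweight samplers, and refit oracles.

The generator emulates the few-observations / many-predictors (n << p)
binary classification regime in which leave-one-out importance weights
are characteristically heavy tailed: i.i.d. standard-normal covariates
(optionally with an equicorrelation block mimicking microarray-style
multicollinearity), a sparse true coefficient vector, and Bernoulli
labels through the logistic link.  The default unstable regime is a
scaled-down n=50, p_x=300 problem that reliably produces observations
with Pareto tail shape above 0.7, so the stabilizing transformations
are actually exercised.

Two posterior "truth" channels support testing:

* a deterministic quadrature grid (parameter dimension <= 2), treated
  as exact, with i.i.d. resampling of draws from the grid masses;
* an adaptive random-walk Metropolis sampler (any dimension), whose
  scale adaptation is frozen after warmup so detailed balance holds for
  the retained draws.

``brute_force_loo`` refits (re-runs the sampler or quadrature) on every
leave-one-out fold — exactly the computation the adaptive importance
sampler is designed to avoid — and is the package's acceptance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .models import GaussianPrior, StudentTPrior, sigmoid
from .sample_io import Dataset, PosteriorDraws

__all__ = [
    "SyntheticSpec",
    "generate_classification",
    "GridPosterior",
    "grid_posterior_sampler",
    "mh_posterior_sampler",
    "brute_force_loo",
    "unstable_regime_problem",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic binary-classification problem.

    ``regime="unstable_npp"`` requires ``p_x > n`` (the n << p setting);
    ``rho`` adds a single equicorrelation block across all covariates.
    """

    n: int = 50
    p_x: int = 300
    sparsity: int = 5
    effect_size: float = 2.0
    regime: str = "unstable_npp"
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("stable", "unstable_npp"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "unstable_npp" and self.p_x <= self.n:
            raise ValueError("unstable_npp regime requires p_x > n")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


def generate_classification(spec: SyntheticSpec):
    """Draw a synthetic dataset; a pure function of ``spec.seed``.

    Returns ``(Dataset, true_theta)`` where ``true_theta`` has
    ``spec.sparsity`` entries of alternating sign ``+-effect_size`` at
    random positions and zeros elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p_x))
    if spec.rho > 0:
        shared = rng.standard_normal((spec.n, 1))
        X = np.sqrt(1 - spec.rho) * X + np.sqrt(spec.rho) * shared
    beta = np.zeros(spec.p_x)
    idx = rng.choice(spec.p_x, size=spec.sparsity, replace=False)
    signs = np.where(np.arange(spec.sparsity) % 2 == 0, 1.0, -1.0)
    beta[idx] = signs * spec.effect_size
    probs = sigmoid(X @ beta)
    y = (rng.uniform(size=spec.n) < probs).astype(int)
    return Dataset(X, y), beta


# ---------------------------------------------------------------------------
# quadrature truth channel (p <= 2)


class GridPosterior:
    """Deterministic quadrature grid over an unnormalized log posterior.

    The grid is centered on the MAP with half-width ``width_sd`` Laplace
    standard deviations per dimension.  Grid-weighted expectations are
    the package's "exact" truth channel for 1- and 2-parameter models.
    """

    def __init__(self, model, data, n_grid: int = 201, width_sd: float = 8.0):
        p = model.n_params
        if p > 2:
            raise ValueError("quadrature grid supports at most 2 parameters")
        self.model = model
        self.data = data
        mode, hess_diag = _laplace_mode(model, data)
        sds = 1.0 / np.sqrt(np.maximum(hess_diag, 1e-8))
        axes = [
            np.linspace(mode[a] - width_sd * sds[a], mode[a] + width_sd * sds[a], n_grid)
            for a in range(p)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        self.points = np.column_stack([m.ravel() for m in mesh])
        self.log_post = model.log_posterior(self.points, data)
        self._log_norm = logsumexp(self.log_post)
        self.log_prob = self.log_post - self._log_norm
        self.prob = np.exp(self.log_prob)
        self.axes = axes
        self._log_dx = float(sum(np.log(ax[1] - ax[0]) for ax in axes))

    @property
    def log_norm(self) -> float:
        """Log model evidence by midpoint quadrature (sum times cell volume)."""
        return float(self._log_norm + self._log_dx)

    def expectation(self, values: np.ndarray) -> float:
        """Quadrature expectation of per-point values under the posterior."""
        return float(self.prob @ np.asarray(values, dtype=float))

    def mean(self) -> np.ndarray:
        return self.prob @ self.points

    def reweight(self, delta_log: np.ndarray) -> "GridPosterior":
        """A new grid posterior with ``delta_log`` added to the log density
        (used to drop one observation's log-likelihood for LOO truths)."""
        out = object.__new__(GridPosterior)
        out.model, out.data, out.points, out.axes = (
            self.model,
            self.data,
            self.points,
            self.axes,
        )
        out.log_post = self.log_post + np.asarray(delta_log, dtype=float)
        out._log_dx = self._log_dx
        out._log_norm = logsumexp(out.log_post)
        out.log_prob = out.log_post - out._log_norm
        out.prob = np.exp(out.log_prob)
        return out

    def resample(self, s: int, seed: int) -> PosteriorDraws:
        """I.i.d. resampling of ``s`` draws from the grid masses."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.points.shape[0], size=s, p=self.prob)
        names = tuple(f"theta{a}" for a in range(self.points.shape[1]))
        return PosteriorDraws(self.points[idx], names)


def grid_posterior_sampler(model, data, s: int = 4000, seed: int = 0, n_grid: int = 201):
    """Build the quadrature grid and resample ``s`` i.i.d. draws from it.

    Returns ``(PosteriorDraws, GridPosterior)`` — the grid is the truth
    channel for quadrature expectations.
    """
    grid = GridPosterior(model, data, n_grid=n_grid)
    return grid.resample(s, seed), grid


def _laplace_mode(model, data):
    """MAP point and diagonal curvature via quasi-Newton optimization."""
    p = model.n_params

    def negative(theta):
        return -float(model.log_posterior(theta[None, :], data)[0])

    def grad(theta):
        return -model.grad_log_posterior(theta[None, :], data)[0]

    res = optimize.minimize(negative, np.zeros(p), jac=grad, method="L-BFGS-B")
    mode = res.x
    eps = 1e-4
    hess_diag = np.empty(p)
    for a in range(p):
        e = np.zeros(p)
        e[a] = eps
        hess_diag[a] = (grad(mode + e)[a] - grad(mode - e)[a]) / (2 * eps)
    return mode, np.abs(hess_diag)


# ---------------------------------------------------------------------------
# Metropolis sampler (any dimension)


def mh_posterior_sampler(
    model,
    data,
    n_draws: int = 1000,
    seed: int = 0,
    warmup: int = 2000,
    thin: int = 10,
    source: str = "mcmc",
) -> PosteriorDraws:
    """Adaptive random-walk Metropolis targeting the unnormalized posterior.

    Starts at the MAP.  During warmup a global proposal scale adapts
    toward ~23% acceptance and per-component scales track the running
    posterior spread; both are frozen afterward, so the retained
    (thinned) draws satisfy detailed balance.
    """
    rng = np.random.default_rng(seed)
    p = model.n_params
    mode, hess_diag = _laplace_mode(model, data)
    comp_sd = 1.0 / np.sqrt(np.maximum(hess_diag, 1e-8))
    log_scale = np.log(2.38 / np.sqrt(p))
    theta = mode.copy()
    lp = float(model.log_posterior(theta[None, :], data)[0])

    # Welford running moments for component scales
    mean = theta.copy()
    m2 = np.zeros(p)

    def propose(scale):
        return theta + scale * comp_sd * rng.standard_normal(p)

    for t in range(1, warmup + 1):
        prop = propose(np.exp(log_scale))
        lp_prop = float(model.log_posterior(prop[None, :], data)[0])
        accept = np.log(rng.uniform()) < lp_prop - lp
        if accept:
            theta, lp = prop, lp_prop
        log_scale += (1.0 if accept else 0.0) / np.sqrt(t) - 0.234 / np.sqrt(t)
        delta = theta - mean
        mean += delta / t
        m2 += delta * (theta - mean)
        if t == warmup // 2 and t > 10:
            est = np.sqrt(m2 / t)
            comp_sd = np.where(est > 0, est, comp_sd)

    scale = np.exp(log_scale)
    out = np.empty((n_draws, p))
    n_accept = 0
    for k in range(n_draws):
        for _ in range(thin):
            prop = propose(scale)
            lp_prop = float(model.log_posterior(prop[None, :], data)[0])
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                n_accept += 1
        out[k] = theta
    names = tuple(f"theta{a}" for a in range(p))
    return PosteriorDraws(out, names, source=source)


# ---------------------------------------------------------------------------
# brute-force LOO oracle


@dataclass(frozen=True)
class LOOTruthRecord:
    index: int
    p_loo: float
    p_loo_se: float
    elpd: float
    elpd_se: float


def brute_force_loo(model, data, method: str = "grid", **sampler_kwargs):
    """Refit-based LOO truths: one posterior refit per left-out point.

    ``method="grid"`` (p <= 2) reuses a single full-data quadrature grid
    and removes one observation's log-likelihood column per fold — exact
    up to grid resolution, so standard errors are 0.  ``method="mh"``
    re-runs the Metropolis sampler per fold and reports naive
    Monte-Carlo standard errors (draws are thinned toward independence).
    Returns one :class:`LOOTruthRecord` per observation.
    """
    n = data.n_obs
    records = []
    if method == "grid":
        grid = GridPosterior(model, data, **sampler_kwargs)
        ll = model.loglik_all(grid.points, data)  # (n_points, n)
        for i in range(n):
            loo = grid.reweight(-ll[:, i])
            p_i = sigmoid(model.mu_all(grid.points, data.X[i : i + 1])[:, 0])
            p_loo = loo.expectation(p_i)
            elpd = float(logsumexp(loo.log_prob + ll[:, i]))
            records.append(LOOTruthRecord(i, p_loo, 0.0, elpd, 0.0))
        return records
    if method != "mh":
        raise ValueError(f"unknown refit method {method!r}")
    seed = int(sampler_kwargs.pop("seed", 0))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = Dataset(data.X[mask], data.y[mask])
        draws = mh_posterior_sampler(model, fold, seed=seed + i, **sampler_kwargs)
        s = draws.n_draws
        p_i = sigmoid(model.mu_all(draws.draws, data.X[i : i + 1])[:, 0])
        lik_i = np.exp(model.loglik_all(draws.draws, data)[:, i])
        p_loo = float(p_i.mean())
        p_se = float(p_i.std(ddof=1) / np.sqrt(s))
        m = float(lik_i.mean())
        m_se = float(lik_i.std(ddof=1) / np.sqrt(s))
        records.append(
            LOOTruthRecord(i, p_loo, p_se, float(np.log(m)), m_se / m)
        )
    return records


# ---------------------------------------------------------------------------
# canonical unstable-regime problem


def unstable_regime_problem(seed: int, n: int = 50, p_x: int = 300, s: int = 1000):
    """Dataset + draws + model for the scaled-down n << p experiment.

    Logistic regression with a Student-t shrinkage prior; posterior
    draws from the adaptive Metropolis sampler.  Everything derives
    from ``seed``.
    """
    from .models import LogisticRegression

    spec = SyntheticSpec(n=n, p_x=p_x, sparsity=5, effect_size=2.0, seed=seed)
    data, beta = generate_classification(spec)
    model = LogisticRegression(p_x, prior=StudentTPrior(df=3.0, scale=0.5))
    draws = mh_posterior_sampler(
        model, data, n_draws=s, seed=seed + 1, warmup=3000, thin=25
    )
    return data, draws, model, beta
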