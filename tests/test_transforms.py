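import numpy as np
import pytest

from adaloo import psis, transforms
from adaloo.models import GaussianPrior, LogisticRegression, ReluNet1Hidden, sigmoid
from adaloo.sample_io import Dataset

from conftest import fd_grad, fd_jacobian_logdet


def uniform_nu(s):
    return np.full(s, 1.0 / s)


def random_nu(rng, s):
    return psis.self_normalize(rng.standard_normal(s))


class TestPMM1:
    def test_zero_step_identity(self, rng):
        theta = rng.standard_normal((20, 3))
        res = transforms.pmm1(theta, random_nu(rng, 20), 0.0)
        np.testing.assert_array_equal(res.phi, theta)
        np.testing.assert_array_equal(res.log_jac, 0.0)

    def test_uniform_nu_identity(self, rng):
        theta = rng.standard_normal((20, 3))
        res = transforms.pmm1(theta, uniform_nu(20), 1.0)
        np.testing.assert_allclose(res.phi, theta, atol=1e-12)

    def test_full_step_moment_match(self, rng):
        theta = rng.standard_normal((50, 4))
        nu = random_nu(rng, 50)
        res = transforms.pmm1(theta, nu, 1.0)
        np.testing.assert_allclose(res.phi.mean(axis=0), nu @ theta, atol=1e-12)


class TestPMM2:
    def test_zero_step_identity(self, rng):
        theta = rng.standard_normal((30, 3))
        res = transforms.pmm2(theta, random_nu(rng, 30), 0.0)
        np.testing.assert_allclose(res.phi, theta, atol=1e-14)
        np.testing.assert_array_equal(res.log_jac, 0.0)

    def test_full_step_matches_both_moments(self, rng):
        theta = rng.standard_normal((60, 4))
        nu = random_nu(rng, 60)
        res = transforms.pmm2(theta, nu, 1.0)
        mean = theta.mean(axis=0)
        centered = theta - mean
        target_var = nu @ (centered**2)
        np.testing.assert_allclose(res.phi.mean(axis=0), nu @ theta, atol=1e-12)
        np.testing.assert_allclose(
            np.mean((res.phi - res.phi.mean(axis=0)) ** 2, axis=0),
            target_var,
            rtol=1e-12,
        )

    def test_already_matched_is_identity(self, rng):
        theta = rng.standard_normal((40, 2))
        res = transforms.pmm2(theta, uniform_nu(40), 0.7)
        np.testing.assert_allclose(res.phi, theta, atol=1e-12)

    def test_log_jac_is_diagonal_affine(self, rng):
        theta = rng.standard_normal((40, 3))
        nu = random_nu(rng, 40)
        hbar = 0.5
        res = transforms.pmm2(theta, nu, hbar)
        mean = theta.mean(axis=0)
        v = np.mean((theta - mean) ** 2, axis=0)
        vw = nu @ ((theta - mean) ** 2)
        expect = np.sum(np.log(np.abs(1 + hbar * (np.sqrt(vw / v) - 1))))
        np.testing.assert_allclose(res.log_jac, expect, rtol=1e-12)


class TestQTerms:
    def test_well_classified_point_barely_moves(self, lr_problem):
        model, data, _ = lr_problem
        # y=1 with mu -> +inf: e^{-mu} factor kills Q
        x = data.X[0]
        big = 50.0 * x / (x @ x)
        t_small = transforms.q_kl(model, big, (x, 1), data)
        t_big = transforms.q_kl(model, 5.0 * big, (x, 1), data)
        assert t_big.log_mag[0] < t_small.log_mag[0]

    def test_label_flips_sign(self, lr_problem):
        model, data, draws = lr_problem
        x = data.X[1]
        t0 = transforms.q_kl(model, draws[0], (x, 0), data)
        t1 = transforms.q_kl(model, draws[0], (x, 1), data)
        assert t0.sign[0] == -t1.sign[0]

    def test_var_equals_kl_at_mu_zero(self, rng):
        model = LogisticRegression(2, prior=GaussianPrior(1.0))
        data = Dataset(rng.standard_normal((4, 2)), np.array([0, 1, 0, 1]))
        x = rng.standard_normal(2)
        th = np.zeros(2)
        perp = np.array([-x[1], x[0]])  # mu(th)=0 along x-perp too; use th with mu=0
        kl = transforms.q_kl(model, th, (x, 1), data)
        var = transforms.q_var(model, th, (x, 1), data)
        assert kl.log_mag[0] == pytest.approx(var.log_mag[0], rel=1e-12)

    def test_var_exceeds_kl_when_misclassified(self, lr_problem):
        model, data, _ = lr_problem
        x = data.X[2]
        th = -2.0 * x / (x @ x)  # mu = -2, y = 1: misclassified
        kl = transforms.q_kl(model, th, (x, 1), data)
        var = transforms.q_var(model, th, (x, 1), data)
        assert var.log_mag[0] > kl.log_mag[0]

    def test_kl_matches_density_times_grad_inverse_lik(self, lr_problem):
        """Q_KL equals posterior density times grad(1/likelihood), the
        gradient-flow composite form, via finite differences."""
        model, data, draws = lr_problem
        for i in (0, 3):
            x, y = data.X[i], int(data.y[i])
            th = draws[2]
            term = transforms.q_kl(model, th, (x, y), data)
            Q = term.dense()[0]

            def inv_lik(t):
                return np.exp(-model.log_likelihood(t, x, y))

            dens = np.exp(model.log_posterior(th[None], data)[0])
            expect = dens * fd_grad(inv_lik, th)
            np.testing.assert_allclose(Q, expect, rtol=1e-5, atol=1e-12)

    def test_var_matches_composite_form(self, lr_problem):
        """Q_Var equals density * (f/lik) * grad(f/lik) with f the
        complement-probability function."""
        model, data, draws = lr_problem
        for i in (1, 4):
            x, y = data.X[i], int(data.y[i])
            th = draws[5]
            term = transforms.q_var(model, th, (x, y), data)
            Q = term.dense()[0]

            def f_over_lik(t):
                p = sigmoid(model.mu(t, x))
                f = p ** (1 - y) * (1 - p) ** y
                lik = p**y * (1 - p) ** (1 - y)
                return f / lik

            dens = np.exp(model.log_posterior(th[None], data)[0])
            expect = dens * f_over_lik(th) * fd_grad(f_over_lik, th)
            np.testing.assert_allclose(Q, expect, rtol=1e-5, atol=1e-12)

    def test_ll_closed_form_and_fd(self, lr_problem):
        model, data, draws = lr_problem
        # mu=0, y=1, x=(2,0,...) -> Q = -0.5*x
        x = np.zeros(data.n_covariates)
        x[0] = 2.0
        term = transforms.q_ll(model, np.zeros(data.n_covariates), (x, 1))
        np.testing.assert_allclose(term.dense()[0], -0.5 * x, rtol=1e-12)
        # general: Q = -grad log lik by finite differences
        xi, yi = data.X[0], int(data.y[0])
        th = draws[3]
        Q = transforms.q_ll(model, th, (xi, yi)).dense()[0]
        fd = -fd_grad(lambda t: model.log_likelihood(t, xi, yi), th)
        np.testing.assert_allclose(Q, fd, rtol=1e-5, atol=1e-9)


class TestStepSize:
    def test_forced_by_sd_rule(self):
        h = transforms.step_size(np.array([[2.0]]), np.array([1.0]), 1.0)
        assert h == 0.5

    def test_homogeneity(self, rng):
        Q = rng.standard_normal((10, 3))
        sd = np.abs(rng.standard_normal(3)) + 0.1
        h = transforms.step_size(Q, sd, 0.5)
        assert transforms.step_size(10 * Q, sd, 0.5) == pytest.approx(h / 10, rel=1e-12)
        assert transforms.step_size(Q, 2 * sd, 0.5) == pytest.approx(2 * h, rel=1e-12)
        assert transforms.step_size(Q, sd, 1.0) == pytest.approx(2 * h, rel=1e-12)

    def test_binding_constraint(self, rng):
        Q = rng.standard_normal((20, 4))
        sd = np.abs(rng.standard_normal(4)) + 0.1
        hbar = 0.25
        h = transforms.step_size(Q, sd, hbar)
        assert np.max(np.abs(h * Q) / sd) == pytest.approx(hbar, rel=1e-12)

    def test_all_zero_sentinel(self):
        assert np.isnan(transforms.step_size(np.zeros((5, 2)), np.ones(2), 1.0))


class TestApplyGradientTransform:
    @pytest.mark.parametrize("method", ["KL", "Var", "LL"])
    def test_small_hbar_limit(self, lr_problem, method):
        model, data, draws = lr_problem
        res = transforms.apply_gradient_transform(draws, model, data, 0, method, 1e-9)
        np.testing.assert_allclose(res.phi, draws, atol=1e-7)
        np.testing.assert_allclose(res.log_jac, 0.0, atol=1e-7)

    def test_binding_step_contract(self, lr_problem):
        """Max move is exactly hbar posterior sd in the binding component."""
        model, data, draws = lr_problem
        sd = draws.std(axis=0, ddof=1)
        for hbar in (1.0, 0.25, 4.0**-5):
            res = transforms.apply_gradient_transform(draws, model, data, 1, "KL", hbar)
            ratio = np.abs(res.phi - draws) / sd
            assert np.max(ratio) == pytest.approx(hbar, rel=1e-13)

    def test_invariant_to_posterior_constant(self, lr_problem):
        """Absorbing the normalizer into h: shifting the log posterior by
        any constant leaves phi and log_jac unchanged."""
        model, data, draws = lr_problem

        class ShiftedPrior:
            def __init__(self, base, c):
                self.base, self.c = base, c

            def log_density(self, t):
                return self.base.log_density(t) + self.c

            def grad_log_density(self, t):
                return self.base.grad_log_density(t)

        shifted = LogisticRegression(
            model.n_params, prior=ShiftedPrior(model.prior, 321.5)
        )
        for method in ("KL", "Var"):
            a = transforms.apply_gradient_transform(draws, model, data, 2, method, 0.5)
            b = transforms.apply_gradient_transform(draws, shifted, data, 2, method, 0.5)
            np.testing.assert_allclose(a.phi, b.phi, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(a.log_jac, b.log_jac, rtol=1e-9, atol=1e-10)

    def test_moves_where_q_nonzero(self, lr_problem):
        model, data, draws = lr_problem
        res = transforms.apply_gradient_transform(draws, model, data, 0, "KL", 0.5)
        x = data.X[0]
        moved = np.abs(res.phi - draws) > 0
        assert np.all(moved[:, np.abs(x) > 0])


def make_T(model, data, x, y, method, h):
    def T(t):
        term = transforms._q_terms(model, t[None, :], x, y, data, method)
        return t + h * term.dense()[0]

    return T


class TestExactLRJacobian:
    @pytest.mark.parametrize("method", ["KL", "Var"])
    def test_matches_fd_jacobian_100_configs(self, method, rng):
        p, n = 5, 6
        count = 0
        while count < 100:
            model = LogisticRegression(p, prior=GaussianPrior(1.0))
            X = rng.standard_normal((n, p))
            y = (rng.uniform(size=n) < 0.5).astype(int)
            data = Dataset(X, y)
            th = rng.standard_normal(p) * 0.6
            i = int(rng.integers(n))
            xi, yi = X[i], int(y[i])
            Q = transforms._q_terms(model, th[None, :], xi, yi, data, method).dense()[0]
            qmax = np.max(np.abs(Q))
            if qmax == 0:
                continue
            count += 1
            h = 0.1 / qmax
            exact = transforms.jac_logdet_lr_exact(model, th, (xi, yi), data, h, method)
            fd = fd_jacobian_logdet(make_T(model, data, xi, yi, method, h), th)
            assert exact == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_zero_h_and_zero_covariate(self, lr_problem):
        model, data, draws = lr_problem
        assert transforms.jac_logdet_lr_exact(
            model, draws[0], (data.X[0], 1), data, 0.0, "KL"
        ) == 0.0
        x0 = np.zeros(data.n_covariates)
        assert transforms.jac_logdet_lr_exact(
            model, draws[0], (x0, 1), data, 0.3, "KL"
        ) == 0.0

    def test_wrong_model_kind(self, relu_problem):
        model, data, draws = relu_problem
        with pytest.raises(ValueError):
            transforms.jac_logdet_lr_exact(model, draws[0], (data.X[0], 1), data, 0.1, "KL")


class TestExactReluJacobian:
    @pytest.mark.parametrize("method", ["KL", "Var", "LL"])
    def test_matches_fd_jacobian_50_configs(self, method, rng):
        d, p_x, n = 3, 4, 5
        model = ReluNet1Hidden(d, p_x, prior=GaussianPrior(1.0))
        count = 0
        while count < 50:
            X = rng.standard_normal((n, p_x))
            y = (rng.uniform(size=n) < 0.5).astype(int)
            data = Dataset(X, y)
            th = rng.standard_normal(model.n_params) * 0.7
            i = int(rng.integers(n))
            xi, yi = X[i], int(y[i])
            z1 = model.unpack(th)[0] @ xi
            if np.min(np.abs(z1)) < 1e-2:  # avoid activation kinks for FD
                continue
            Q = transforms._q_terms(model, th[None, :], xi, yi, data, method).dense()[0]
            qmax = np.max(np.abs(Q))
            if qmax == 0:
                continue
            count += 1
            h = 0.05 / qmax
            exact = transforms.jac_logdet_relu_exact(model, th, (xi, yi), data, h, method)
            fd = fd_jacobian_logdet(make_T(model, data, xi, yi, method, h), th)
            assert exact == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_dead_network_collapses_to_rank_one(self, rng):
        d, p_x = 2, 3
        model = ReluNet1Hidden(d, p_x, prior=GaussianPrior(1.0))
        X = np.abs(rng.standard_normal((4, p_x)))
        y = np.array([0, 1, 0, 1])
        data = Dataset(X, y)
        W1 = -np.ones((d, p_x))  # all units dead on positive x
        th = model.pack(W1, rng.standard_normal(d), 0.4)
        xi, yi = X[1], 1
        h = 1e-2
        exact = transforms.jac_logdet_relu_exact(model, th, (xi, yi), data, h, "KL")
        # rank-one formula: Hessian gone, g has only the b2 component
        g = model.grad_mu(th, xi)
        w = model.grad_log_posterior(th[None], data)[0] + (1 - 2 * yi) * g
        A = (-1.0) ** yi * np.exp(
            model.log_posterior(th[None], data)[0] + model.mu(th, xi) * (1 - 2 * yi)
        )
        expect = np.log(abs(1 + h * A * (g @ w)))
        assert exact == pytest.approx(expect, rel=1e-10)

    def test_zero_h(self, relu_problem):
        model, data, draws = relu_problem
        assert transforms.jac_logdet_relu_exact(
            model, draws[0], (data.X[0], 0), data, 0.0, "Var"
        ) == 0.0


class TestFirstOrderJacobian:
    def test_closed_forms(self):
        assert transforms.jac_logdet_first_order(-1.0, 0.0) == 0.0
        assert transforms.jac_logdet_first_order(-1.0, 0.5) == pytest.approx(np.log(0.5))
        with pytest.raises(transforms.DegenerateTransformError):
            transforms.jac_logdet_first_order(-1.0, 1.0)

    def test_exact_for_logistic_regression(self, lr_problem):
        """For LR the Jacobian of Q is rank one, so the first-order rule
        coincides with the exact determinant identically."""
        model, data, draws = lr_problem
        for method in ("KL", "Var", "LL"):
            for k in range(5):
                th = draws[k]
                xi, yi = data.X[1], int(data.y[1])
                div = transforms.divergence_q(model, th, (xi, yi), data, method)
                if div == 0:
                    continue
                h = 0.01 / abs(div)
                ex = transforms.jac_logdet_lr_exact(model, th, (xi, yi), data, h, method)
                fo = transforms.jac_logdet_first_order(div, h)
                assert ex == pytest.approx(fo, abs=1e-12)

    def test_second_order_convergence_on_relu(self, rng):
        """Against the exact ReLU rule the truncation error decays as
        O(h^2): fitted log-log slope 2 +- 0.1."""
        d, p_x, n = 3, 4, 5
        model = ReluNet1Hidden(d, p_x, prior=GaussianPrior(1.0))
        slopes = []
        while len(slopes) < 5:
            X = rng.standard_normal((n, p_x))
            y = (rng.uniform(size=n) < 0.5).astype(int)
            data = Dataset(X, y)
            th = rng.standard_normal(model.n_params) * 0.7
            i = int(rng.integers(n))
            xi, yi = X[i], int(y[i])
            div = transforms.divergence_q(model, th, (xi, yi), data, "KL")
            if div == 0:
                continue
            hs = np.array([1e-2, 1e-3, 1e-4, 1e-5]) / abs(div)
            errs = []
            for h in hs:
                ex = transforms.jac_logdet_relu_exact(model, th, (xi, yi), data, h, "KL")
                fo = transforms.jac_logdet_first_order(div, h)
                errs.append(abs(ex - fo))
            if min(errs) < 1e-14:  # rank-one config: rule already exact
                continue
            slopes.append(np.polyfit(np.log(hs), np.log(errs), 1)[0])
        assert all(abs(s - 2.0) <= 0.1 for s in slopes)
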