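"""Caputo fractional gradient kernel: scale, quadrature, derivative assembly."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from csacfgd.fractional import (
    FractionalConfig,
    ReferencePoint,
    build_quadrature,
    caputo_gradient,
    caputo_scale,
    directional_derivatives,
)


def adaptive_weighted_integral(func, alpha):
    """Independent oracle: adaptive integration of f(u) (1-u)^(-alpha) on [-1, 1]."""
    val, _ = quad(func, -1.0, 1.0, weight="alg", wvar=(0.0, -alpha))
    return val


class TestCaputoScale:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(1.0, 0.0), (1e-12, 0.5), (0.5, 0.5 * 2 ** -0.5)],
    )
    def test_formula(self, alpha, expected):
        assert caputo_scale(alpha) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("alpha", [0.0, -0.3, 1.2])
    def test_domain(self, alpha):
        with pytest.raises(ValueError):
            caputo_scale(alpha)


class TestQuadrature:
    def test_alpha_zero_single_point_is_midpoint_legendre(self):
        rule = build_quadrature(0.0, 1)
        assert rule.nodes[0] == pytest.approx(0.0, abs=1e-12)
        assert rule.weights[0] == pytest.approx(2.0, rel=1e-12)

    def test_single_point_matches_moment_ratio(self):
        # one-point Gauss rule: node = m1/m0, weight = m0
        alpha = 0.5
        m0 = adaptive_weighted_integral(lambda u: 1.0, alpha)
        m1 = adaptive_weighted_integral(lambda u: u, alpha)
        rule = build_quadrature(alpha, 1)
        assert rule.nodes[0] == pytest.approx(m1 / m0, rel=1e-10)
        assert rule.weights[0] == pytest.approx(m0, rel=1e-10)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("n_quad", [1, 2, 3, 5])
    def test_moments_match_adaptive_integration(self, alpha, n_quad):
        rule = build_quadrature(alpha, n_quad)
        for p in range(2 * n_quad):
            exact = adaptive_weighted_integral(lambda u: u**p, alpha)
            approx = float(np.sum(rule.weights * rule.nodes**p))
            assert approx == pytest.approx(exact, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.2, 0.7])
    def test_structure_invariants(self, alpha):
        rule = build_quadrature(alpha, 8)
        assert np.all(rule.weights > 0)
        assert np.all((rule.nodes > -1) & (rule.nodes < 1))
        assert np.all(np.diff(rule.nodes) > 0)
        assert np.sum(rule.weights) == pytest.approx(
            2.0 ** (1 - alpha) / (1 - alpha), rel=1e-10
        )

    def test_non_integrable_weight_rejected(self):
        with pytest.raises(ValueError):
            build_quadrature(1.0, 4)


class TestDirectionalDerivatives:
    def test_quadratic(self):
        d1, d2 = directional_derivatives(lambda z: z[0] ** 2, np.array([5.0]), 0, 1.0, 1e-5)
        assert d1 == pytest.approx(2.0, rel=1e-6)
        assert d2 == pytest.approx(2.0, rel=1e-4)

    def test_constant(self):
        d1, d2 = directional_derivatives(lambda z: 4.2, np.array([1.0, 2.0]), 1, 0.3, 1e-5)
        assert d1 == 0.0 and d2 == 0.0

    def test_sine(self):
        d1, d2 = directional_derivatives(
            lambda z: float(np.sin(z[0])), np.array([0.0]), 0, 0.0, 1e-4
        )
        assert d1 == pytest.approx(1.0, abs=1e-7)
        assert d2 == pytest.approx(0.0, abs=1e-4)

    def test_non_finite_objective_names_coordinate(self):
        with pytest.raises(FloatingPointError, match="coordinate 1"):
            directional_derivatives(
                lambda z: math.inf, np.array([0.0, 0.0]), 1, 0.0, 1e-6
            )


class TestCaputoGradient:
    def test_zero_on_constants_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = int(rng.integers(1, 6))
            x = rng.normal(size=d)
            c = rng.normal(size=d)
            alpha = float(rng.uniform(0.05, 1.0))
            cfg = FractionalConfig(alpha=alpha, gamma=1.0)
            est = caputo_gradient(lambda z: 3.7, x, ReferencePoint(c), cfg)
            assert np.max(np.abs(est.g)) <= 1e-10

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7, 0.9])
    def test_quadratic_closed_form(self, alpha):
        # f(x) = x^2 with lower terminal 0: gradient is 2x / (2 - alpha)
        cfg = FractionalConfig(alpha=alpha, gamma=0.0, n_quad=8)
        x = np.array([1.7])
        est = caputo_gradient(lambda z: z[0] ** 2, x, np.array([0.0]), cfg)
        assert est.g[0] == pytest.approx(2 * 1.7 / (2 - alpha), rel=1e-6)

    def test_classical_limit_on_random_spd_quadratics(self):
        rng = np.random.default_rng(1)
        cfg = FractionalConfig(alpha=0.999, gamma=0.0, n_quad=8)
        for _ in range(10):
            d = int(rng.integers(1, 6))
            M = rng.normal(size=(d, d))
            A = M @ M.T + d * np.eye(d)
            x = rng.normal(size=d)
            c = x - rng.uniform(0.1, 1.0, size=d)
            est = caputo_gradient(lambda z: float(z @ A @ z), x, c, cfg)
            exact = 2 * A @ x
            assert np.linalg.norm(est.g - exact) / np.linalg.norm(exact) <= 1e-2

    def test_gauss_rule_matches_adaptive_integration_with_curvature(self):
        # polynomial objective up to degree 6, gamma active
        alpha, gamma = 0.6, 0.8
        coeffs = np.array([0.3, -1.2, 0.5, 0.05, -0.02, 0.01, 0.004])  # degree 6
        poly = np.polynomial.Polynomial(coeffs)
        dpoly = poly.deriv()
        ddpoly = dpoly.deriv()
        x, c = np.array([1.3]), np.array([-0.4])
        delta = (x[0] - c[0]) / 2
        c_a = caputo_scale(alpha)
        first = adaptive_weighted_integral(
            lambda u: dpoly(delta * (1 + u) + c[0]), alpha
        )
        second = adaptive_weighted_integral(
            lambda u: ddpoly(delta * (1 + u) + c[0]), alpha
        )
        expected = c_a * first + c_a * gamma * abs(x[0] - c[0]) * second
        cfg = FractionalConfig(alpha=alpha, gamma=gamma, n_quad=8)
        est = caputo_gradient(
            lambda z: float(poly(z[0])),
            x,
            c,
            cfg,
            deriv_f=lambda i, t: (float(dpoly(t)), float(ddpoly(t))),
        )
        assert est.g[0] == pytest.approx(expected, rel=1e-6)
        # finite-difference fallback agrees to second-difference noise level
        est_fd = caputo_gradient(lambda z: float(poly(z[0])), x, c, cfg)
        assert est_fd.g[0] == pytest.approx(expected, rel=1e-3)

    def test_convergence_in_quadrature_points(self):
        f = lambda z: float(np.sin(z[0]) + np.exp(0.3 * z[1]))

        def deriv(i, t):
            if i == 0:
                return math.cos(t), -math.sin(t)
            return 0.3 * math.exp(0.3 * t), 0.09 * math.exp(0.3 * t)

        x = np.array([0.8, -0.5])
        c = np.array([0.1, 0.2])
        ests = [
            caputo_gradient(
                f, x, c, FractionalConfig(alpha=0.6, gamma=0.5, n_quad=n),
                deriv_f=deriv,
            ).g
            for n in (16, 32)
        ]
        assert np.linalg.norm(ests[0] - ests[1]) / np.linalg.norm(ests[1]) <= 1e-8

    def test_linearity_in_objective(self):
        rng = np.random.default_rng(3)
        x, c = rng.normal(size=4), rng.normal(size=4)
        cfg = FractionalConfig(alpha=0.45, gamma=0.7)

        def make_deriv(s):
            return lambda i, t: (s * (3 * t**2 - 1.0), s * 6 * t)

        f = lambda z: float(np.sum(z**3) - np.sum(z))
        g1 = caputo_gradient(f, x, c, cfg, deriv_f=make_deriv(1.0)).g
        g5 = caputo_gradient(
            lambda z: 5.0 * f(z), x, c, cfg, deriv_f=make_deriv(5.0)
        ).g
        np.testing.assert_allclose(g5, 5.0 * g1, rtol=1e-12, atol=1e-14)
        # finite-difference path stays linear to differencing noise
        g1_fd = caputo_gradient(f, x, c, cfg).g
        g5_fd = caputo_gradient(lambda z: 5.0 * f(z), x, c, cfg).g
        np.testing.assert_allclose(g5_fd, 5.0 * g1_fd, rtol=1e-3)

    def test_identity_derivative_and_normalized_variant(self):
        # the smoothed form gives exactly 1 on the identity; the normalized
        # variant divides by |x-c|^(1-alpha)/Gamma(2-alpha)
        alpha = 0.6
        x, c = np.array([2.0]), np.array([0.5])
        plain = caputo_gradient(
            lambda z: z[0], x, c, FractionalConfig(alpha=alpha, gamma=0.0)
        )
        assert plain.g[0] == pytest.approx(1.0, rel=1e-7)
        normed = caputo_gradient(
            lambda z: z[0], x, c,
            FractionalConfig(alpha=alpha, gamma=0.0, normalize=True),
        )
        expected = 1.0 / ((x[0] - c[0]) ** (1 - alpha) / gamma_fn(2 - alpha))
        assert normed.g[0] == pytest.approx(expected, rel=1e-6)

    def test_gradient_callback_matches_finite_differences(self):
        # separable objective: the joint-shift fast path must agree
        f = lambda z: float(np.sum(z**2))
        grad_f = lambda z: 2.0 * z
        x = np.array([1.0, -2.0, 0.5])
        c = np.array([0.0, -1.0, 0.0])
        cfg = FractionalConfig(alpha=0.7, gamma=0.3)
        slow = caputo_gradient(f, x, c, cfg).g
        fast = caputo_gradient(f, x, c, cfg, grad_f=grad_f).g
        np.testing.assert_allclose(fast, slow, rtol=1e-4)

    def test_coincident_terminals(self):
        # x == c: first term collapses to c_a * f'(c) * sum(weights)
        alpha = 0.5
        cfg = FractionalConfig(alpha=alpha, gamma=1.0, n_quad=8)
        x = np.array([1.2])
        est = caputo_gradient(lambda z: z[0] ** 2, x, x.copy(), cfg)
        rule_sum = 2.0 ** (1 - alpha) / (1 - alpha)
        assert est.g[0] == pytest.approx(
            caputo_scale(alpha) * 2 * 1.2 * rule_sum, rel=1e-6
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            caputo_gradient(
                lambda z: 0.0, np.zeros(3), np.zeros(2), FractionalConfig()
            )
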