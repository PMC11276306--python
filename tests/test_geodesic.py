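"""The e-geodesic family, its feasible interval, and the convex optimisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igpid import (
    CrossCorrelationSystem,
    assemble_sigma,
    d_determinant,
    feasible_interval,
    kl_gaussian,
    optimize_t,
    project,
    sigma_t,
    sigma_t_prime,
    synergy_objective,
)
from igpid.core import NotPositiveDefiniteError

from conftest import random_system, scalar_system


@pytest.fixture
def scalar_546():
    return scalar_system(0.5, 0.6, 0.4)


def _endpoints(sys):
    return project(sys, 5), project(sys, 6)


class TestSigmaT:
    def test_endpoints_recover_the_projections(self, scalar_546):
        s5, s6 = _endpoints(scalar_546)
        assert np.allclose(sigma_t(0.0, s5, s6), s5, atol=1e-12)
        assert np.allclose(sigma_t(1.0, s5, s6), s6, atol=1e-12)

    def test_midpoint_matches_brute_force_precision_average(self, scalar_546):
        s5, s6 = _endpoints(scalar_546)
        brute = np.linalg.inv(0.5 * np.linalg.inv(s5) + 0.5 * np.linalg.inv(s6))
        assert np.allclose(sigma_t(0.5, s5, s6), brute, atol=1e-12)

    def test_infeasible_t_raises(self, scalar_546):
        s5, s6 = _endpoints(scalar_546)
        interval = feasible_interval(s5, s6)
        with pytest.raises(NotPositiveDefiniteError):
            sigma_t(interval.upper + 1.0, s5, s6)

    def test_companion_matrix_endpoints(self, scalar_546):
        """Sigma_t' inverts the covariance mixture: t=0 -> inv(Sigma6), t=1 -> inv(Sigma5)."""
        s5, s6 = _endpoints(scalar_546)
        assert np.allclose(sigma_t_prime(0.0, s5, s6), np.linalg.inv(s6), atol=1e-12)
        assert np.allclose(sigma_t_prime(1.0, s5, s6), np.linalg.inv(s5), atol=1e-12)

    def test_companion_matrix_pd_on_unit_interval(self, rng):
        s5, s6 = _endpoints(random_system(rng))
        for t in np.linspace(0, 1, 11):
            np.linalg.cholesky(sigma_t_prime(t, s5, s6))


class TestFeasibleInterval:
    def test_scalar_pure_q_closed_form(self):
        """(p, q, r) = (0, 0.6, 0): feasibility requires 1 + 0.6 t and 1 - 0.6 t > 0."""
        s5, s6 = _endpoints(scalar_system(0.0, 0.6, 0.0))
        interval = feasible_interval(s5, s6)
        assert interval.lower == pytest.approx(-5.0 / 3.0, abs=1e-9)
        assert interval.upper == pytest.approx(5.0 / 3.0, abs=1e-9)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_unit_interval_strictly_inside(self, seed):
        sys = random_system(np.random.default_rng(seed))
        s5, s6 = _endpoints(sys)
        if np.allclose(s5, s6, atol=1e-12):
            return
        interval = feasible_interval(s5, s6)
        assert interval.lower < 0.0 < 1.0 < interval.upper

    def test_degenerate_geodesic_is_signalled(self):
        sys = scalar_system(0.5, 0.0, 0.0)
        s5, s6 = _endpoints(sys)
        with pytest.raises(ValueError, match="degenerate"):
            feasible_interval(s5, s6)


class TestDDeterminant:
    def test_endpoint_values(self, scalar_546):
        """d(0) = |I - R'R| and d(1) = |I - Q'Q| (the mixture at t=0 is Sigma6)."""
        assert d_determinant(0.0, scalar_546) == pytest.approx(1 - 0.16)
        assert d_determinant(1.0, scalar_546) == pytest.approx(1 - 0.36)

    def test_scalar_quadratic_closed_form(self, scalar_546):
        p, q, r = 0.5, 0.6, 0.4
        for t in np.linspace(-0.5, 1.5, 9):
            closed = 1 - t**2 * q**2 - 2 * t * (1 - t) * p * q * r - (1 - t) ** 2 * r**2
            assert d_determinant(t, scalar_546) == pytest.approx(closed, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mixture_determinant_factorises(self, seed):
        """|(1-t) Sigma6 + t Sigma5| = |I - P'P| d(t) across the feasible interval."""
        sys = random_system(np.random.default_rng(seed))
        s5, s6 = _endpoints(sys)
        if np.allclose(s5, s6, atol=1e-12):
            return
        interval = feasible_interval(s5, s6)
        factor = np.linalg.det(np.eye(sys.blocks.n2) - sys.p.T @ sys.p)
        lo, hi = interval.shrunk()
        for t in np.linspace(lo + 0.01 * interval.width, hi - 0.01 * interval.width, 7):
            direct = np.linalg.det((1 - t) * s6 + t * s5)
            assert direct == pytest.approx(factor * d_determinant(t, sys), rel=1e-9)


class TestSynergyObjective:
    def test_matches_direct_kl_on_grid(self, scalar_546):
        sigma = assemble_sigma(scalar_546)
        s5, s6 = _endpoints(scalar_546)
        for t in np.linspace(-0.3, 1.3, 9):
            direct = kl_gaussian(sigma, sigma_t(t, s5, s6))
            assert synergy_objective(t, scalar_546) == pytest.approx(direct, abs=1e-10)

    def test_endpoints_equal_projection_divergences(self, rng):
        sys = random_system(rng)
        sigma = assemble_sigma(sys)
        assert synergy_objective(0.0, sys) == pytest.approx(kl_gaussian(sigma, project(sys, 5)), abs=1e-10)
        assert synergy_objective(1.0, sys) == pytest.approx(kl_gaussian(sigma, project(sys, 6)), abs=1e-10)

    def test_nonnegative_and_convex_on_feasible_grid(self, rng):
        sys = random_system(rng)
        s5, s6 = _endpoints(sys)
        interval = feasible_interval(s5, s6)
        ts = np.linspace(interval.lower + 0.05 * interval.width,
                         interval.upper - 0.05 * interval.width, 41)
        gs = np.array([synergy_objective(t, sys) for t in ts])
        assert (gs >= -1e-12).all()
        assert (np.diff(gs, 2) >= -1e-9).all()


class TestOptimizeT:
    def test_symmetric_scalar_system_optimum_at_half(self):
        """q = r makes g symmetric under source exchange, so t* = 1/2."""
        for p in (-0.3, 0.0, 0.4):
            sol = optimize_t(scalar_system(p, 0.35, 0.35))
            assert sol.t_star == pytest.approx(0.5, abs=1e-6)

    def test_system_on_s5_has_zero_synergy_at_zero_t(self, rng):
        sys = random_system(rng)
        on_s5 = CrossCorrelationSystem(p=sys.p, q=sys.q, r=sys.p.T @ sys.q, blocks=sys.blocks)
        sol = optimize_t(on_s5)
        assert sol.g_min == pytest.approx(0.0, abs=1e-10)
        assert sol.t_star == pytest.approx(0.0, abs=1e-5)
        # d(t*) = |I - R'R| there, so Unq2 = I[X2;X3] - Shd = 0
        n3 = sys.blocks.n3
        assert sol.d_star == pytest.approx(
            np.linalg.det(np.eye(n3) - on_s5.r.T @ on_s5.r), abs=1e-8
        )

    def test_solution_lies_in_interval_with_valid_determinant(self, rng):
        for _ in range(10):
            sys = random_system(rng)
            sol = optimize_t(sys)
            assert sol.interval.lower <= sol.t_star <= sol.interval.upper
            assert 0.0 < sol.d_star <= 1.0 + 1e-12

    def test_trace_and_pythagorean_certificates(self, rng):
        sys = random_system(rng)
        s5, s6 = _endpoints(sys)
        sigma = assemble_sigma(sys)
        sol = optimize_t(sys)
        st_ = sigma_t(sol.t_star, s5, s6)
        m = sys.blocks.m
        # stationarity (interior optimum): both endpoint precisions trace to m
        if not sol.at_endpoint:
            assert np.trace(np.linalg.solve(s5, st_)) == pytest.approx(m, abs=1e-6)
            assert np.trace(np.linalg.solve(s6, st_)) == pytest.approx(m, abs=1e-6)
        # normalisation along the geodesic
        for t in np.linspace(0, 1, 5):
            assert np.trace(np.linalg.solve(sigma_t(t, s5, s6), sigma)) == pytest.approx(m, abs=1e-8)
        # generalized Pythagoras through the projection point
        assert kl_gaussian(sigma, s5) == pytest.approx(
            sol.g_min + kl_gaussian(st_, s5), abs=1e-6)
        assert kl_gaussian(sigma, s6) == pytest.approx(
            sol.g_min + kl_gaussian(st_, s6), abs=1e-6)
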