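"""Unit and property tests for the ODE term functions.

Hand-evaluated expected values are frozen from the closed forms; the
fitness gradient is checked against central finite differences.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprharvest import core
from cprharvest.errors import DomainError
from cprharvest.params import ModelParams, ModelState

# parameter set with hand-evaluatable round numbers, used by the frozen
# value tests below (independent of the package defaults)
HAND = ModelParams(r=0.03, K=100.0, h_max=0.25, n=5, k_min=10.0, k_var=400.0,
                   q_k=2.0, a=15.0, b=0.8, phi_max=16.5, T=240.0)


class TestLogisticGrowth:
    def test_zero_fixed_point(self, defaults):
        assert core.logistic_growth(0.0, defaults) == 0.0

    def test_carrying_capacity_fixed_point(self, defaults):
        assert core.logistic_growth(defaults.K, defaults) == pytest.approx(0.0)

    def test_maximum_at_half_K(self):
        # r*K/4 = 0.03*100/4
        assert core.logistic_growth(50.0, HAND) == pytest.approx(0.75)

    def test_negative_resource_rejected(self, defaults):
        with pytest.raises(DomainError):
            core.logistic_growth(-1.0, defaults)

    @given(st.floats(0.0, 100.0))
    def test_maximum_is_at_half_K(self, R):
        assert core.logistic_growth(R, HAND) <= core.logistic_growth(50.0, HAND) + 1e-12


class TestHalfSaturation:
    def test_lower_boundary(self):
        assert core.half_saturation(0.0, HAND) == pytest.approx(10.0)

    def test_upper_boundary(self):
        assert core.half_saturation(1.0, HAND) == pytest.approx(410.0)

    def test_hand_evaluation_midpoint(self):
        # 10 + 400 * 0.5**2
        assert core.half_saturation(0.5, HAND) == pytest.approx(110.0)

    def test_out_of_bounds_rejected(self, defaults):
        with pytest.raises(DomainError):
            core.half_saturation(1.5, defaults)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_and_bounded_below(self, t1, t2):
        k1, k2 = core.half_saturation(t1, HAND), core.half_saturation(t2, HAND)
        assert k1 >= HAND.k_min
        if t2 - t1 > 1e-9:
            assert k1 < k2


class TestHarvestRate:
    def test_zero_resource(self):
        assert core.harvest_rate(0.0, 0.3, HAND) == 0.0

    def test_saturation_asymptote(self):
        assert core.harvest_rate(1e12, 0.0, HAND) == pytest.approx(
            HAND.n * HAND.h_max, rel=1e-9)

    def test_hand_evaluation(self):
        # 5*0.25*50/(10+50)
        assert core.harvest_rate(50.0, 0.0, HAND) == pytest.approx(1.25 * 50 / 60)

    def test_negative_resource_rejected(self, defaults):
        with pytest.raises(DomainError):
            core.harvest_rate(-0.1, 0.5, defaults)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_strictly_decreasing_in_theta(self, t1, t2):
        if t1 == t2:
            return
        lo, hi = sorted((t1, t2))
        assert core.harvest_rate(50.0, hi, HAND) < core.harvest_rate(50.0, lo, HAND)


class TestPunishmentRate:
    def test_treatment_off(self):
        p = HAND.replace(punishment_on=False)
        assert core.punishment_rate(0.5, p) == 0.0

    def test_gaussian_peak(self):
        p = HAND.replace(punishment_on=True)
        assert core.punishment_rate(p.theta_p, p) == pytest.approx(p.p)

    def test_gaussian_tail_three_sigma(self):
        p = HAND.replace(punishment_on=True, theta_p=0.4, sigma_p=0.15)
        theta = p.theta_p + 3 * p.sigma_p
        assert core.punishment_rate(theta, p) == pytest.approx(p.p * math.exp(-4.5))

    def test_even_about_peak(self):
        p = HAND.replace(punishment_on=True)
        d = 0.2
        assert core.punishment_rate(p.theta_p - d, p) == pytest.approx(
            core.punishment_rate(p.theta_p + d, p))


class TestDiscountFactor:
    def test_zero_ceiling(self):
        p = HAND.replace(phi_max=0.0)
        for theta in (0.0, 0.5, 1.0):
            for t in (0.0, 120.0, 240.0):
                assert core.discount_factor(theta, t, p) == 0.0

    def test_logistic_evaluation_at_start(self):
        # a=15, b=0.8: D(0) = 1/(1+e^-12)
        expected = HAND.phi_max / (1.0 + math.exp(-12.0))
        assert core.discount_factor(1.0, 0.0, HAND) == pytest.approx(expected)

    def test_logistic_evaluation_at_end(self):
        # D(T) = 1/(1+e^3) ~ 0.047
        expected = HAND.phi_max / (1.0 + math.exp(3.0))
        assert core.discount_factor(1.0, HAND.T, HAND) == pytest.approx(expected)

    def test_zero_at_zero_trait(self):
        assert core.discount_factor(0.0, 10.0, HAND) == 0.0

    def test_time_outside_round_rejected(self):
        with pytest.raises(DomainError):
            core.discount_factor(0.5, -1.0, HAND)
        with pytest.raises(DomainError):
            core.discount_factor(0.5, HAND.T + 1.0, HAND)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 240.0), st.floats(0.0, 240.0))
    def test_bounded_and_nonincreasing_in_time(self, theta, ta, tb):
        phi_a = core.discount_factor(theta, ta, HAND)
        assert 0.0 <= phi_a <= HAND.phi_max
        if ta < tb:
            assert core.discount_factor(theta, tb, HAND) <= phi_a + 1e-12


class TestFutureProductivity:
    def test_zero_ceiling(self):
        p = HAND.replace(phi_max=0.0)
        assert core.future_productivity(50.0, 0.7, 10.0, p) == 0.0

    def test_zero_at_carrying_capacity(self):
        assert core.future_productivity(HAND.K, 0.7, 10.0, HAND) == pytest.approx(0.0)

    def test_product_of_oracle_evaluations(self):
        expected = core.discount_factor(1.0, 0.0, HAND) * 0.75
        assert core.future_productivity(50.0, 1.0, 0.0, HAND) == pytest.approx(expected)


class TestFitness:
    def test_reduces_to_harvest(self):
        p = HAND.replace(phi_max=0.0, punishment_on=False)
        assert core.fitness(50.0, 0.5, 10.0, p) == pytest.approx(
            core.harvest_rate(50.0, 0.5, p))

    def test_no_resource_only_costs(self):
        p = HAND.replace(punishment_on=True)
        w = core.fitness(0.0, 0.5, 10.0, p)
        assert w == pytest.approx(-core.punishment_rate(0.5, p))
        assert w <= 0.0

    def test_term_by_term_oracle(self):
        p = HAND.replace(punishment_on=True)
        R, theta, t = 50.0, 0.5, 0.0
        expected = (core.harvest_rate(R, theta, p)
                    + core.future_productivity(R, theta, t, p)
                    - core.punishment_rate(theta, p))
        assert core.fitness(R, theta, t, p) == pytest.approx(expected)


def _fd_gradient(R, theta, t, params, h=1e-6):
    return (core.fitness(R, theta + h, t, params)
            - core.fitness(R, theta - h, t, params)) / (2 * h)


class TestFitnessGradient:
    def test_myopic_gradient_negative(self):
        p = HAND.replace(phi_max=0.0, punishment_on=False)
        for theta in (0.1, 0.5, 0.9):
            assert core.fitness_gradient(50.0, theta, 0.0, p) < 0.0

    def test_punishment_contribution_zero_at_peak(self):
        p_on = HAND.replace(punishment_on=True)
        p_off = HAND.replace(punishment_on=False)
        theta = p_on.theta_p
        assert core.fitness_gradient(50.0, theta, 0.0, p_on) == pytest.approx(
            core.fitness_gradient(50.0, theta, 0.0, p_off))

    def test_matches_finite_difference_single(self):
        p = HAND.replace(punishment_on=True)
        grad = core.fitness_gradient(50.0, 0.5, 0.0, p)
        assert grad == pytest.approx(_fd_gradient(50.0, 0.5, 0.0, p), rel=1e-5)

    def test_matches_finite_difference_1000_points(self, rng):
        p = HAND.replace(punishment_on=True)
        for _ in range(1000):
            R = rng.uniform(1.0, 99.0)
            theta = rng.uniform(0.05, 0.95)
            t = rng.uniform(0.0, p.T)
            grad = core.fitness_gradient(R, theta, t, p)
            assert grad == pytest.approx(_fd_gradient(R, theta, t, p), rel=1e-5, abs=1e-10)


class TestRhs:
    def test_extinct_resource(self):
        p = HAND.replace(punishment_on=False)
        dR, dH, _ = core.rhs(ModelState(R=0.0, H=0.0, theta=0.5), 0.0, p)
        assert dR == 0.0
        assert dH == 0.0

    def test_projection_noop_for_inward_gradient(self):
        # at the upper bound the myopic gradient points down (inward): untouched
        p = HAND.replace(phi_max=0.0, punishment_on=False)
        _, _, dtheta = core.rhs(ModelState(R=50.0, H=0.0, theta=1.0), 0.0, p)
        assert dtheta == pytest.approx(p.delta * core.fitness_gradient(50.0, 1.0, 0.0, p))

    def test_projection_zeroes_outward_gradient(self):
        # strong future term at theta_max pushes up: projected to zero
        p = HAND.replace(phi_max=30.0, punishment_on=False)
        assert core.fitness_gradient(50.0, 1.0, 0.0, p) > 0
        _, _, dtheta = core.rhs(ModelState(R=50.0, H=0.0, theta=1.0), 0.0, p)
        assert dtheta == 0.0

    def test_component_oracle(self):
        p = HAND.replace(punishment_on=True)
        state = ModelState(R=50.0, H=0.0, theta=0.8)
        dR, dH, dtheta = core.rhs(state, 0.0, p)
        G = core.harvest_rate(50.0, 0.8, p)
        assert dR == pytest.approx(core.logistic_growth(50.0, p) - G)
        assert dH == pytest.approx(G - core.punishment_rate(0.8, p))
        assert dtheta == pytest.approx(p.delta * core.fitness_gradient(50.0, 0.8, 0.0, p))

    def test_invalid_state_rejected(self, defaults):
        with pytest.raises(ValueError):
            core.rhs(ModelState(R=-1.0, H=0.0, theta=0.5), 0.0, defaults)


class TestGridInvariants:
    """Non-negativity and the trade-off, asserted by grid scan."""

    def test_k_and_phi_nonnegative_on_grid(self, defaults):
        thetas = np.linspace(defaults.theta_min, defaults.theta_max, 101)
        times = np.linspace(0.0, defaults.T, 101)
        for theta in thetas:
            assert core.half_saturation(theta, defaults) >= defaults.k_min > 0
            for t in times[::10]:
                phi = core.discount_factor(theta, t, defaults)
                assert 0.0 <= phi <= defaults.phi_max

    def test_tradeoff_monotonicity(self, defaults):
        """G strictly decreasing, phi strictly increasing in theta (interior)."""
        thetas = np.linspace(0.01, 0.99, 50)
        G = [core.harvest_rate(50.0, t, defaults) for t in thetas]
        phi = [core.discount_factor(t, 0.0, defaults) for t in thetas]
        assert all(np.diff(G) < 0)
        assert all(np.diff(phi) > 0)

    def test_myopic_trait_always_declines(self, defaults):
        p = defaults.replace(phi_max=0.0, punishment_on=False)
        for theta in np.linspace(0.05, 0.95, 10):
            for R in (1.0, 30.0, 80.0):
                _, _, dtheta = core.rhs(ModelState(R=R, H=0.0, theta=theta), 0.0, p)
                assert dtheta < 0
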