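"""Pure functions defining every term of the coupled resource/harvest/trait ODE.

No integration and no I/O here. All functions take scalar inputs plus a
:class:`~cprharvest.params.ModelParams` and raise
:class:`~cprharvest.errors.DomainError` on out-of-domain arguments.

The trade-off that drives the model: raising the harvest trait ``theta``
lowers the current group harvest ``G`` (through the half-saturation
constant) but raises the discounted future productivity ``F`` (through
the discount weight ``phi``).
"""
from __future__ import annotations

import math

from .errors import DomainError
from .params import ModelParams, ModelState

__all__ = [
    "logistic_growth",
    "half_saturation",
    "harvest_rate",
    "max_harvest_rate",
    "cooperation",
    "punishment_rate",
    "discount_factor",
    "future_productivity",
    "fitness",
    "fitness_gradient",
    "rhs",
]


def _check_R(R: float) -> None:
    if R < 0:
        raise DomainError(f"resource level must be >= 0, got {R}")


def _check_theta(theta: float, params: ModelParams) -> None:
    if not params.theta_min <= theta <= params.theta_max:
        raise DomainError(
            f"theta={theta} outside [{params.theta_min}, {params.theta_max}]"
        )


def _check_t(t: float, params: ModelParams) -> None:
    if not 0.0 <= t <= params.T:
        raise DomainError(f"t={t} outside [0, {params.T}]")


def logistic_growth(R: float, params: ModelParams) -> float:
    """Net resource production rate ``g(R) = r*R*(1 - R/K)``."""
    _check_R(R)
    return params.r * R * (1.0 - R / params.K)


def half_saturation(theta: float, params: ModelParams) -> float:
    """Trait-dependent half-saturation ``k(theta) = k_min + k_var*theta**q_k``."""
    _check_theta(theta, params)
    return params.k_min + params.k_var * theta ** params.q_k


def harvest_rate(R: float, theta: float, params: ModelParams) -> float:
    """Group harvest rate ``G = n*h_max*R/(k(theta) + R)`` (Monod kinetics)."""
    _check_R(R)
    k = half_saturation(theta, params)
    return params.n * params.h_max * R / (k + R)


def max_harvest_rate(R: float, params: ModelParams) -> float:
    """Harvest rate at maximal aggressiveness (``k = k_min``)."""
    _check_R(R)
    return params.n * params.h_max * R / (params.k_min + R)


def cooperation(R: float, theta: float, params: ModelParams) -> float:
    """Foregone harvest normalized by the maximum possible harvest.

    ``A = (G_max(R) - G(R, theta)) / G_max(R)``, in [0, 1]. Defined as 0
    at ``R = 0``, where no harvest is foregone.
    """
    _check_R(R)
    if R == 0.0:
        return 0.0
    g_max = max_harvest_rate(R, params)
    return (g_max - harvest_rate(R, theta, params)) / g_max


def punishment_rate(theta: float, params: ModelParams) -> float:
    """Punishment cost rate, a Gaussian kernel around ``theta_p``.

    Zero when punishment is not available in the round.
    """
    _check_theta(theta, params)
    if not params.punishment_on:
        return 0.0
    z = (theta - params.theta_p) / params.sigma_p
    return params.p * math.exp(-0.5 * z * z)


def discount_factor(theta: float, t: float, params: ModelParams) -> float:
    """Weight on future productivity, ``phi(theta, t) = phi_max*theta**q_phi*D(t)``.

    ``D(t) = 1/(1 + exp(a*(t/T - b)))`` decays as the round elapses, so
    future pay-offs lose weight when little time remains.
    """
    _check_theta(theta, params)
    _check_t(t, params)
    decay = 1.0 / (1.0 + math.exp(params.a * (t / params.T - params.b)))
    return params.phi_max * theta ** params.q_phi * decay


def future_productivity(R: float, theta: float, t: float, params: ModelParams) -> float:
    """Discounted future productivity expected by the users, ``F = phi*g(R)``."""
    return discount_factor(theta, t, params) * logistic_growth(R, params)


def fitness(R: float, theta: float, t: float, params: ModelParams) -> float:
    """Fitness ``W = G + F - P``: current plus discounted future pay-offs
    minus punishment costs."""
    return (
        harvest_rate(R, theta, params)
        + future_productivity(R, theta, t, params)
        - punishment_rate(theta, params)
    )


def fitness_gradient(R: float, theta: float, t: float, params: ModelParams) -> float:
    """Analytic partial derivative of :func:`fitness` with respect to theta."""
    _check_R(R)
    _check_theta(theta, params)
    _check_t(t, params)
    # dG/dtheta = -n*h_max*R * k'(theta) / (k + R)^2
    k = params.k_min + params.k_var * theta ** params.q_k
    if theta == 0.0 and params.q_k < 1.0:
        raise DomainError("k(theta) gradient singular at theta=0 for q_k < 1")
    kprime = params.k_var * params.q_k * theta ** (params.q_k - 1.0) if params.q_k != 0 else 0.0
    dG = -params.n * params.h_max * R * kprime / (k + R) ** 2
    # dF/dtheta = phi_max * q_phi * theta^(q_phi-1) * D(t) * g(R)
    decay = 1.0 / (1.0 + math.exp(params.a * (t / params.T - params.b)))
    if theta == 0.0 and params.q_phi < 1.0:
        raise DomainError("phi gradient singular at theta=0 for q_phi < 1")
    theta_pow = theta ** (params.q_phi - 1.0) if params.q_phi != 1.0 else 1.0
    g = params.r * R * (1.0 - R / params.K)
    dF = params.phi_max * params.q_phi * theta_pow * decay * g
    # dP/dtheta = -P(theta) * (theta - theta_p) / sigma_p^2
    dP = 0.0
    if params.punishment_on:
        z = (theta - params.theta_p) / params.sigma_p
        P = params.p * math.exp(-0.5 * z * z)
        dP = -P * (theta - params.theta_p) / params.sigma_p ** 2
    return dG + dF - dP


def rhs(state: ModelState, t: float, params: ModelParams) -> tuple[float, float, float]:
    """Time derivatives ``(dR/dt, dH/dt, dtheta/dt)``.

    The trait derivative is the fitness gradient scaled by ``delta``,
    projected to zero when theta sits at a bound and the gradient points
    outward.
    """
    state.validate(params)
    R, theta = state.R, state.theta
    dR = logistic_growth(R, params) - harvest_rate(R, theta, params)
    dH = harvest_rate(R, theta, params) - punishment_rate(theta, params)
    dtheta = params.delta * fitness_gradient(R, theta, t, params)
    if theta <= params.theta_min and dtheta < 0.0:
        dtheta = 0.0
    elif theta >= params.theta_max and dtheta > 0.0:
        dtheta = 0.0
    return dR, dH, dtheta
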