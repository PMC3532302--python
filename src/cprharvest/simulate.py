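"""Round integration and derived diagnostic series.

A :class:`Trajectory` bundles the state series of one round together
with the instantaneous terms and the behavioral diagnostics (cooperation
``A``, relative productivity ``omega``, resource affinity ``1/k``).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import _kernel, core
from .errors import DomainError, IntegrationError
from .params import DEFAULT_INIT, ModelParams, ModelState

__all__ = [
    "Trajectory",
    "integrate_round",
    "cooperation_series",
    "relative_productivity",
    "affinity_from_observed",
    "total_harvest",
]

DEFAULT_DT = 0.05
DEFAULT_DT_OUT = 1.0


@dataclass
class Trajectory:
    """One integrated round on a uniform output grid.

    All series share the grid ``t`` (``t[0] = 0``, ``t[-1] = T``).
    ``growth_cum`` is the cumulative production integral carried by the
    integrator; it is not part of the CSV contract.
    """

    t: np.ndarray
    R: np.ndarray
    H: np.ndarray
    theta: np.ndarray
    G: np.ndarray
    phi: np.ndarray
    P: np.ndarray
    A: np.ndarray
    omega: np.ndarray
    affinity: np.ndarray
    H_T: float
    params_used: ModelParams
    growth_cum: np.ndarray | None = field(default=None, repr=False)

    SERIES = ("t", "R", "H", "theta", "G", "phi", "P", "A", "omega", "affinity")

    def __len__(self) -> int:
        return self.t.size


def integrate_round(
    params: ModelParams,
    init: ModelState | None = None,
    dt: float = DEFAULT_DT,
    dt_out: float = DEFAULT_DT_OUT,
) -> Trajectory:
    """Integrate one round of the ODE system with fixed-step RK4.

    ``dt`` must not exceed ``dt_out`` and ``dt_out`` must divide the
    round duration ``T``. The resource is floored at zero (absorbing)
    and the trait is projected onto its bounds.
    """
    init = DEFAULT_INIT if init is None else init
    init.validate(params)
    if dt <= 0 or dt_out <= 0:
        raise ValueError("dt and dt_out must be positive")
    if dt > dt_out + 1e-12:
        raise ValueError(f"dt={dt} must be <= dt_out={dt_out}")
    n_out = params.T / dt_out
    if abs(n_out - round(n_out)) > 1e-9:
        raise ValueError(f"dt_out={dt_out} must divide T={params.T}")

    pv = params.to_vector()
    t, R, H, theta, gcum = _kernel.integrate(pv, init.R, init.H, init.theta, dt, dt_out)
    for name, arr in (("R", R), ("H", H), ("theta", theta)):
        bad = ~np.isfinite(arr)
        if bad.any():
            t_bad = t[int(np.argmax(bad))]
            raise IntegrationError(f"non-finite {name} at t={t_bad}")

    return _with_diagnostics(t, R, H, theta, gcum, params)


def _with_diagnostics(t, R, H, theta, gcum, params: ModelParams) -> Trajectory:
    k = params.k_min + params.k_var * theta ** params.q_k
    G = params.n * params.h_max * R / (k + R)
    decay = 1.0 / (1.0 + np.exp(params.a * (t / params.T - params.b)))
    phi = params.phi_max * theta ** params.q_phi * decay
    if params.punishment_on:
        P = params.p * np.exp(-0.5 * ((theta - params.theta_p) / params.sigma_p) ** 2)
    else:
        P = np.zeros_like(t)
    traj = Trajectory(
        t=t, R=R, H=H, theta=theta, G=G, phi=phi, P=P,
        A=np.empty_like(t), omega=np.empty_like(t), affinity=1.0 / k,
        H_T=float(H[-1]), params_used=params, growth_cum=gcum,
    )
    traj.A = cooperation_series(traj, params)
    traj.omega = relative_productivity(traj, params)
    return traj


def cooperation_series(traj: Trajectory, params: ModelParams) -> np.ndarray:
    """Cooperation ``A(t)``: foregone harvest over maximum possible harvest.

    ``A = (G_max - G)/G_max`` with ``G_max = n*h_max*R/(k_min + R)``;
    defined as 0 where ``R = 0`` (no harvest is foregone there).
    """
    R, theta = traj.R, traj.theta
    A = np.zeros_like(R)
    pos = R > 0.0
    g_max = params.n * params.h_max * R[pos] / (params.k_min + R[pos])
    k = params.k_min + params.k_var * theta[pos] ** params.q_k
    G = params.n * params.h_max * R[pos] / (k + R[pos])
    A[pos] = (g_max - G) / g_max
    return A


def relative_productivity(traj: Trajectory, params: ModelParams) -> np.ndarray:
    """Remaining cumulated productivity scaled by the round's initial resource.

    ``omega(t) = (integral of g(R) from t to T) / R(0)``, evaluated by
    the trapezoidal rule on the output grid. Non-increasing in t while
    the resource stays at or below carrying capacity.
    """
    if traj.R[0] <= 0:
        raise DomainError("relative productivity undefined for R(0) = 0")
    g = params.r * traj.R * (1.0 - traj.R / params.K)
    cum = cumulative_trapezoid(g, traj.t, initial=0.0)
    return (cum[-1] - cum) / traj.R[0]


def affinity_from_observed(
    R_obs: np.ndarray,
    G_obs: np.ndarray,
    params: ModelParams,
    eps: float = 1e-6,
) -> np.ndarray:
    """Resource affinity ``1/k`` inferred from observed harvest rates.

    Inverts the Monod law: ``k = R*(n*h_max - G)/G``. Entries where the
    inversion is ill-posed (harvest at zero or saturation, or no
    resource) are returned as NaN.
    """
    R_obs = np.asarray(R_obs, dtype=float)
    G_obs = np.asarray(G_obs, dtype=float)
    if R_obs.shape != G_obs.shape:
        raise ValueError("R_obs and G_obs must be aligned")
    if (R_obs < 0).any() or (G_obs < 0).any():
        raise DomainError("observed series must be non-negative")
    g_sat = params.n * params.h_max
    ok = (G_obs > eps) & (G_obs < g_sat * (1.0 - eps)) & (R_obs > eps)
    out = np.full_like(R_obs, np.nan)
    k = R_obs[ok] * (g_sat - G_obs[ok]) / G_obs[ok]
    out[ok] = 1.0 / k
    if not ok.any():
        warnings.warn("all entries masked in affinity_from_observed", stacklevel=2)
    return out


def total_harvest(traj: Trajectory) -> float:
    """Total harvest realized over the round, ``H(T)``."""
    return float(traj.H[-1])
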