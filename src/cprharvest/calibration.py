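"""Round-wise calibration of the discount ceiling against observed resource series.

Two modes: a one-parameter fit of ``phi_max`` alone (the between-round
free parameter) and a three-parameter fit of ``(phi_max, a, b)`` that
additionally frees the decay shape. Both minimize the RMSE between the
modeled and observed resource series by deterministic grid search plus
golden-section refinement; gradient-based optimizers are avoided because
the objective can kink at the collapse-onset boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .errors import DomainError, FitError
from .params import DEFAULT_INIT, ModelParams, ModelState
from .simulate import DEFAULT_DT, Trajectory

__all__ = [
    "ObservedRound",
    "CalibrationResult",
    "rmse",
    "fit_phi_max",
    "fit_three_params",
    "sensitivity_scan",
    "normalized_curvature",
    "DEFAULT_BOUNDS",
]

#: Search ranges for the three free parameters. The discount ceiling is
#: unconstrained a priori and spans its full calibration range; the two
#: decay-shape parameters are structurally confined to a plausible band
#: (the weight must decay in the later middle of the round, at a
#: moderate sharpness) around the model defaults.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "phi_max": (0.0, 40.0),
    "a": (10.0, 20.0),
    "b": (0.45, 0.65),
}

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ObservedRound:
    """A sampled (noisy) resource series for one experimental round."""

    session_id: str
    round_index: int
    treatment: str
    t_obs: np.ndarray
    R_obs: np.ndarray
    G_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_obs = np.asarray(self.t_obs, dtype=float)
        self.R_obs = np.asarray(self.R_obs, dtype=float)
        if self.G_obs is not None:
            self.G_obs = np.asarray(self.G_obs, dtype=float)
        if self.t_obs.size == 0:
            raise DomainError("observed round has no samples")
        if self.t_obs.size != self.R_obs.size:
            raise DomainError("t_obs and R_obs must be aligned")
        if (np.diff(self.t_obs) <= 0).any():
            raise DomainError("t_obs must be strictly increasing")
        if self.t_obs[0] < 0:
            raise DomainError("t_obs must be >= 0")
        if (self.R_obs < 0).any():
            raise DomainError("R_obs must be >= 0")
        if self.treatment not in ("C", "P", "CP", "NCP"):
            raise DomainError(f"unknown treatment {self.treatment!r}")


@dataclass
class CalibrationResult:
    """Outcome of a calibration run.

    ``trace`` records every objective evaluation as
    ``(parameter dict, rmse)``; the reported optimum is the best traced
    evaluation, so ``rmse_at_optimum <= rmse`` of every trace entry.
    """

    estimates: dict[str, float]
    rmse_at_optimum: float
    evaluations: int
    trace: list[tuple[dict[str, float], float]] = field(repr=False)
    mode: str = "one"
    ill_identified: tuple[str, ...] = ()
    n_nonfinite: int = 0
    H_T: float = float("nan")


def rmse(traj: Trajectory, obs: ObservedRound) -> float:
    """Root-mean-square error between model and observed resource series.

    The model series is linearly interpolated onto the sampling times,
    which must fall inside the trajectory grid.
    """
    if obs.t_obs[-1] > traj.t[-1] + 1e-9:
        raise DomainError("observation times extend beyond the trajectory")
    r_model = np.interp(obs.t_obs, traj.t, traj.R)
    return float(np.sqrt(np.mean((r_model - obs.R_obs) ** 2)))


class _Objective:
    """RMSE of the modeled resource series as a function of free parameters."""

    def __init__(self, obs: ObservedRound, params_base: ModelParams,
                 init: ModelState | None, dt: float):
        if obs.t_obs[-1] > params_base.T + 1e-9:
            raise DomainError("observation times extend beyond the round duration")
        self.obs = obs
        self.base = params_base
        self.init = DEFAULT_INIT if init is None else init
        self.dt = dt
        self.trace: list[tuple[dict[str, float], float]] = []
        self.n_nonfinite = 0

    def __call__(self, **free: float) -> float:
        pv = self.base.replace(**free).to_vector()
        r_model = _kernel.resource_at(
            pv, self.init.R, self.init.H, self.init.theta, self.dt, self.obs.t_obs
        )
        err = float(np.sqrt(np.mean((r_model - self.obs.R_obs) ** 2)))
        if not np.isfinite(err):
            self.n_nonfinite += 1
            err = float("inf")
        self.trace.append((dict(free), err))
        return err

    def best(self) -> tuple[dict[str, float], float]:
        finite = [(p, e) for p, e in self.trace if np.isfinite(e)]
        if not finite:
            raise FitError("objective non-finite everywhere")
        return min(finite, key=lambda pe: pe[1])


def _golden_section(f, lo: float, hi: float, tol: float) -> None:
    """Golden-section minimization; evaluations land in the caller's trace."""
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = f(x1), f(x2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = f(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = f(x2)


def fit_phi_max(
    obs: ObservedRound,
    params_base: ModelParams,
    bounds: tuple[float, float] = DEFAULT_BOUNDS["phi_max"],
    grid_step: float = 0.5,
    tol: float = 0.01,
    init: ModelState | None = None,
    dt: float = DEFAULT_DT,
) -> CalibrationResult:
    """Fit the discount ceiling alone; all other parameters stay fixed.

    Coarse grid scan (``grid_step``) followed by golden-section
    refinement (``tol``) around the best grid point. Deterministic.
    """
    objective = _Objective(obs, params_base, init, dt)
    lo, hi = bounds
    grid = np.arange(lo, hi + 1e-9, grid_step)
    errs = [objective(phi_max=float(x)) for x in grid]
    i_best = int(np.argmin(errs))
    if not np.isfinite(errs[i_best]):
        raise FitError("objective non-finite over the whole grid")
    blo = max(lo, grid[i_best] - grid_step)
    bhi = min(hi, grid[i_best] + grid_step)
    _golden_section(lambda x: objective(phi_max=float(x)), blo, bhi, tol)
    est, err = objective.best()
    result = CalibrationResult(
        estimates=est,
        rmse_at_optimum=err,
        evaluations=len(objective.trace),
        trace=objective.trace,
        mode="one",
        n_nonfinite=objective.n_nonfinite,
    )
    result.ill_identified = _flag_ill_identified(result, {"phi_max": bounds})
    result.H_T = _fitted_H_T(objective, est)
    return result


def fit_three_params(
    obs: ObservedRound,
    params_base: ModelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    resolution: tuple[int, int, int] = (30, 15, 15),
    tol: float = 0.01,
    n_sweeps: int = 2,
    init: ModelState | None = None,
    dt: float = DEFAULT_DT,
) -> CalibrationResult:
    """Fit ``(phi_max, a, b)`` by full-factorial grid + coordinate refinement.

    The one-parameter optimum (at the base decay shape) is evaluated as
    an extra candidate before refinement, so the three-parameter RMSE
    can never exceed the one-parameter RMSE on the same observations.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    objective = _Objective(obs, params_base, init, dt)
    names = ("phi_max", "a", "b")
    grids = {
        name: np.linspace(*bounds[name], num=resolution[i])
        for i, name in enumerate(names)
    }
    for phi in grids["phi_max"]:
        for a in grids["a"]:
            for b in grids["b"]:
                objective(phi_max=float(phi), a=float(a), b=float(b))

    # seed with the nested one-parameter optimum (dominance guarantee)
    one = fit_phi_max(obs, params_base, bounds["phi_max"], tol=tol, init=init, dt=dt)
    objective(phi_max=one.estimates["phi_max"], a=params_base.a, b=params_base.b)

    current, _ = objective.best()
    steps = {name: (grids[name][1] - grids[name][0]) for name in names}
    for _ in range(n_sweeps):
        for name in names:
            lo = max(bounds[name][0], current[name] - steps[name])
            hi = min(bounds[name][1], current[name] + steps[name])

            def f(x, _name=name):
                free = dict(current)
                free[_name] = float(x)
                return objective(**free)

            _golden_section(f, lo, hi, max(tol, 1e-3 * (bounds[name][1] - bounds[name][0])))
            current, _ = objective.best()

    est, err = objective.best()
    result = CalibrationResult(
        estimates=est,
        rmse_at_optimum=err,
        evaluations=len(objective.trace),
        trace=objective.trace,
        mode="three",
        n_nonfinite=objective.n_nonfinite,
    )
    result.ill_identified = _flag_ill_identified(result, bounds)
    result.H_T = _fitted_H_T(objective, est)
    return result


def _fitted_H_T(objective: _Objective, est: dict[str, float]) -> float:
    pv = objective.base.replace(**est).to_vector()
    ini = objective.init
    _, _, H, _, _ = _kernel.integrate(pv, ini.R, ini.H, ini.theta, objective.dt, objective.dt)
    return float(H[-1])


def _flag_ill_identified(
    result: CalibrationResult,
    bounds: dict[str, tuple[float, float]],
    rel_band: float = 0.05,
    spread_frac: float = 0.25,
) -> tuple[str, ...]:
    """Flag parameters whose near-optimal trace spread is a large fraction
    of their search range (flat objective -> not identified)."""
    cutoff = result.rmse_at_optimum * (1.0 + rel_band) + 1e-12
    near = [p for p, e in result.trace if e <= cutoff]
    flags = []
    for name, (lo, hi) in bounds.items():
        vals = [p[name] for p in near if name in p]
        if len(vals) >= 2 and (max(vals) - min(vals)) > spread_frac * (hi - lo):
            flags.append(name)
    return tuple(flags)


def sensitivity_scan(
    obs: ObservedRound,
    result: CalibrationResult,
    params_base: ModelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_points: int = 41,
    init: ModelState | None = None,
    dt: float = DEFAULT_DT,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One-at-a-time RMS curves around a three-parameter optimum.

    For each free parameter, the RMSE along a grid over its bounds while
    the other two stay at their fitted values. The fitted value itself
    is inserted into the grid, so each curve's minimum is at most
    ``rmse_at_optimum``.
    """
    if result.mode != "three":
        raise ValueError("sensitivity_scan requires a three-parameter result")
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    objective = _Objective(obs, params_base, init, dt)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in ("phi_max", "a", "b"):
        grid = np.linspace(*bounds[name], num=n_points)
        grid = np.unique(np.append(grid, result.estimates[name]))
        errs = np.empty_like(grid)
        for i, x in enumerate(grid):
            free = dict(result.estimates)
            free[name] = float(x)
            errs[i] = objective(**free)
        curves[name] = (grid, errs)
    return curves


def normalized_curvature(
    grid: np.ndarray,
    errs: np.ndarray,
    bounds: tuple[float, float],
    half_width: int = 3,
) -> float:
    """Quadratic curvature of an RMS curve at its minimum, on the
    parameter axis normalized by the bound range (comparable across
    parameters)."""
    i0 = int(np.argmin(errs))
    lo = max(0, i0 - half_width)
    hi = min(len(grid), i0 + half_width + 1)
    x = (grid[lo:hi] - grid[i0]) / (bounds[1] - bounds[0])
    coeffs = np.polyfit(x, errs[lo:hi], 2)
    return float(2.0 * coeffs[0])
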