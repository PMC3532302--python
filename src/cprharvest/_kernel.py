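"""Compiled fixed-step RK4 integrator.

This duplicates the algebra of :mod:`cprharvest.core` in a form numba
can compile; ``tests/test_simulate.py`` cross-checks the two routes.
Parameter vectors come from :meth:`ModelParams.to_vector` (see
``params.py`` for the field order).
"""
from __future__ import annotations

import numpy as np
from numba import njit

# indices into the parameter vector
_R_, _K_, _HMAX_, _N_ = 0, 1, 2, 3
_KMIN_, _KVAR_, _QK_ = 4, 5, 6
_THMIN_, _THMAX_, _DELTA_ = 7, 8, 9
_P_, _THP_, _SIGP_ = 10, 11, 12
_PHIMAX_, _A_, _B_, _QPHI_ = 13, 14, 15, 16
_T_, _PUNISH_ = 17, 18


@njit(cache=True)
def _derivs(pv, R, theta, t):
    """(dR, dH, dtheta, g) at a clipped state."""
    if R < 0.0:
        R = 0.0
    thmin, thmax = pv[_THMIN_], pv[_THMAX_]
    if theta < thmin:
        theta = thmin
    elif theta > thmax:
        theta = thmax

    g = pv[_R_] * R * (1.0 - R / pv[_K_])
    k = pv[_KMIN_] + pv[_KVAR_] * theta ** pv[_QK_]
    G = pv[_N_] * pv[_HMAX_] * R / (k + R)
    P = 0.0
    dP = 0.0
    if pv[_PUNISH_] > 0.5:
        z = (theta - pv[_THP_]) / pv[_SIGP_]
        P = pv[_P_] * np.exp(-0.5 * z * z)
        dP = -P * (theta - pv[_THP_]) / (pv[_SIGP_] * pv[_SIGP_])
    decay = 1.0 / (1.0 + np.exp(pv[_A_] * (t / pv[_T_] - pv[_B_])))

    kprime = pv[_KVAR_] * pv[_QK_] * theta ** (pv[_QK_] - 1.0)
    dG = -pv[_N_] * pv[_HMAX_] * R * kprime / ((k + R) * (k + R))
    if pv[_QPHI_] == 1.0:
        theta_pow = 1.0
    else:
        theta_pow = theta ** (pv[_QPHI_] - 1.0)
    dF = pv[_PHIMAX_] * pv[_QPHI_] * theta_pow * decay * g

    dtheta = pv[_DELTA_] * (dG + dF - dP)
    if theta <= thmin and dtheta < 0.0:
        dtheta = 0.0
    elif theta >= thmax and dtheta > 0.0:
        dtheta = 0.0
    return g - G, G - P, dtheta, g


@njit(cache=True)
def integrate(pv, R0, H0, th0, dt, dt_out):
    """RK4 over [0, T]; returns (t, R, H, theta, Gcum) on the dt_out grid.

    Gcum is the cumulative resource production integral, carried as a
    fourth state so conservation checks see integrator-level accuracy.
    R is floored at 0 (absorbing) and theta clipped to its bounds after
    every step.
    """
    T = pv[_T_]
    n_out = int(round(T / dt_out))
    sub = int(round(dt_out / dt))
    h = dt_out / sub  # actual step, dt rounded to divide dt_out

    t_grid = np.empty(n_out + 1)
    R_out = np.empty(n_out + 1)
    H_out = np.empty(n_out + 1)
    th_out = np.empty(n_out + 1)
    gc_out = np.empty(n_out + 1)

    R, H, th, gc = R0, H0, th0, 0.0
    t_grid[0], R_out[0], H_out[0], th_out[0], gc_out[0] = 0.0, R, H, th, gc
    thmin, thmax = pv[_THMIN_], pv[_THMAX_]

    for i in range(n_out):
        t0 = i * dt_out
        for s in range(sub):
            t = t0 + s * h
            k1R, k1H, k1t, k1g = _derivs(pv, R, th, t)
            k2R, k2H, k2t, k2g = _derivs(pv, R + 0.5 * h * k1R, th + 0.5 * h * k1t, t + 0.5 * h)
            k3R, k3H, k3t, k3g = _derivs(pv, R + 0.5 * h * k2R, th + 0.5 * h * k2t, t + 0.5 * h)
            k4R, k4H, k4t, k4g = _derivs(pv, R + h * k3R, th + h * k3t, t + h)
            R += h * (k1R + 2.0 * k2R + 2.0 * k3R + k4R) / 6.0
            H += h * (k1H + 2.0 * k2H + 2.0 * k3H + k4H) / 6.0
            th += h * (k1t + 2.0 * k2t + 2.0 * k3t + k4t) / 6.0
            gc += h * (k1g + 2.0 * k2g + 2.0 * k3g + k4g) / 6.0
            if R < 0.0:
                R = 0.0
            if th < thmin:
                th = thmin
            elif th > thmax:
                th = thmax
        t_grid[i + 1] = (i + 1) * dt_out
        R_out[i + 1] = R
        H_out[i + 1] = H
        th_out[i + 1] = th
        gc_out[i + 1] = gc

    return t_grid, R_out, H_out, th_out, gc_out


@njit(cache=True)
def resource_at(pv, R0, H0, th0, dt, t_obs):
    """Model resource series linearly interpolated onto sampling times.

    Integrates on the fixed step dt and interpolates R between steps;
    used by the calibration objective where only R(t_obs) is needed.
    """
    t, R, H, th, gc = integrate(pv, R0, H0, th0, dt, dt)
    out = np.empty(t_obs.size)
    for j in range(t_obs.size):
        out[j] = np.interp(t_obs[j], t, R)
    return out
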