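"""Between-round feedback analysis.

Links each round's fitted discount ceiling to the outcome of the
preceding round with the same treatment, derives the implied
exponential discount rates, fits the sigmoid response of the rate to
the previous total harvest, and estimates the sustainability threshold
as the fixed point of the previous-vs-current regression.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

__all__ = [
    "RoundOutcome",
    "FeedbackFit",
    "ThresholdFit",
    "discount_rate_from_weight",
    "fit_logistic_response",
    "sustainability_threshold",
    "build_round_outcomes",
]

log = logging.getLogger(__name__)

#: Rounds eligible for between-round analysis: those preceded by a round
#: with the same treatment under the switch-after-round-3 design.
ELIGIBLE_ROUNDS = (2, 3, 5, 6)


@dataclass
class RoundOutcome:
    session_id: str
    round_index: int
    treatment: str
    phi_max_fit: float
    H_T: float
    previous_phi_max: float | None = None
    previous_H_T: float | None = None


@dataclass
class FeedbackFit:
    """Four-parameter logistic fit ``y = lower + (upper-lower)/(1+exp(slope*(x-midpoint)))``."""

    lower: float
    upper: float
    midpoint: float
    slope: float
    rmse: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            # canonical orientation: swap asymptotes and flip the slope
            self.lower, self.upper = self.upper, self.lower
            self.slope = -self.slope

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(x, dtype=float),
                         self.lower, self.upper, self.midpoint, self.slope)


@dataclass
class ThresholdFit:
    """OLS of previous-round value on current-round value, and its fixed point."""

    intercept: float
    slope: float
    threshold: float
    #: slope < 1: the round-to-round dynamics diverge away from the
    #: threshold (improve above it, deteriorate below it)
    expansive: bool


def discount_rate_from_weight(phi_max: float, T: float) -> float:
    """Exponential discount rate implied by an integrated weight.

    Solves ``(1 - exp(-rho*T))/rho = phi_max`` for ``rho >= 0`` by
    bisection. The left side decreases from ``T`` (at ``rho -> 0``) to 0,
    so a root exists for ``0 < phi_max < T``. For ``phi_max >= T`` the
    undiscounted boundary ``rho = 0`` is returned with a warning.
    """
    if phi_max <= 0:
        raise DomainError(f"phi_max must be > 0, got {phi_max}")
    if T <= 0:
        raise DomainError(f"T must be > 0, got {T}")
    if phi_max >= T:
        warnings.warn(f"phi_max={phi_max} >= T={T}: returning rho=0", stacklevel=2)
        return 0.0

    def f(rho: float) -> float:
        return -math.expm1(-rho * T) / rho - phi_max

    lo, hi = 1e-300, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid input
            raise FitError("bisection bracket not found")
    # f(lo) ~ T - phi_max > 0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _logistic(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(slope * (x - midpoint)))


def fit_logistic_response(x: np.ndarray, y: np.ndarray) -> FeedbackFit:
    """Least-squares fit of a four-parameter logistic to (x, y) points.

    Multi-start from data quantiles; the best converged start wins.
    Flat responses (no y-range) are returned as a degenerate fit with
    both asymptotes at the mean rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be aligned")
    if x.size < 5:
        raise DomainError(f"need at least 5 points, got {x.size}")

    y_span = float(np.ptp(y))
    if y_span < 1e-12 * max(1.0, float(np.abs(y).max())):
        return FeedbackFit(lower=float(y.mean()), upper=float(y.mean()),
                           midpoint=float(np.median(x)), slope=0.0,
                           rmse=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
                           degenerate=True)

    x_span = float(np.ptp(x)) or 1.0
    sign = -1.0 if np.polyfit(x, y, 1)[0] > 0 else 1.0
    starts = []
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        starts.append((
            float(np.quantile(y, 0.05)), float(np.quantile(y, 0.95)),
            float(np.quantile(x, q)), sign * 4.0 / x_span,
        ))

    # a midpoint far outside the sampled x-range is not identifiable;
    # constrain it to the data range padded by half a span
    y_lo, y_hi = float(y.min()) - y_span, float(y.max()) + y_span
    bounds = (
        [y_lo, y_lo, float(x.min()) - 0.5 * x_span, -100.0 / x_span],
        [y_hi, y_hi, float(x.max()) + 0.5 * x_span, 100.0 / x_span],
    )
    best: FeedbackFit | None = None
    errors = []
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_logistic, x, y, p0=p0, bounds=bounds,
                                    maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            errors.append(f"start {p0}: {exc}")
            continue
        resid = y - _logistic(x, *popt)
        fit = FeedbackFit(lower=float(popt[0]), upper=float(popt[1]),
                          midpoint=float(popt[2]), slope=float(popt[3]),
                          rmse=float(np.sqrt(np.mean(resid ** 2))))
        if best is None or fit.rmse < best.rmse:
            best = fit
    if best is None:
        raise FitError("all starts failed:\n" + "\n".join(errors))
    return best


def sustainability_threshold(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> ThresholdFit:
    """Fixed point of the previous-on-current regression.

    ``pairs`` holds ``(current, previous)`` values of the fitted
    discount ceiling. The previous value is regressed on the current one
    (``previous = intercept + slope * current``); the threshold is where
    the regression crosses the identity line:
    ``threshold = intercept / (1 - slope)``. Above it the round-to-round
    dynamics improve, below it they deteriorate.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (current, previous) tuples")
    if arr.shape[0] < 3:
        raise DomainError(f"need at least 3 pairs, got {arr.shape[0]}")
    current, previous = arr[:, 0], arr[:, 1]
    slope, intercept = np.polyfit(current, previous, 1)
    if abs(1.0 - slope) < 1e-6:
        raise FitError("regression parallel to the identity line: no intersection")
    threshold = intercept / (1.0 - slope)
    return ThresholdFit(
        intercept=float(intercept),
        slope=float(slope),
        threshold=float(threshold),
        expansive=bool(slope < 1.0),
    )


def build_round_outcomes(
    report: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
) -> list[RoundOutcome]:
    """Link each eligible round to its same-treatment predecessor.

    ``report`` needs columns ``session_id, round_index, treatment,
    phi_max, H_T`` (one row per calibrated round); a manifest may be
    passed to restrict/validate the rows. Rounds 1 and 4 start a new
    treatment block and are excluded; eligible rounds with a missing
    predecessor row are skipped with a log entry.
    """
    required = {"session_id", "round_index", "treatment", "phi_max", "H_T"}
    missing = required - set(report.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    if manifest is not None:
        keys = set(zip(manifest["session_id"].astype(str), manifest["round_index"].astype(int)))
        mask = [
            (str(s), int(r)) in keys
            for s, r in zip(report["session_id"], report["round_index"])
        ]
        report = report.loc[mask]

    by_key = {
        (str(row.session_id), int(row.round_index)): row
        for row in report.itertuples()
    }
    outcomes: list[RoundOutcome] = []
    for (session, rnd), row in sorted(by_key.items()):
        if rnd not in ELIGIBLE_ROUNDS:
            continue
        prev = by_key.get((session, rnd - 1))
        if prev is None:
            log.warning("session %s round %d: predecessor missing, skipped", session, rnd)
            continue
        if prev.treatment != row.treatment:
            log.warning(
                "session %s round %d: predecessor treatment %s != %s, skipped",
                session, rnd, prev.treatment, row.treatment,
            )
            continue
        outcomes.append(RoundOutcome(
            session_id=session,
            round_index=rnd,
            treatment=str(row.treatment),
            phi_max_fit=float(row.phi_max),
            H_T=float(row.H_T),
            previous_phi_max=float(prev.phi_max),
            previous_H_T=float(prev.H_T),
        ))
    return outcomes
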