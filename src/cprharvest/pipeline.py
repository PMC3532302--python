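"""Convenience wrappers chaining the stages: study -> calibration -> feedback."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import (FeedbackFit, RoundOutcome, ThresholdFit,
                       build_round_outcomes, discount_rate_from_weight,
                       fit_logistic_response, sustainability_threshold)
from .calibration import CalibrationResult, ObservedRound, fit_phi_max, fit_three_params
from .params import ModelParams

__all__ = ["calibrate_rounds", "FeedbackAnalysis", "analyze_feedback"]


def calibrate_rounds(
    rounds: list[ObservedRound],
    params_base: ModelParams,
    mode: str = "one",
    **kwargs,
) -> list[tuple[ObservedRound, CalibrationResult]]:
    """Calibrate every round of a study.

    Punishment availability is set from each round's treatment label
    before fitting; remaining keyword arguments go to the fitter.
    """
    if mode not in ("one", "three"):
        raise ValueError(f"mode must be 'one' or 'three', got {mode!r}")
    fit = fit_phi_max if mode == "one" else fit_three_params
    out = []
    for obs in rounds:
        p = params_base.replace(punishment_on=obs.treatment in ("P", "CP"))
        out.append((obs, fit(obs, p, **kwargs)))
    return out


@dataclass
class FeedbackAnalysis:
    outcomes: list[RoundOutcome]
    pairs: np.ndarray  # columns: current phi_max, previous phi_max
    threshold: ThresholdFit
    logistic: FeedbackFit
    rates: pd.DataFrame  # previous_H_T, rho per eligible round


def analyze_feedback(report: pd.DataFrame, T: float, manifest: pd.DataFrame | None = None) -> FeedbackAnalysis:
    """Between-round analysis of a calibration report.

    Builds the eligible-round outcome list, estimates the
    sustainability threshold from the previous-vs-current regression,
    and fits the sigmoid response of the implied discount rate to the
    previous round's total harvest.
    """
    outcomes = build_round_outcomes(report, manifest)
    pairs = np.array([(o.phi_max_fit, o.previous_phi_max) for o in outcomes])
    threshold = sustainability_threshold(pairs)

    rows = []
    for o in outcomes:
        if o.phi_max_fit <= 0:
            continue
        rho = discount_rate_from_weight(min(o.phi_max_fit, T * (1 - 1e-12)), T)
        rows.append({"session_id": o.session_id, "round_index": o.round_index,
                     "previous_H_T": o.previous_H_T, "rho": rho})
    rates = pd.DataFrame(rows)
    logistic = fit_logistic_response(rates["previous_H_T"].to_numpy(),
                                     rates["rho"].to_numpy())
    return FeedbackAnalysis(outcomes=outcomes, pairs=pairs,
                            threshold=threshold, logistic=logistic, rates=rates)
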