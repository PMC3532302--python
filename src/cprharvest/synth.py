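"""Synthetic pseudo-experimental studies.

Generates noisy sampled resource trajectories with the structure the
analysis pipeline assumes: sessions of six rounds, a treatment change
after round three, and a between-round feedback that maps the previous
same-treatment round's realized total harvest to the next round's
discount ceiling through a logistic response.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import ObservedRound
from .params import DEFAULT_INIT, ModelParams, ModelState
from .simulate import DEFAULT_DT, integrate_round, total_harvest

__all__ = [
    "FeedbackSpec",
    "StudyDesign",
    "SessionDataset",
    "generate_round",
    "generate_session",
    "generate_study",
    "induced_fixed_point",
]

#: Treatment sequences (first half, second half) for the six default sessions.
DEFAULT_SEQUENCES: tuple[tuple[str, str], ...] = (
    ("NCP", "C"), ("NCP", "P"), ("NCP", "CP"),
    ("C", "NCP"), ("P", "NCP"), ("CP", "NCP"),
)

#: Discount ceiling of the first round of each treatment block.
DEFAULT_INITIAL_PHI_MAX: dict[str, float] = {
    "NCP": 5.5, "C": 12.0, "P": 5.0, "CP": 13.0,
}


@dataclass(frozen=True)
class FeedbackSpec:
    """Logistic map from previous total harvest to the next discount ceiling.

    ``phi' = phi_lo + (phi_hi - phi_lo) / (1 + exp(-slope*(H_T - H_star)))``.

    The defaults put the induced fixed point of the composite map
    (harvest model followed by this response) at 8.5 under default
    model parameters, with a contracting round-to-round slope of about
    0.5 there.
    """

    phi_lo: float = 2.0
    phi_hi: float = 15.0
    H_star: float = 195.835
    slope: float = 0.08

    def __call__(self, H_T: float) -> float:
        return self.phi_lo + (self.phi_hi - self.phi_lo) / (
            1.0 + math.exp(-self.slope * (H_T - self.H_star))
        )


@dataclass(frozen=True)
class StudyDesign:
    """Layout and stochastic settings of a synthetic study."""

    n_sessions: int = 6
    rounds_per_session: int = 6
    sequences: tuple[tuple[str, str], ...] = DEFAULT_SEQUENCES
    sampling_interval: float = 5.0
    noise_sigma: float = 2.0
    seed: int = 0
    feedback: FeedbackSpec = field(default_factory=FeedbackSpec)
    initial_phi_max: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_PHI_MAX)
    )
    with_harvest_series: bool = False

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.rounds_per_session < 1:
            raise ValueError("n_sessions and rounds_per_session must be >= 1")
        if self.rounds_per_session % 2 != 0:
            raise ValueError("rounds_per_session must be even (treatment switch at half)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    def treatment_of(self, session_index: int, round_index: int) -> str:
        first, second = self.sequences[session_index % len(self.sequences)]
        return first if round_index <= self.rounds_per_session // 2 else second


@dataclass
class SessionDataset:
    session_id: str
    rounds: list[ObservedRound]
    phi_max_true: list[float]
    H_T_true: list[float]


def _punishment_on(treatment: str) -> bool:
    return treatment in ("P", "CP")


def generate_round(
    params: ModelParams,
    noise_sigma: float,
    sampling_interval: float,
    seed: int | np.random.Generator,
    session_id: str = "S1",
    round_index: int = 1,
    treatment: str = "NCP",
    init: ModelState | None = None,
    with_harvest_series: bool = False,
) -> tuple[ObservedRound, float]:
    """Integrate one round, sample it, and add truncated Gaussian noise.

    Returns the observed round and the model's (noiseless) total
    harvest. The same seed always produces the same output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = integrate_round(params, init=init, dt=DEFAULT_DT, dt_out=1.0)
    n = int(round(params.T / sampling_interval))
    t_obs = np.arange(n + 1) * sampling_interval
    t_obs = t_obs[t_obs <= params.T + 1e-9]
    R_true = np.interp(t_obs, traj.t, traj.R)
    R_obs = np.clip(R_true + rng.normal(0.0, noise_sigma, size=R_true.size)
                    if noise_sigma > 0 else R_true, 0.0, None)
    G_obs = None
    if with_harvest_series:
        G_true = np.interp(t_obs, traj.t, traj.G)
        G_obs = np.clip(G_true + rng.normal(0.0, noise_sigma * 0.01, size=G_true.size)
                        if noise_sigma > 0 else G_true, 0.0, None)
    obs = ObservedRound(
        session_id=session_id,
        round_index=round_index,
        treatment=treatment,
        t_obs=t_obs,
        R_obs=R_obs,
        G_obs=G_obs,
    )
    return obs, total_harvest(traj)


def generate_session(
    design: StudyDesign,
    session_index: int,
    params: ModelParams,
    seed: int | np.random.SeedSequence | None = None,
) -> SessionDataset:
    """Generate one six-round session.

    Rounds 1 and 4 (block starts) use the treatment's initial discount
    ceiling; later rounds receive the ceiling from the feedback applied
    to the previous same-treatment round's realized total harvest.
    Punishment availability follows the treatment label.
    """
    if seed is None:
        seed = np.random.SeedSequence([design.seed, session_index])
    elif isinstance(seed, int):
        seed = np.random.SeedSequence([seed, session_index])
    round_seeds = seed.spawn(design.rounds_per_session)
    session_id = f"S{session_index + 1}"
    half = design.rounds_per_session // 2

    rounds: list[ObservedRound] = []
    phi_true: list[float] = []
    ht_true: list[float] = []
    prev_ht: float | None = None
    for rnd in range(1, design.rounds_per_session + 1):
        treatment = design.treatment_of(session_index, rnd)
        if rnd in (1, half + 1):
            phi = design.initial_phi_max[treatment]
        else:
            phi = design.feedback(prev_ht)
        p = params.replace(phi_max=phi, punishment_on=_punishment_on(treatment))
        obs, ht = generate_round(
            p, design.noise_sigma, design.sampling_interval,
            np.random.default_rng(round_seeds[rnd - 1]),
            session_id=session_id, round_index=rnd, treatment=treatment,
            with_harvest_series=design.with_harvest_series,
        )
        rounds.append(obs)
        phi_true.append(phi)
        ht_true.append(ht)
        prev_ht = ht
    return SessionDataset(session_id=session_id, rounds=rounds,
                          phi_max_true=phi_true, H_T_true=ht_true)


def generate_study(
    design: StudyDesign,
    params: ModelParams | None = None,
    seed: int | None = None,
) -> list[SessionDataset]:
    """Generate all sessions of a study (deterministic in the master seed)."""
    params = ModelParams() if params is None else params
    master = design.seed if seed is None else seed
    return [
        generate_session(design, i, params, seed=master)
        for i in range(design.n_sessions)
    ]


def induced_fixed_point(
    design: StudyDesign,
    params: ModelParams | None = None,
    treatment: str = "NCP",
    tol: float = 1e-6,
) -> float:
    """Fixed point of the composite round-to-round map.

    Solves ``feedback(H_T(phi)) = phi`` by bisection, where ``H_T(phi)``
    is the model's total harvest at discount ceiling ``phi``. This is
    the ground-truth sustainability threshold of a synthetic study.
    """
    params = ModelParams() if params is None else params
    params = params.replace(punishment_on=_punishment_on(treatment))

    def g(phi: float) -> float:
        traj = integrate_round(params.replace(phi_max=phi))
        return design.feedback(total_harvest(traj)) - phi

    lo, hi = design.feedback.phi_lo * 0.5, design.feedback.phi_hi
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValueError("feedback map has no bracketed interior fixed point")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
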