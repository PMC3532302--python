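"""Model parameters and state for the adaptive harvest system.

The group of users is treated as a single adaptive entity: the state
variables are the resource level ``R``, the cumulated net harvest ``H``
and the mean harvest trait ``theta`` (higher theta = more restraint).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "ModelState", "DEFAULT_INIT"]


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, trait bounds and shape parameters of the model.

    Parameters
    ----------
    r, K
        Maximum specific growth rate (1/time) and carrying capacity
        (resource units) of the logistic resource.
    h_max, n
        Maximum specific harvest rate per user (resource units/time)
        and number of users.
    k_min, k_var, q_k
        Half-saturation constant of the Monod harvest term:
        ``k(theta) = k_min + k_var * theta**q_k``.
    theta_min, theta_max
        Bounds of the harvest trait.
    delta
        Rate constant of the adaptive (trait) process.
    p, theta_p, sigma_p
        Specific punishment rate, trait value of the punishment
        maximum, and punishment standard deviation (Gaussian kernel).
    phi_max, a, b, q_phi
        Discount weight: ``phi(theta, t) = phi_max * theta**q_phi /
        (1 + exp(a*(t/T - b)))``. ``phi_max`` is the only parameter
        meant to vary between rounds; ``a`` and ``b`` shape the decay
        of the weight as the round elapses.
    T
        Round duration (time units).
    punishment_on
        Whether punishment is available in the round.
    """

    r: float = 0.03
    K: float = 100.0
    h_max: float = 0.5
    n: int = 5
    k_min: float = 10.0
    k_var: float = 150.0
    q_k: float = 2.0
    theta_min: float = 0.0
    theta_max: float = 1.0
    delta: float = 0.5
    p: float = 0.05
    theta_p: float = 0.5
    sigma_p: float = 0.15
    phi_max: float = 16.5
    a: float = 15.0
    b: float = 0.55
    q_phi: float = 1.0
    T: float = 240.0
    punishment_on: bool = False

    def __post_init__(self) -> None:
        positive = ("r", "K", "h_max", "k_min", "delta", "sigma_p", "T")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.k_var < 0:
            raise ValueError(f"k_var must be >= 0, got {self.k_var}")
        if self.phi_max < 0:
            raise ValueError(f"phi_max must be >= 0, got {self.phi_max}")
        if not self.theta_min < self.theta_max:
            raise ValueError(
                f"theta_min must be < theta_max, got {self.theta_min} >= {self.theta_max}"
            )
        # theta enters as theta**q with possibly non-integer q, and both
        # k(theta) and phi(theta, t) must be non-negative on the whole
        # trait range, so the range itself must be non-negative.
        if self.theta_min < 0:
            raise ValueError(f"theta_min must be >= 0, got {self.theta_min}")
        if self.p < 0:
            raise ValueError(f"p must be >= 0, got {self.p}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_vector(self) -> np.ndarray:
        """Pack into the flat float vector used by the compiled kernel."""
        return np.array(
            [
                self.r, self.K, self.h_max, float(self.n),
                self.k_min, self.k_var, self.q_k,
                self.theta_min, self.theta_max, self.delta,
                self.p, self.theta_p, self.sigma_p,
                self.phi_max, self.a, self.b, self.q_phi,
                self.T, 1.0 if self.punishment_on else 0.0,
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (group aggregates)."""

    R: float
    H: float
    theta: float

    def validate(self, params: ModelParams) -> None:
        if not np.isfinite(self.R) or self.R < 0:
            raise ValueError(f"R must be finite and >= 0, got {self.R}")
        if not np.isfinite(self.H):
            raise ValueError(f"H must be finite, got {self.H}")
        if not params.theta_min <= self.theta <= params.theta_max:
            raise ValueError(
                f"theta={self.theta} outside [{params.theta_min}, {params.theta_max}]"
            )


#: Initial conditions shared by all rounds.
DEFAULT_INIT = ModelState(R=50.0, H=0.0, theta=0.8)
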