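"""YAML configuration: schema, validation, lossless round-trips.

Flat sections: ``model`` (every rate constant and shape parameter),
``solver`` (integration steps), ``calibration`` (search settings),
``design`` (synthetic study layout) and top-level ``output_dir``,
``seed``, ``log_level``. Unknown keys are rejected by name.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import DEFAULT_BOUNDS
from .params import ModelParams
from .synth import FeedbackSpec, StudyDesign

__all__ = ["Config", "SolverSettings", "CalibrationSettings",
           "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class SolverSettings:
    dt: float = 0.05
    dt_out: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt_out <= 0:
            raise ValueError("dt and dt_out must be > 0")
        if self.dt > self.dt_out:
            raise ValueError("dt must be <= dt_out")


@dataclass(frozen=True)
class CalibrationSettings:
    bounds_phi_max: tuple[float, float] = DEFAULT_BOUNDS["phi_max"]
    bounds_a: tuple[float, float] = DEFAULT_BOUNDS["a"]
    bounds_b: tuple[float, float] = DEFAULT_BOUNDS["b"]
    grid_step: float = 0.5
    tol: float = 0.01
    resolution: tuple[int, int, int] = (30, 15, 15)

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {"phi_max": tuple(self.bounds_phi_max),
                "a": tuple(self.bounds_a),
                "b": tuple(self.bounds_b)}


@dataclass(frozen=True)
class Config:
    model: ModelParams = field(default_factory=ModelParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    design: StudyDesign = field(default_factory=StudyDesign)
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "model": dataclasses.asdict(self.model),
            "solver": dataclasses.asdict(self.solver),
            "calibration": dataclasses.asdict(self.calibration),
            "design": dataclasses.asdict(self.design),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        d["design"]["sequences"] = [list(s) for s in self.design.sequences]
        return d


def _build(cls, data: dict, section: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in {section}: {exc}") from exc


def _normalize(obj):
    if isinstance(obj, list):
        return tuple(_normalize(x) for x in obj)
    return obj


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    top_known = {"model", "solver", "calibration", "design",
                 "output_dir", "seed", "log_level"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    model = _build(ModelParams, raw.get("model", {}) or {}, "model")
    solver_raw = {k: _normalize(v) for k, v in (raw.get("solver", {}) or {}).items()}
    solver = _build(SolverSettings, solver_raw, "solver")
    calib_raw = {k: _normalize(v) for k, v in (raw.get("calibration", {}) or {}).items()}
    calib = _build(CalibrationSettings, calib_raw, "calibration")

    design_raw = dict(raw.get("design", {}) or {})
    if "feedback" in design_raw:
        design_raw["feedback"] = _build(FeedbackSpec, design_raw["feedback"] or {},
                                        "design.feedback")
    if "sequences" in design_raw:
        design_raw["sequences"] = tuple(tuple(s) for s in design_raw["sequences"])
    design = _build(StudyDesign, design_raw, "design")

    return Config(
        model=model, solver=solver, calibration=calib, design=design,
        output_dir=str(raw.get("output_dir", "out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: Config) -> str:
    """Stable short hash of the full configuration, for run logs."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
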