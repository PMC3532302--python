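"""CSV readers/writers for trajectories, observed rounds, manifests and reports.

Dialect everywhere: comma-separated, ``.`` decimal, one header row,
UTF-8, LF line endings.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, ObservedRound
from .params import ModelParams
from .simulate import Trajectory
from .synth import SessionDataset

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_observed_round", "read_observed_round",
    "write_study", "read_manifest", "load_observed_rounds",
    "write_calibration_report", "read_calibration_report",
]

MANIFEST_COLUMNS = ["session_id", "round_index", "treatment", "path"]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame({name: getattr(traj, name) for name in Trajectory.SERIES})
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_trajectory(path: str | Path, params: ModelParams | None = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    ``params_used`` is restored from the argument (defaults otherwise);
    ``growth_cum`` is not part of the CSV contract and comes back None.
    """
    df = pd.read_csv(path)
    missing = [c for c in Trajectory.SERIES if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} missing column(s): {missing}")
    series = {name: df[name].to_numpy(dtype=float) for name in Trajectory.SERIES}
    return Trajectory(
        **series,
        H_T=float(series["H"][-1]),
        params_used=params if params is not None else ModelParams(),
    )


def write_observed_round(obs: ObservedRound, path: str | Path) -> None:
    data = {"t": obs.t_obs, "R": obs.R_obs}
    if obs.G_obs is not None:
        data["G"] = obs.G_obs
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n",
                              float_format="%.17g")


def read_observed_round(
    path: str | Path, session_id: str, round_index: int, treatment: str
) -> ObservedRound:
    df = pd.read_csv(path)
    for col in ("t", "R"):
        if col not in df.columns:
            raise ValueError(f"observed-round file {path} missing column {col!r}")
    return ObservedRound(
        session_id=session_id,
        round_index=round_index,
        treatment=treatment,
        t_obs=df["t"].to_numpy(dtype=float),
        R_obs=df["R"].to_numpy(dtype=float),
        G_obs=df["G"].to_numpy(dtype=float) if "G" in df.columns else None,
    )


def write_study(sessions: list[SessionDataset], out_dir: str | Path) -> Path:
    """Write per-round CSVs plus a manifest (and the generating truth).

    Returns the manifest path. The truth table (true discount ceiling
    and total harvest per round) goes to ``truth.csv`` alongside; the
    calibration pipeline only ever reads the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, truth = [], []
    for session in sessions:
        for obs, phi, ht in zip(session.rounds, session.phi_max_true, session.H_T_true):
            fname = f"{session.session_id}_round{obs.round_index}.csv"
            write_observed_round(obs, out_dir / fname)
            rows.append({"session_id": session.session_id,
                         "round_index": obs.round_index,
                         "treatment": obs.treatment,
                         "path": fname})
            truth.append({"session_id": session.session_id,
                          "round_index": obs.round_index,
                          "phi_max_true": phi, "H_T_true": ht})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False, lineterminator="\n")
    pd.DataFrame(truth).to_csv(out_dir / "truth.csv", index=False,
                               lineterminator="\n", float_format="%.17g")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    return df


def load_observed_rounds(manifest_path: str | Path) -> list[ObservedRound]:
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    rounds = []
    for row in df.itertuples():
        path = manifest_path.parent / row.path
        rounds.append(read_observed_round(
            path, str(row.session_id), int(row.round_index), str(row.treatment)))
    return rounds


def write_calibration_report(
    results: list[tuple[ObservedRound, CalibrationResult]], path: str | Path
) -> None:
    rows = []
    for obs, res in results:
        row = {
            "session_id": obs.session_id,
            "round_index": obs.round_index,
            "treatment": obs.treatment,
            "mode": res.mode,
            "phi_max": res.estimates.get("phi_max", np.nan),
            "a": res.estimates.get("a", np.nan),
            "b": res.estimates.get("b", np.nan),
            "rmse": res.rmse_at_optimum,
            "H_T": res.H_T,
            "evaluations": res.evaluations,
            "ill_identified": ";".join(res.ill_identified),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n",
                              float_format="%.17g")


def read_calibration_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"session_id", "round_index", "treatment", "phi_max", "H_T"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration report {path} missing column(s): {sorted(missing)}")
    return df
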