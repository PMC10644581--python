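"""Delimited-text readers/writers for every pipeline artifact."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .gait import StrideMetrics, WalkSummary, strides_to_frame
from .reconstruct import FootTrajectory, ImuRecording

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
TRAJ_COLUMNS = ["t", "x", "y", "z", "vx", "vy", "vz", "pitch_deg"]


def write_imu_csv(rec: ImuRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel, rec.gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False)


def read_imu_csv(path, sample_rate: float | None = None) -> ImuRecording:
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IMU file {path} is missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return ImuRecording(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


def write_trajectory_csv(traj: FootTrajectory, path) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.t, traj.position, traj.velocity, traj.pitch_deg]),
        columns=TRAJ_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> FootTrajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns {missing}")
    return FootTrajectory(
        t=df["t"].to_numpy(dtype=float),
        position=df[["x", "y", "z"]].to_numpy(dtype=float),
        velocity=df[["vx", "vy", "vz"]].to_numpy(dtype=float),
        pitch_deg=df["pitch_deg"].to_numpy(dtype=float),
    )


def write_strides_csv(strides: list[StrideMetrics], path) -> None:
    strides_to_frame(strides).to_csv(path, index=False)


def write_summary(summary: WalkSummary, csv_path=None, json_path=None) -> None:
    row = summary.to_feature_row()
    if csv_path is not None:
        pd.DataFrame([row]).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(row, fh, indent=2)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "faller" not in df.columns:
        raise ValueError(f"cohort file {path} has no 'faller' column")
    if not set(pd.unique(df["faller"])) <= {0, 1}:
        raise ValueError("'faller' must be binary 0/1")
    return df


def load_study_cohort(path, column_map: dict[str, str], faller_column: str = "faller") -> pd.DataFrame:
    """Load an externally deposited cohort table with a config-driven
    column mapping (experimental; the deposit's schema is not standardized,
    so every column of interest must be mapped explicitly)."""
    df = pd.read_csv(path)
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise ValueError(f"study file {path} is missing mapped columns {missing}")
    out = pd.DataFrame({dst: df[src] for dst, src in column_map.items()})
    if faller_column not in df.columns:
        raise ValueError(f"study file {path} has no faller column {faller_column!r}")
    out["faller"] = df[faller_column].astype(int)
    return out
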