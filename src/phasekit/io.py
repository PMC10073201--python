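"""Readers and writers for recordings, trajectories and result tables.

Time series travel as CSV with a ``time_h`` column; parameters and
reports as JSON.  All grids are validated as uniform on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import PDTrajectory, PhaseTrajectory
from .wavelet import WaveletRidge

__all__ = [
    "read_recording",
    "write_recording",
    "write_phase_trajectory",
    "read_phase_trajectory",
    "write_pd_trajectory",
    "write_ridge",
    "RecordingFormatError",
]


class RecordingFormatError(ValueError):
    """The recording file violates the expected CSV layout."""


def _check_uniform(t: np.ndarray) -> None:
    if len(t) < 2:
        raise RecordingFormatError("recording needs at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0],
                                             rtol=1e-6, atol=1e-9):
        raise RecordingFormatError("time grid must be uniform and increasing")


def read_recording(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a CSV recording: ``time_h`` plus one column per region.

    Returns ``(t, {region: series})``.  Raises
    :class:`RecordingFormatError` on a missing time column, non-uniform
    grid, or runs of more than three consecutive NaNs in any region.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise RecordingFormatError(f"{path}: missing 'time_h' column")
    regions = [c for c in df.columns if c != "time_h"]
    if not regions:
        raise RecordingFormatError(f"{path}: no region columns")
    t = df["time_h"].to_numpy(dtype=float)
    _check_uniform(t)
    series = {}
    for region in regions:
        x = df[region].to_numpy(dtype=float)
        nan = np.isnan(x)
        if nan.any():
            run, longest = 0, 0
            for flag in nan:
                run = run + 1 if flag else 0
                longest = max(longest, run)
            if longest > 3:
                raise RecordingFormatError(
                    f"{path}: column {region!r} has a NaN run of {longest} "
                    "samples (max 3); too large to interpolate")
            x = np.interp(t, t[~nan], x[~nan])
        series[region] = x
    return t, series


def write_recording(path: str | Path, t: np.ndarray, series: dict) -> None:
    df = pd.DataFrame({"time_h": t, **series})
    df.to_csv(path, index=False)


def write_phase_trajectory(path: str | Path, traj: PhaseTrajectory) -> None:
    pd.DataFrame({"time_h": traj.t, "theta_a": traj.theta_a,
                  "theta_n": traj.theta_n, "theta_v": traj.theta_v}
                 ).to_csv(path, index=False)


def read_phase_trajectory(path: str | Path) -> PhaseTrajectory:
    df = pd.read_csv(path)
    needed = {"time_h", "theta_a", "theta_n", "theta_v"}
    if not needed.issubset(df.columns):
        raise RecordingFormatError(
            f"{path}: expected columns {sorted(needed)}")
    return PhaseTrajectory(t=df["time_h"].to_numpy(float),
                           theta_a=df["theta_a"].to_numpy(float),
                           theta_n=df["theta_n"].to_numpy(float),
                           theta_v=df["theta_v"].to_numpy(float))


def write_pd_trajectory(path: str | Path, pdt: PDTrajectory) -> None:
    pd.DataFrame({"time_h": pdt.t, "pd_an_h": pdt.theta_an,
                  "pd_av_h": pdt.theta_av}).to_csv(path, index=False)


def write_ridge(path: str | Path, ridge: WaveletRidge) -> None:
    pd.DataFrame({"time_h": ridge.t, "period_h": ridge.period,
                  "phase_rad": ridge.phase, "power": ridge.power,
                  "in_coi": ridge.in_coi.astype(int)}).to_csv(path, index=False)
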