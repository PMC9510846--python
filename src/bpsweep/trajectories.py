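"""Tumor-volume time series and finite-difference growth rates.

A :class:`Trajectory` is the raw observable: volume v(t) sampled at strictly
increasing times (days). A :class:`GradientSeries` holds per-timepoint
estimates of dv/dt, the regression target of the grid sweep. Gradients are
estimated with second-order central differences on the (possibly non-uniform)
interior and first-order one-sided differences at the endpoints — the scheme
``numpy.gradient`` implements with ``edge_order=1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MalformedInputError

__all__ = [
    "Trajectory",
    "GradientSeries",
    "read_trajectory",
    "write_trajectory",
    "estimate_gradients",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise MalformedInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise MalformedInputError(f"{name} contains a non-finite value at row {bad}")
    return arr


@dataclass(frozen=True)
class Trajectory:
    """Timestamped tumor volumes.

    Parameters
    ----------
    times : array-like
        Observation times in days, strictly increasing, length >= 3.
    volumes : array-like
        Tumor volumes (unit-agnostic), strictly positive.
    """

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        volumes = _as_float_array(self.volumes, "volumes")
        if len(times) != len(volumes):
            raise MalformedInputError(
                f"times (n={len(times)}) and volumes (n={len(volumes)}) differ in length"
            )
        if len(times) < 3:
            raise InsufficientDataError(
                f"need at least 3 observations for gradient estimation, got {len(times)}"
            )
        dt = np.diff(times)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise MalformedInputError(
                f"times must be strictly increasing; violation at row {bad} "
                f"(t={times[bad]!r} after t={times[bad - 1]!r})"
            )
        if np.any(volumes <= 0):
            bad = int(np.flatnonzero(volumes <= 0)[0])
            raise MalformedInputError(
                f"volumes must be strictly positive; row {bad} has v={volumes[bad]!r}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "volume": self.volumes})


@dataclass(frozen=True)
class GradientSeries:
    """Per-timepoint estimates of dv/dt (volume units per day)."""

    times: np.ndarray
    dvdt: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        dvdt = _as_float_array(self.dvdt, "dvdt")
        if len(times) != len(dvdt):
            raise MalformedInputError("times and dvdt differ in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dvdt", dvdt)

    def __len__(self) -> int:
        return len(self.times)


def read_trajectory(
    source, time_col: str = "time", volume_col: str = "volume"
) -> Trajectory:
    """Read a trajectory from a two-column CSV file (RFC-4180, '.' decimals).

    The file must have a header row naming the time and volume columns and a
    numeric body. Row order is preserved; unsorted input is an error, never
    silently sorted.
    """
    df = pd.read_csv(source)
    for col in (time_col, volume_col):
        if col not in df.columns:
            raise MalformedInputError(
                f"column {col!r} not found in header {list(df.columns)!r}"
            )
    try:
        times = df[time_col].to_numpy(dtype=float)
        volumes = df[volume_col].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MalformedInputError(f"non-numeric body: {exc}") from exc
    return Trajectory(times, volumes)


def write_trajectory(traj: Trajectory, target, time_col: str = "time",
                     volume_col: str = "volume") -> None:
    """Write a trajectory as CSV with the same schema ``read_trajectory`` reads."""
    df = pd.DataFrame({time_col: traj.times, volume_col: traj.volumes})
    df.to_csv(target, index=False)


def estimate_gradients(traj: Trajectory) -> GradientSeries:
    """Estimate dv/dt at every timepoint by finite differences.

    Interior points use the second-order central scheme for non-uniform
    spacing; the endpoints use first-order one-sided differences. Exact for
    affine v(t) on any grid.
    """
    dvdt = np.gradient(traj.volumes, traj.times, edge_order=1)
    return GradientSeries(traj.times, dvdt)
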