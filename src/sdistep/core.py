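"""Core containers for foot-mounted IMU gait analysis.

Conventions used throughout the package:

* Time is in seconds since trial start; sampling is nominally uniform.
* Accelerometer channels carry specific force in m/s^2 in the sensor frame
  (a level, stationary sensor reads (0, 0, +g)).
* Gyroscope channels carry angular velocity in deg/s in the sensor frame.
* The global frame is z-up; heading (yaw) is unobservable without a
  magnetometer and is initialised to zero per trace, so all horizontal
  quantities are reported via the estimated walking axis.
* Quaternions are Hamilton, scalar-first, and encode the passive
  sensor-to-global rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Standard gravity, m/s^2.
G = 9.80665

SIDES = ("left", "right")


class SdiStepError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SdiStepError):
    """A file does not conform to the documented CSV dialect."""


class DataError(SdiStepError):
    """Input data violate a container invariant (e.g. non-monotonic time)."""


class SyncError(SdiStepError):
    """Two traces cannot be placed on a common clock."""


class CalibrationError(SdiStepError):
    """Quiet-standing calibration failed (movement inside the window)."""


class ParameterError(SdiStepError):
    """A configuration parameter is out of its valid range."""


class InsufficientDataError(SdiStepError):
    """Too few events/samples for the requested computation."""


class PairingError(SdiStepError):
    """Measured and reference step series cannot be paired."""


def _as_float_array(x, name: str, ncol: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if ncol is None:
        if arr.ndim != 1:
            raise DataError(f"{name} must be 1-D, got shape {arr.shape}")
    else:
        if arr.ndim != 2 or arr.shape[1] != ncol:
            raise DataError(f"{name} must have shape (n, {ncol}), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass
class IMUTrace:
    """Timestamped tri-axial accelerometer + gyroscope series for one foot.

    Attributes
    ----------
    side : {"left", "right"}
    fs : float
        Sampling rate in Hz (nominal 128).
    t : (n,) array, seconds
    accel : (n, 3) array, m/s^2, sensor frame
    gyro : (n, 3) array, deg/s, sensor frame
    """

    side: str
    fs: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise DataError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        self.t = _as_float_array(self.t, "t")
        self.accel = _as_float_array(self.accel, "accel", 3)
        self.gyro = _as_float_array(self.gyro, "gyro", 3)
        n = len(self.t)
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise DataError("t, accel and gyro must have equal length")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise DataError(
                f"timestamps not strictly increasing at row {bad[0] + 1} "
                f"(t={self.t[bad[0] + 1]:.6f} s)"
            )

    def validate_rate(self, tol: float = 0.10) -> None:
        """Check sample spacing within ``tol`` of 1/fs and length >= 2*fs."""
        dt = np.diff(self.t)
        nominal = 1.0 / self.fs
        off = np.abs(dt - nominal) > tol * nominal
        if np.any(off):
            i = int(np.nonzero(off)[0][0])
            raise DataError(
                f"sample interval at row {i + 1} is {dt[i]:.6f} s, "
                f"outside {tol:.0%} of nominal {nominal:.6f} s"
            )
        if len(self.t) < 2 * self.fs:
            raise DataError(
                f"trace too short: {len(self.t)} samples < 2*fs = {2 * self.fs:.0f}"
            )

    @property
    def n(self) -> int:
        return len(self.t)

    def copy(self) -> "IMUTrace":
        return replace(
            self, t=self.t.copy(), accel=self.accel.copy(), gyro=self.gyro.copy()
        )


@dataclass
class StandingCalibration:
    """Quiet-standing estimate of the sensor-frame up direction and gyro bias.

    ``gravity_dir`` is the unit vector along which the accelerometer reads +g
    while stationary (i.e. the world "up" expressed in the sensor frame);
    ``gyro_bias`` is in deg/s.
    """

    gravity_dir: np.ndarray
    gyro_bias: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.gravity_dir = _as_float_array(self.gravity_dir, "gravity_dir")
        self.gyro_bias = _as_float_array(self.gyro_bias, "gyro_bias")
        if self.gravity_dir.shape != (3,) or self.gyro_bias.shape != (3,):
            raise DataError("gravity_dir and gyro_bias must be 3-vectors")
        if abs(np.linalg.norm(self.gravity_dir) - 1.0) > 1e-9:
            raise DataError("gravity_dir must have unit norm")
        t0, t1 = self.window
        if t1 - t0 < 1.0:
            raise CalibrationError(
                f"standing window {t1 - t0:.3f} s shorter than 1 s"
            )


FOOT_FLAT = "foot_flat"
SWING = "swing"


@dataclass
class PhaseSegmentation:
    """Alternating foot-flat / swing segments tiling the analysed interval.

    ``segments`` is an ordered list of (phase, t_start, t_end).
    """

    segments: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_phase = None
        prev_end = None
        for phase, t0, t1 in self.segments:
            if phase not in (FOOT_FLAT, SWING):
                raise DataError(f"unknown phase {phase!r}")
            if t1 <= t0:
                raise DataError("segment end must follow its start")
            if prev_end is not None and abs(t0 - prev_end) > 1e-9:
                raise DataError("segments must tile without gaps or overlaps")
            if phase == prev_phase:
                raise DataError("phases must strictly alternate")
            prev_phase, prev_end = phase, t1

    def of_phase(self, phase: str) -> list[tuple[float, float]]:
        return [(t0, t1) for p, t0, t1 in self.segments if p == phase]

    @property
    def swing_count(self) -> int:
        return sum(1 for p, _, _ in self.segments if p == SWING)


@dataclass
class GaitEvents:
    """Swing onsets and heel-strike instants for one foot."""

    side: str
    swing_onsets: np.ndarray
    heel_strikes: np.ndarray

    def __post_init__(self) -> None:
        self.swing_onsets = _as_float_array(self.swing_onsets, "swing_onsets")
        self.heel_strikes = _as_float_array(self.heel_strikes, "heel_strikes")
        for name, arr in (("swing_onsets", self.swing_onsets),
                          ("heel_strikes", self.heel_strikes)):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise DataError(f"{name} must be strictly increasing")


@dataclass
class OrientationSeries:
    """Unit quaternion (Hamilton, scalar-first, sensor-to-global) per sample."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.q = _as_float_array(self.q, "q", 4)
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise DataError("quaternions must be unit-norm within 1e-9")
        dots = np.sum(self.q[:-1] * self.q[1:], axis=1)
        if np.any(dots < 0):
            raise DataError("quaternion series has a sign flip")


@dataclass
class GlobalAccelTrace:
    """Gravity-free linear acceleration in the global (z-up) frame."""

    t: np.ndarray
    a_global: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.a_global = _as_float_array(self.a_global, "a_global", 3)


@dataclass
class KinematicTrace:
    """Drift-corrected velocity and position of one foot, global frame.

    Positions are relative to the shared quiet-standing origin (velocity is
    identically zero there), so both feet live in one coordinate system.
    """

    t: np.ndarray
    v: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.v = _as_float_array(self.v, "v", 3)
        self.p = _as_float_array(self.p, "p", 3)


STEP_COLUMNS = ["index", "side", "t_strike", "step_time", "step_length"]


@dataclass
class StepSeries:
    """Ordered per-step records from merged bilateral heel strikes.

    ``steps`` is a DataFrame with columns index, side, t_strike (s),
    step_time (s), step_length (m). Each record describes the step that
    *ends* at ``t_strike`` of foot ``side``: its duration since the previous
    (opposite-foot) strike and the anterior-posterior progression.
    """

    steps: pd.DataFrame
    walking_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in STEP_COLUMNS if c not in self.steps.columns]
        if missing:
            raise DataError(f"step table missing columns {missing}")
        self.steps = self.steps.loc[:, STEP_COLUMNS].reset_index(drop=True)
        if len(self.steps):
            ts = self.steps["t_strike"].to_numpy(float)
            if np.any(np.diff(ts) <= 0):
                raise DataError("t_strike must be strictly increasing")
            if (self.steps["step_time"] <= 0).any():
                raise DataError("step_time must be positive")
        if self.walking_axis is not None:
            self.walking_axis = _as_float_array(self.walking_axis, "walking_axis")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, float, float, float]],
        walking_axis: Sequence[float] | None = None,
    ) -> "StepSeries":
        """Build from (side, t_strike, step_time, step_length) tuples."""
        rows = [
            {"index": i, "side": s, "t_strike": t, "step_time": dt,
             "step_length": dl}
            for i, (s, t, dt, dl) in enumerate(records)
        ]
        df = pd.DataFrame(rows, columns=STEP_COLUMNS)
        axis = None if walking_axis is None else np.asarray(walking_axis, float)
        return cls(df, axis)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def step_times(self) -> np.ndarray:
        return self.steps["step_time"].to_numpy(float)

    @property
    def step_lengths(self) -> np.ndarray:
        return self.steps["step_length"].to_numpy(float)

    @property
    def strike_times(self) -> np.ndarray:
        return self.steps["t_strike"].to_numpy(float)

    @property
    def sides(self) -> np.ndarray:
        return self.steps["side"].to_numpy()

    def for_side(self, side: str) -> pd.DataFrame:
        return self.steps[self.steps["side"] == side]
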