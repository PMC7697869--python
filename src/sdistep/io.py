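"""Reading, writing, synchronising and calibrating IMU traces and step tables.

The CSV dialect is this package's own (vendor formats vary): header
``time_s,ax_mps2,ay_mps2,az_mps2,gx_dps,gy_dps,gz_dps``, comma separated,
``.`` decimal, optional ``#`` comment lines.  Accepted alternates:
``time_ms`` (milliseconds, divided by 1000 on load) and accelerometer
columns in g (``ax_g`` etc., multiplied by standard gravity).  Magnetometer
columns, if present, are ignored: the pipeline uses only accelerometer and
gyroscope.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    G,
    CalibrationError,
    DataError,
    FormatError,
    IMUTrace,
    InsufficientDataError,
    StandingCalibration,
    StepSeries,
    SyncError,
    STEP_COLUMNS,
)

_TIME_COLS = {"time_s": 1.0, "time_ms": 1e-3}
_ACCEL_COLS = {
    "ax": [("ax_mps2", 1.0), ("ax_g", G)],
    "ay": [("ay_mps2", 1.0), ("ay_g", G)],
    "az": [("az_mps2", 1.0), ("az_g", G)],
}
_GYRO_COLS = {"gx": "gx_dps", "gy": "gy_dps", "gz": "gz_dps"}


def load_imu_csv(path: str, side: str, fs: float = 128.0) -> IMUTrace:
    """Read one foot's IMU trace from CSV.

    Units are converted to m/s^2 and deg/s according to the header names;
    a ``time_ms`` column is converted to seconds.

    Raises
    ------
    FormatError
        if a required column is absent.
    DataError
        if timestamps are not strictly increasing (the message cites the
        first offending data row, 1-based).
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip() for c in df.columns]

    tcol = next((c for c in _TIME_COLS if c in df.columns), None)
    if tcol is None:
        raise FormatError(f"{path}: missing time column (time_s or time_ms)")
    t = df[tcol].to_numpy(float) * _TIME_COLS[tcol]

    accel = np.empty((len(df), 3))
    for j, axis in enumerate(("ax", "ay", "az")):
        for name, scale in _ACCEL_COLS[axis]:
            if name in df.columns:
                accel[:, j] = df[name].to_numpy(float) * scale
                break
        else:
            raise FormatError(
                f"{path}: missing accelerometer column {axis}_mps2 (or {axis}_g)"
            )

    gyro = np.empty((len(df), 3))
    for j, axis in enumerate(("gx", "gy", "gz")):
        name = _GYRO_COLS[axis]
        if name not in df.columns:
            raise FormatError(f"{path}: missing gyroscope column {name}")
        gyro[:, j] = df[name].to_numpy(float)

    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise DataError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2} "
            f"(t={t[bad[0] + 1]!r})"
        )
    return IMUTrace(side=side, fs=fs, t=t, accel=accel, gyro=gyro)


def write_imu_csv(trace: IMUTrace, path: str) -> None:
    """Write a trace in the canonical dialect (10 significant digits)."""
    df = pd.DataFrame(
        {
            "time_s": trace.t,
            "ax_mps2": trace.accel[:, 0],
            "ay_mps2": trace.accel[:, 1],
            "az_mps2": trace.accel[:, 2],
            "gx_dps": trace.gyro[:, 0],
            "gy_dps": trace.gyro[:, 1],
            "gz_dps": trace.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def synchronize_pair(left: IMUTrace, right: IMUTrace) -> tuple[IMUTrace, IMUTrace]:
    """Crop both traces to their common interval and resample onto a shared
    uniform grid at min(fs_left, fs_right) by linear interpolation.

    Idempotent: traces already on the common grid are returned value-equal.
    """
    t0 = max(left.t[0], right.t[0])
    t1 = min(left.t[-1], right.t[-1])
    if t1 - t0 < 2.0:
        raise SyncError(
            f"traces overlap {max(t1 - t0, 0):.3f} s < 2 s "
            f"(left [{left.t[0]:.3f}, {left.t[-1]:.3f}], "
            f"right [{right.t[0]:.3f}, {right.t[-1]:.3f}])"
        )
    fs = min(left.fs, right.fs)
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs

    def _resample(tr: IMUTrace) -> IMUTrace:
        if (
            tr.fs == fs
            and len(tr.t) == n
            and abs(tr.t[0] - t0) < 1e-12
            and abs(tr.t[-1] - grid[-1]) < 1e-12
        ):
            return tr.copy()
        accel = np.column_stack(
            [np.interp(grid, tr.t, tr.accel[:, j]) for j in range(3)]
        )
        gyro = np.column_stack(
            [np.interp(grid, tr.t, tr.gyro[:, j]) for j in range(3)]
        )
        return IMUTrace(side=tr.side, fs=fs, t=grid.copy(), accel=accel, gyro=gyro)

    return _resample(left), _resample(right)


def calibrate_standing(
    trace: IMUTrace,
    window: tuple[float, float] | None = None,
    swing_threshold: float = 20.0,
) -> StandingCalibration:
    """Estimate sensor-frame gravity direction and gyro bias while standing.

    With ``window=None`` the window defaults to the first 2 s, auto-shrunk to
    the longest prefix whose gyro norm stays below ``swing_threshold``; an
    explicitly given window must itself be quiet or a CalibrationError names
    the first violating time.
    """
    gnorm = np.linalg.norm(trace.gyro, axis=1)
    if window is None:
        end = min(trace.t[0] + 2.0, trace.t[-1])
        mask = trace.t <= end
        moving = np.nonzero((gnorm >= swing_threshold) & mask)[0]
        if moving.size:
            end = trace.t[moving[0]]
        window = (float(trace.t[0]), float(end))
        sel = (trace.t >= window[0]) & (trace.t < window[1] - 1e-12) if moving.size \
            else (trace.t >= window[0]) & (trace.t <= window[1])
    else:
        if window[0] < trace.t[0] - 1e-9 or window[1] > trace.t[-1] + 1e-9:
            raise CalibrationError("calibration window lies outside the trace")
        sel = (trace.t >= window[0]) & (trace.t <= window[1])
        viol = np.nonzero(sel & (gnorm >= swing_threshold))[0]
        if viol.size:
            raise CalibrationError(
                f"movement inside standing window at t={trace.t[viol[0]]:.3f} s "
                f"(gyro norm {gnorm[viol[0]]:.1f} deg/s)"
            )
    if window[1] - window[0] < 1.0:
        raise CalibrationError(
            f"quiet-standing prefix only {window[1] - window[0]:.3f} s (< 1 s)"
        )
    mean_a = trace.accel[sel].mean(axis=0)
    norm = np.linalg.norm(mean_a)
    if norm == 0:
        raise CalibrationError("zero mean accelerometer vector in window")
    return StandingCalibration(
        gravity_dir=mean_a / norm,
        gyro_bias=trace.gyro[sel].mean(axis=0),
        window=window,
    )


def write_steps_csv(steps: StepSeries, path: str) -> None:
    """Write a step table (header index,side,t_strike_s,step_time_s,step_length_m).

    Values round-trip to 1e-9 relative (10 significant digits). Refuses an empty
    series and does not create the file in that case.
    """
    if len(steps) == 0:
        raise InsufficientDataError("refusing to write an empty step series")
    df = steps.steps.rename(
        columns={
            "t_strike": "t_strike_s",
            "step_time": "step_time_s",
            "step_length": "step_length_m",
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_steps_csv(path: str) -> StepSeries:
    """Read a step table written by :func:`write_steps_csv`."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    rename = {
        "t_strike_s": "t_strike",
        "step_time_s": "step_time",
        "step_length_m": "step_length",
    }
    df = df.rename(columns=rename)
    missing = [c for c in STEP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing step columns {missing}")
    return StepSeries(df)
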