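"""Complementary-filter orientation estimation and gravity removal.

The filter propagates a Hamilton scalar-first quaternion (sensor-to-global)
with the gyroscope and, at each sample, blends in the accelerometer-derived
tilt with weight ``1 - alpha`` (gyro weight ``alpha``).  Heading is
unobservable without a magnetometer: the initial quaternion aligns the
calibrated gravity direction with global +z through the *smallest* rotation
(zero initial yaw), and downstream step metrics are yaw-invariant by
construction (walking-axis projection).

Tilt blending is suspended outside quasi-static conditions — whenever, at
any point in the trailing 0.15 s, the accelerometer norm deviates from g
by more than 20% or the gyro norm exceeds a quasi-static gate (default
20 deg/s).  During the high-dynamics swing the accelerometer measures
mostly linear acceleration, not gravity: its norm can transit the
acceptance band while pointing far from vertical (momentarily also with a
quiet gyro, e.g. between push-off and heel-strike rotation bursts), which
is why the condition must hold over a window rather than instantaneously.
The foot-flat phases provide ample quasi-static time for the tilt
reference to rein in gyro drift.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    G,
    DataError,
    GlobalAccelTrace,
    IMUTrace,
    OrientationSeries,
    ParameterError,
    StandingCalibration,
)

logger = logging.getLogger(__name__)

_DEG = math.pi / 180.0


def _quat_mult(q, r):
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return (
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    )


def _quat_normalize(q):
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def _quat_from_axis_angle(axis, angle):
    half = 0.5 * angle
    s = math.sin(half)
    return (math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s)


def _rotate(q, v):
    """Rotate vector v by quaternion q (sensor -> global)."""
    w, x, y, z = q
    vx, vy, vz = v
    # q * (0, v) * q^-1, expanded
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return (
        vx + w * tx + (y * tz - z * ty),
        vy + w * ty + (z * tx - x * tz),
        vz + w * tz + (x * ty - y * tx),
    )


def _initial_quaternion(gravity_dir: np.ndarray) -> tuple:
    """Smallest rotation taking the sensor-frame up direction to global +z."""
    u = gravity_dir / np.linalg.norm(gravity_dir)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(u, z), -1.0, 1.0))
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return (1.0, 0.0, 0.0, 0.0)
        # upside-down: rotate pi about x (any horizontal axis works)
        return (0.0, 1.0, 0.0, 0.0)
    axis = axis / s
    angle = math.atan2(s, c)
    return _quat_from_axis_angle(axis, angle)


def complementary_orientation(
    trace: IMUTrace,
    calib: StandingCalibration,
    alpha: float = 0.98,
    gyro_gate_dps: float = 20.0,
) -> OrientationSeries:
    """Estimate the sensor-to-global orientation at every sample.

    ``trace`` must already be gyro-bias-corrected (and normally filtered).
    ``alpha`` in (0, 1) is the per-sample gyro weight; ``alpha = 1`` would
    be pure strap-down integration and is rejected here (use a value like
    ``1 - 1e-12`` to approximate it in tests).  ``gyro_gate_dps`` is the
    quasi-static gate above which tilt blending is suspended.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")

    t = trace.t
    gyro_rad = trace.gyro * _DEG
    accel = trace.accel
    anorm = np.linalg.norm(accel, axis=1)
    gnorm = np.linalg.norm(trace.gyro, axis=1)
    quasi_static = (np.abs(anorm - G) <= 0.2 * G) & (gnorm <= gyro_gate_dps)
    # sustained stillness: every sample within +/-0.15 s quasi-static, so
    # tilt updates stop before a movement transition corrupts the reference
    fs_est = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    k = max(int(round(0.15 * fs_est)), 1)
    bad = np.cumsum(np.concatenate(([0], (~quasi_static).astype(int))))
    idx = np.arange(len(t))
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k + 1, len(t))
    reliable = (bad[hi] - bad[lo]) == 0

    # warn about long unreliable stretches (tilt reference unusable)
    low = anorm < 0.5 * G
    if low.any():
        d = np.diff(np.concatenate(([0], low.astype(int), [0])))
        starts, ends = np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]
        for i0, i1 in zip(starts, ends):
            if t[min(i1, len(t) - 1)] - t[i0] > 0.5:
                logger.warning(
                    "accelerometer norm < 0.5 g for %.2f s from t=%.3f s; "
                    "tilt reference unreliable",
                    t[min(i1, len(t) - 1)] - t[i0], t[i0],
                )
                break

    q = _initial_quaternion(calib.gravity_dir)
    n = len(t)
    out = np.empty((n, 4))
    out[0] = q
    tilt_gain = 1.0 - alpha

    for i in range(1, n):
        dt = t[i] - t[i - 1]
        # gyro propagation with the midpoint rate
        wx = 0.5 * (gyro_rad[i - 1, 0] + gyro_rad[i, 0])
        wy = 0.5 * (gyro_rad[i - 1, 1] + gyro_rad[i, 1])
        wz = 0.5 * (gyro_rad[i - 1, 2] + gyro_rad[i, 2])
        wn = math.sqrt(wx * wx + wy * wy + wz * wz)
        if wn > 1e-12:
            dq = _quat_from_axis_angle((wx / wn, wy / wn, wz / wn), wn * dt)
            q = _quat_mult(q, dq)

        if reliable[i]:
            an = anorm[i]
            u = (accel[i, 0] / an, accel[i, 1] / an, accel[i, 2] / an)
            vx, vy, vz = _rotate(q, u)  # measured up, world frame
            # rotation correcting v toward +z, applied fractionally
            cx, cy = vy, -vx  # v x z
            s = math.sqrt(cx * cx + cy * cy)
            if s > 1e-12:
                ang = math.atan2(s, max(min(vz, 1.0), -1.0))
                corr = _quat_from_axis_angle((cx / s, cy / s, 0.0), tilt_gain * ang)
                q = _quat_mult(corr, q)

        q = _quat_normalize(q)
        if (
            q[0] * out[i - 1, 0] + q[1] * out[i - 1, 1]
            + q[2] * out[i - 1, 2] + q[3] * out[i - 1, 3]
        ) < 0.0:
            q = (-q[0], -q[1], -q[2], -q[3])
        out[i] = q

    return OrientationSeries(t=t.copy(), q=out)


def to_global_linear_accel(
    trace: IMUTrace, orient: OrientationSeries
) -> GlobalAccelTrace:
    """Rotate accelerometer samples to the global frame and remove gravity."""
    if len(trace.t) != len(orient.t) or np.any(np.abs(trace.t - orient.t) > 1e-9):
        raise DataError("trace and orientation series are on different time grids")
    # scipy uses scalar-last quaternions
    rot = Rotation.from_quat(orient.q[:, [1, 2, 3, 0]])
    a_world = rot.apply(trace.accel)
    a_world[:, 2] -= G
    return GlobalAccelTrace(t=trace.t.copy(), a_global=a_world)
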