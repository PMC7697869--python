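"""Forward simulator of bilateral foot-IMU recordings with exact ground truth.

The simulator emulates the standard validation protocol for wearable gait
systems: a few seconds of quiet standing, then straight-line walking at a
configurable mean step length and step time, with lognormal step-to-step
variability, optional left-right step-length asymmetry, sensor noise and
gyroscope bias.  It stands in for a laboratory reference system (pressure
walkway / optoelectronic capture): the ground truth it emits is exact by
construction.

Foot model (per swing of duration D ending at the heel strike T):

* anterior-posterior translation follows a minimum-jerk profile,
* vertical heel lift is ``h * sin^2(pi s)`` (3 cm default peak), so the
  heel's vertical minimum is reached exactly at T — the ground-truth
  heel-strike convention,
* sagittal (pitch) angular velocity is a positive raised-cosine
  dorsiflexion lobe plus a sharper negative raised-cosine pulse centred at
  T (the heel-strike signature), their areas matched so net foot pitch per
  stride is zero.  The lobe starts 0.25 D *before* the translation does,
  emulating the heel-off/push-off foot roll of terminal double support:
  the foot rotates before it leaves the ground, so an angular-rate
  threshold fires before any forward displacement occurs.  Centring the
  negative pulse at T and making it symmetric means the
  sagittal-gyro-minimum detection convention coincides with the
  vertical-minimum truth convention by construction, so recovery error
  isolates algorithm error rather than a definition mismatch.  A toe-off
  plantarflexion spike is deliberately omitted: it would add a second
  negative extremum with no counterpart in the truth tables.

Ideal sensor signals are obtained by rotating world acceleration plus
gravity into the foot frame through the true orientation; Gaussian noise
and a constant gyro bias are added last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import G, IMUTrace, ParameterError, StepSeries

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for one simulated trial.

    Means are per step; ``asymmetry_pct`` a splits the step-length mean as
    left = mean*(1 + a/200), right = mean*(1 - a/200), so (L - R)/mean = a%.
    ``stance_fraction`` is the fraction of a stride spent in foot-flat.
    Noise sigmas are per-axis Gaussian; ``gyro_bias_dps`` is a constant
    3-vector added to the gyroscope.
    """

    n_steps: int = 50
    step_length_mean: float = 0.65
    step_time_mean: float = 0.55
    cv_length: float = 0.0
    cv_time: float = 0.0
    asymmetry_pct: float = 0.0
    stance_fraction: float = 0.6
    fs: float = 128.0
    standing_s: float = 3.0
    accel_noise_sigma: float = 0.0
    gyro_noise_sigma: float = 0.0
    gyro_bias_dps: tuple[float, float, float] = (0.0, 0.0, 0.0)
    heading_deg: float = 0.0
    seed: int = 0
    lift_height_m: float = 0.03
    pitch_excursion_deg: float = 30.0
    heel_pulse_frac: float = 0.18
    lateral_offset_m: float = 0.05
    swing_min_s: float = 0.25
    swing_max_s: float = 0.80

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if min(self.step_length_mean, self.step_time_mean) <= 0:
            raise ParameterError("step means must be positive")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ParameterError("stance_fraction must lie in (0, 1)")
        if min(self.cv_length, self.cv_time) < 0:
            raise ParameterError("coefficients of variation must be >= 0")
        if self.fs <= 0 or self.standing_s < 1.0:
            raise ParameterError("fs must be positive and standing_s >= 1 s")


@dataclass
class GroundTruth:
    """Exact per-trial truth emitted alongside the simulated traces."""

    steps: StepSeries
    strike_times: dict[str, np.ndarray]
    strike_ap: dict[str, np.ndarray]
    swing_onsets: dict[str, np.ndarray]
    activity_intervals: dict[str, np.ndarray]  # (k, 2) gyro-active spans
    gravity_dir: np.ndarray
    gyro_bias: np.ndarray
    walking_axis: np.ndarray
    t: np.ndarray = field(repr=False, default=None)
    a_world: dict[str, np.ndarray] = field(repr=False, default=None)
    v_world: dict[str, np.ndarray] = field(repr=False, default=None)
    pitch_deg: dict[str, np.ndarray] = field(repr=False, default=None)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _pulse(t: np.ndarray, center: float, halfwidth: float, amp: float) -> np.ndarray:
    """Raised-cosine (cos^2) pulse; area = amp * halfwidth."""
    u = t - center
    out = np.zeros_like(t)
    sel = np.abs(u) <= halfwidth
    out[sel] = amp * np.cos(np.pi * u[sel] / (2.0 * halfwidth)) ** 2
    return out


def _pulse_integral(t: np.ndarray, center: float, halfwidth: float, amp: float) -> np.ndarray:
    """Running integral of the raised-cosine pulse."""
    u = np.clip(t - center, -halfwidth, halfwidth)
    return amp * (
        0.5 * (u + halfwidth)
        + (halfwidth / (2.0 * np.pi)) * np.sin(np.pi * u / halfwidth)
    )


@dataclass
class _Swing:
    side: str
    t_end: float  # heel-strike time
    duration: float
    ap_from: float
    ap_to: float


def _swing_onset_time(sw: _Swing, cfg: GaitSimConfig, threshold: float = 20.0) -> float:
    """First time the ideal gyro norm reaches ``threshold`` (deg/s)."""
    d = sw.duration
    pre = 0.25 * d
    w = 0.5 * (d + pre)
    c = sw.t_end - d - pre + w
    m_amp = cfg.pitch_excursion_deg / w
    if m_amp <= threshold:
        return sw.t_end - d - pre
    u = (2.0 * w / np.pi) * math.acos(math.sqrt(threshold / m_amp))
    return c - u


def simulate_gait(cfg: GaitSimConfig) -> tuple[IMUTrace, IMUTrace, GroundTruth]:
    """Simulate one straight-line walking trial.

    Returns the left and right foot IMU traces (shared uniform time grid)
    and the exact ground truth.  Deterministic for a given config: the same
    seed yields bit-identical traces.
    """
    rng = np.random.default_rng(cfg.seed)
    n_strikes = cfg.n_steps + 1

    # step draws; strike j has side left for even j
    dt = np.clip(
        _lognormal(rng, cfg.step_time_mean, cfg.cv_time, n_strikes), 0.25, None
    )
    sides = np.array(["left" if j % 2 == 0 else "right" for j in range(n_strikes)])
    mean_l = cfg.step_length_mean * (1.0 + cfg.asymmetry_pct / 200.0)
    mean_r = cfg.step_length_mean * (1.0 - cfg.asymmetry_pct / 200.0)
    lengths = np.where(
        sides == "left",
        np.clip(_lognormal(rng, mean_l, cfg.cv_length, n_strikes), 0.05, None),
        np.clip(_lognormal(rng, mean_r, cfg.cv_length, n_strikes), 0.05, None),
    )

    t_strike = cfg.standing_s + np.cumsum(dt)
    ap = np.empty(n_strikes)
    ap[0] = 0.5 * lengths[0]  # gait-initiation half step
    ap[1:] = ap[0] + np.cumsum(lengths[1:])

    swing_frac = 1.0 - cfg.stance_fraction
    swings: dict[str, list[_Swing]] = {"left": [], "right": []}
    for j in range(n_strikes):
        side = sides[j]
        if j < 2:
            duration = swing_frac * 2.0 * cfg.step_time_mean
            # keep the pre-roll clear of the standing calibration window
            duration = min(duration, (t_strike[j] - 0.8 * cfg.standing_s) / 1.4)
            ap_from = 0.0
        else:
            # swing time is physiologically conserved; step-to-step timing
            # variability loads on stance (hesitation), not on swing speed
            duration = swing_frac * (t_strike[j] - t_strike[j - 2])
            ap_from = ap[j - 2]
        duration = float(np.clip(duration, cfg.swing_min_s, cfg.swing_max_s))
        if duration * cfg.fs <= 3:
            raise ParameterError(
                f"infeasible kinematics: swing {j} lasts {duration * cfg.fs:.1f} "
                "samples"
            )
        swings[side].append(
            _Swing(side=side, t_end=float(t_strike[j]), duration=float(duration),
                   ap_from=float(ap_from), ap_to=float(ap[j]))
        )

    last_pulse_end = t_strike[-1] + cfg.heel_pulse_frac * swings[sides[-1]][-1].duration
    t_total = last_pulse_end + 2.0
    n = int(math.ceil(t_total * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    psi = cfg.heading_deg * _DEG
    fwd = np.array([math.cos(psi), math.sin(psi), 0.0])
    lat = np.array([-math.sin(psi), math.cos(psi), 0.0])
    rot_z = np.array(
        [[math.cos(psi), -math.sin(psi), 0.0],
         [math.sin(psi), math.cos(psi), 0.0],
         [0.0, 0.0, 1.0]]
    )

    traces: dict[str, IMUTrace] = {}
    truth_a_world: dict[str, np.ndarray] = {}
    truth_v_world: dict[str, np.ndarray] = {}
    truth_pitch: dict[str, np.ndarray] = {}
    onsets: dict[str, np.ndarray] = {}
    activity: dict[str, np.ndarray] = {}

    for side in ("left", "right"):
        ap_acc = np.zeros(n)
        ap_vel = np.zeros(n)
        z_acc = np.zeros(n)
        z_vel = np.zeros(n)
        gyro_pitch = np.zeros(n)
        pitch_deg = np.zeros(n)
        spans = []

        for sw in swings[side]:
            d = sw.duration
            t0 = sw.t_end - d
            sel = (t >= t0) & (t <= sw.t_end)
            s = (t[sel] - t0) / d
            dp = sw.ap_to - sw.ap_from
            ap_vel[sel] = dp / d * (30 * s**2 - 60 * s**3 + 30 * s**4)
            ap_acc[sel] = dp / d**2 * (60 * s - 180 * s**2 + 120 * s**3)
            h = cfg.lift_height_m
            z_vel[sel] = h * (np.pi / d) * np.sin(2 * np.pi * s)
            z_acc[sel] = h * (2 * np.pi**2 / d**2) * np.cos(2 * np.pi * s)

            # dorsiflexion lobe spans [t0 - pre-roll, strike]; heel pulse
            # is symmetric about the strike; areas match (zero net pitch)
            pre = 0.25 * d
            w_pos = 0.5 * (d + pre)
            c_pos = t0 - pre + w_pos
            m_amp = cfg.pitch_excursion_deg / w_pos
            # impact transients do not scale with cadence: floor the
            # heel-pulse width so fast steps keep a filter-visible signature
            c_neg, w_neg = sw.t_end, max(cfg.heel_pulse_frac * d, 0.12)
            h_amp = cfg.pitch_excursion_deg / w_neg
            gyro_pitch += _pulse(t, c_pos, w_pos, m_amp)
            gyro_pitch -= _pulse(t, c_neg, w_neg, h_amp)
            pitch_deg += _pulse_integral(t, c_pos, w_pos, m_amp)
            pitch_deg -= _pulse_integral(t, c_neg, w_neg, h_amp)
            spans.append((t0 - pre, sw.t_end + w_neg))

        a_world = np.outer(ap_acc, fwd)
        a_world[:, 2] += z_acc
        v_world = np.outer(ap_vel, fwd)
        v_world[:, 2] += z_vel

        # sensor-to-world rotation R = Rz(psi) @ Ry(pitch); ideal specific
        # force f = R^T (a_world + g z); body rate = (0, pitch_rate, 0)
        phi = pitch_deg * _DEG
        cphi, sphi = np.cos(phi), np.sin(phi)
        a_plus_g = a_world.copy()
        a_plus_g[:, 2] += G
        a_local = a_plus_g @ rot_z  # Rz^T applied to each row
        accel = np.empty_like(a_local)
        accel[:, 0] = cphi * a_local[:, 0] - sphi * a_local[:, 2]
        accel[:, 1] = a_local[:, 1]
        accel[:, 2] = sphi * a_local[:, 0] + cphi * a_local[:, 2]

        gyro = np.zeros((n, 3))
        gyro[:, 1] = gyro_pitch

        if cfg.accel_noise_sigma > 0:
            accel = accel + rng.normal(0.0, cfg.accel_noise_sigma, (n, 3))
        gyro = gyro + np.asarray(cfg.gyro_bias_dps, float)
        if cfg.gyro_noise_sigma > 0:
            gyro = gyro + rng.normal(0.0, cfg.gyro_noise_sigma, (n, 3))

        traces[side] = IMUTrace(side=side, fs=cfg.fs, t=t.copy(), accel=accel, gyro=gyro)
        truth_a_world[side] = a_world
        truth_v_world[side] = v_world
        truth_pitch[side] = pitch_deg
        onsets[side] = np.array([_swing_onset_time(sw, cfg) for sw in swings[side]])
        activity[side] = np.array(spans)

    records = [
        (sides[j], float(t_strike[j]), float(dt[j]), float(lengths[j]))
        for j in range(1, n_strikes)
    ]
    truth_steps = StepSeries.from_records(records, walking_axis=fwd[:2])

    truth = GroundTruth(
        steps=truth_steps,
        strike_times={
            s: t_strike[sides == s].astype(float) for s in ("left", "right")
        },
        strike_ap={s: ap[sides == s].astype(float) for s in ("left", "right")},
        swing_onsets=onsets,
        activity_intervals=activity,
        gravity_dir=np.array([0.0, 0.0, 1.0]),
        gyro_bias=np.asarray(cfg.gyro_bias_dps, float),
        walking_axis=fwd[:2],
        t=t,
        a_world=truth_a_world,
        v_world=truth_v_world,
        pitch_deg=truth_pitch,
    )
    return traces["left"], traces["right"], truth


def pd_preset(**overrides) -> GaitSimConfig:
    """Parkinsonian gait conditions: short, slow, variable steps
    (population mean step length 0.59 m with 0.11 m SD; step time 0.73 s
    with 0.26 s SD) and a blunted heel-strike pitch signature."""
    base = dict(
        step_length_mean=0.59,
        step_time_mean=0.73,
        cv_length=0.11 / 0.59,
        cv_time=0.26 / 0.73,
        pitch_excursion_deg=24.0,
    )
    base.update(overrides)
    return GaitSimConfig(**base)


def ya_preset(**overrides) -> GaitSimConfig:
    """Healthy young-adult gait: 0.68 m (0.09 m SD) steps at 0.59 s
    (0.06 s SD)."""
    base = dict(
        step_length_mean=0.68,
        step_time_mean=0.59,
        cv_length=0.09 / 0.68,
        cv_time=0.06 / 0.59,
        pitch_excursion_deg=32.0,
    )
    base.update(overrides)
    return GaitSimConfig(**base)
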