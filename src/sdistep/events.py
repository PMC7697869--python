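"""Stride segmentation and heel-strike detection.

Swing phases are delimited by the filtered gyro-norm crossing a threshold
(default 20 deg/s): an upward crossing opens a swing, a downward crossing
returns to foot-flat.  Candidate phases shorter than a debounce duration
are merged into their neighbours.  Heel strikes are then located, for each
swing onset, at the minimum of the sagittal-plane (mediolateral-axis) gyro
component within one estimated stride duration — the standard foot-IMU
heel-strike signature, a sharp negative sagittal spike at ground contact.

The sagittal axis can be fixed by configuration or identified automatically
as the gyro axis with the largest variance during swing; its sign is chosen
so that the sustained mid-swing rotation (dorsiflexion-plantarflexion lobe)
is positive, making the heel-strike spike a minimum regardless of how the
sensor was mounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    FOOT_FLAT,
    SWING,
    DataError,
    GaitEvents,
    IMUTrace,
    InsufficientDataError,
    ParameterError,
    PhaseSegmentation,
)

logger = logging.getLogger(__name__)

AXIS_MODES = ("auto", "x", "y", "z", "norm")


@dataclass(frozen=True)
class EventConfig:
    """Gait-event detection settings.

    swing_threshold : deg/s, gyro-norm level separating swing from
        foot-flat (default 20 — the lowest level that avoids false swing
        onsets on typical foot-mounted recordings).
    min_phase_duration : s, debounce — candidate phases shorter than this
        are merged into their neighbours (default 0.1 s).
    stride_window_factor : heel strikes are searched within this multiple of
        the mean stride duration after each swing onset (default 1.0).
    axis_mode : sagittal-axis choice for the heel-strike minimum.
    """

    swing_threshold: float = 20.0
    min_phase_duration: float = 0.1
    stride_window_factor: float = 1.0
    axis_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.swing_threshold <= 0:
            raise ParameterError("swing_threshold must be positive")
        if self.min_phase_duration < 0:
            raise ParameterError("min_phase_duration must be >= 0")
        if self.stride_window_factor <= 0:
            raise ParameterError("stride_window_factor must be positive")
        if self.axis_mode not in AXIS_MODES:
            raise ParameterError(f"axis_mode must be one of {AXIS_MODES}")


def _merge_short(bounds: list[list], min_dur: float) -> list[list]:
    """Merge segments shorter than ``min_dur`` into their neighbours.

    Shortest-first; merging a segment joins its two like-phase neighbours.
    Entries are [phase, t0, t1].
    """
    segs = [list(s) for s in bounds]
    while len(segs) > 1:
        durations = [s[2] - s[1] for s in segs]
        i = int(np.argmin(durations))
        if durations[i] >= min_dur:
            break
        if i == 0:
            segs[1][1] = segs[0][1]
            del segs[0]
        elif i == len(segs) - 1:
            segs[-2][2] = segs[-1][2]
            del segs[-1]
        else:
            # interior: neighbours share a phase; fuse all three
            segs[i - 1][2] = segs[i + 1][2]
            del segs[i : i + 2]
    return segs


def segment_phases(trace: IMUTrace, cfg: EventConfig = EventConfig()) -> PhaseSegmentation:
    """Split a filtered, bias-corrected trace into foot-flat/swing segments.

    Raises ``InsufficientDataError`` ("no gait detected") if the gyro norm
    never crosses the threshold.
    """
    gnorm = np.linalg.norm(trace.gyro, axis=1)
    above = gnorm >= cfg.swing_threshold
    if not above.any():
        raise InsufficientDataError(
            f"no gait detected: gyro norm never reaches "
            f"{cfg.swing_threshold} deg/s"
        )

    # raw alternating segments from threshold crossings
    change = np.nonzero(np.diff(above.astype(int)))[0] + 1  # first idx of new state
    idx_bounds = np.concatenate(([0], change, [len(gnorm)]))
    raw = []
    for k in range(len(idx_bounds) - 1):
        i0, i1 = idx_bounds[k], idx_bounds[k + 1]
        phase = SWING if above[i0] else FOOT_FLAT
        t0 = trace.t[i0] if k > 0 else trace.t[0]
        t1 = trace.t[i1] if i1 < len(gnorm) else trace.t[-1]
        raw.append([phase, float(t0), float(t1)])

    merged = _merge_short(raw, cfg.min_phase_duration)
    if all(p != SWING for p, _, _ in merged):
        raise InsufficientDataError(
            "no gait detected: all swing candidates shorter than the debounce"
        )
    return PhaseSegmentation([tuple(s) for s in merged])


def estimate_stride_duration(seg: PhaseSegmentation) -> float:
    """Mean interval between consecutive swing onsets (one foot's stride)."""
    onsets = [t0 for p, t0, _ in seg.segments if p == SWING]
    if len(onsets) < 2:
        raise InsufficientDataError(
            f"need >= 2 swing phases to estimate stride duration, got {len(onsets)}"
        )
    return float(np.mean(np.diff(onsets)))


def sagittal_axis(
    trace: IMUTrace, seg: PhaseSegmentation, mode: str = "auto"
) -> tuple[int | None, float]:
    """Pick the sagittal gyro axis and its sign.

    Returns (axis index or None for norm mode, sign).  In auto mode the axis
    is the one with the largest variance over swing samples, and the sign
    makes the mean swing-phase rotation positive.
    """
    if mode == "norm":
        return None, 1.0
    swing_mask = np.zeros(len(trace.t), dtype=bool)
    for t0, t1 in seg.of_phase(SWING):
        swing_mask |= (trace.t >= t0) & (trace.t <= t1)
    if mode == "auto":
        variances = trace.gyro[swing_mask].var(axis=0)
        axis = int(np.argmax(variances))
    else:
        axis = {"x": 0, "y": 1, "z": 2}[mode]
    # sign: make the sustained mid-swing rotation positive.  The median over
    # swing samples is dominated by the wide dorsiflexion lobe and is immune
    # to the narrow (but large) heel-strike spike, unlike the mean.
    med = float(np.median(trace.gyro[swing_mask, axis]))
    sign = 1.0 if med >= 0 else -1.0
    return axis, sign


def detect_heel_strikes(
    trace: IMUTrace,
    seg: PhaseSegmentation,
    stride: float,
    cfg: EventConfig = EventConfig(),
    raw_trace: IMUTrace | None = None,
) -> GaitEvents:
    """Heel strike per swing: minimum of the signed sagittal gyro component
    within ``(onset, onset + stride_window_factor * stride]``.

    Equal minima break to the earliest sample.  A final swing whose search
    window extends past the trace end is dropped with a logged warning.

    Timing is coarse-to-fine: the low-pass-filtered signal localises the
    strike robustly, and, when ``raw_trace`` (the unfiltered, bias-corrected
    trace) is supplied, the minimum is re-located on the raw signal within
    +/-60 ms of the coarse estimate — the raw impact signature is sharp and
    symmetric, so its minimum is not skewed by filter smearing of the
    surrounding swing rotation.  Sub-sample timing comes from a parabola
    through the minimum and its neighbours.
    """
    if stride <= 0:
        raise ParameterError("stride duration must be positive")
    axis, sign = sagittal_axis(trace, seg, cfg.axis_mode)
    if axis is None:
        sig = np.linalg.norm(trace.gyro, axis=1)
        raw_sig = None if raw_trace is None else np.linalg.norm(raw_trace.gyro, axis=1)
    else:
        sig = sign * trace.gyro[:, axis]
        raw_sig = None if raw_trace is None else sign * raw_trace.gyro[:, axis]

    window = cfg.stride_window_factor * stride
    onsets, strikes = [], []
    swing_bounds = seg.of_phase(SWING)
    swing_starts = [t0 for t0, _ in swing_bounds]
    for k, (t0, _t1) in enumerate(swing_bounds):
        end = t0 + window
        # the strike ending this swing must precede the foot's next swing
        if k + 1 < len(swing_starts):
            end = min(end, swing_starts[k + 1])
        if t0 + window > trace.t[-1] + 1e-12 and k + 1 >= len(swing_starts):
            logger.warning(
                "dropping swing at t=%.3f s: heel-strike window (%.3f s) "
                "extends past trace end", t0, window,
            )
            continue
        sel = np.nonzero((trace.t > t0) & (trace.t <= end))[0]
        if sel.size == 0:
            continue
        k = sel[int(np.argmin(sig[sel]))]  # argmin returns first of ties
        ref = sig
        if raw_sig is not None:
            near = np.nonzero(np.abs(trace.t - trace.t[k]) <= 0.06)[0]
            k = near[int(np.argmin(raw_sig[near]))]
            ref = raw_sig
        t_hs = float(trace.t[k])
        # sub-sample refinement: parabola through the minimum and neighbours
        if 0 < k < len(ref) - 1:
            y0, y1, y2 = ref[k - 1], ref[k], ref[k + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom > 0:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) < 1.0:
                    t_hs += delta * (trace.t[k + 1] - trace.t[k])
        if strikes and t_hs <= strikes[-1]:
            logger.warning(
                "dropping swing at t=%.3f s: heel strike %.3f s not after "
                "previous %.3f s", t0, t_hs, strikes[-1],
            )
            continue
        onsets.append(float(t0))
        strikes.append(t_hs)
    if not strikes:
        raise InsufficientDataError("no heel strikes detected")
    return GaitEvents(
        side=trace.side,
        swing_onsets=np.array(onsets),
        heel_strikes=np.array(strikes),
    )
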