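"""End-to-end orchestration: two raw foot traces in, a step series out.

The stages, in order, per foot: quiet-standing calibration, gyro-bias
subtraction, low-pass filtering, phase segmentation, stride-duration
estimation, heel-strike detection, complementary-filter orientation,
gravity removal, velocity integration, zero-velocity-update drift
correction, position integration.  The two feet are then merged into
per-step records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import yaml

from .core import IMUTrace, KinematicTrace, StepSeries
from .events import (
    EventConfig,
    detect_heel_strikes,
    estimate_stride_duration,
    segment_phases,
)
from .io import calibrate_standing, synchronize_pair
from .kinematics import (
    FootTrack,
    compute_step_series,
    integrate_position,
    integrate_velocity,
    stance_anchors,
    zupt_drift_correct,
)
from .orientation import complementary_orientation, to_global_linear_accel
from .preprocessing import FilterSpec, lowpass_filter


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the step-estimation pipeline."""

    filter: FilterSpec = FilterSpec()
    events: EventConfig = EventConfig()
    alpha: float = 0.98
    trim_steps: int = 0  # steps trimmed from each end of the series

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        f = d.get("filter", {})
        e = d.get("events", {})
        o = d.get("orientation", {})
        return cls(
            filter=FilterSpec(
                cutoff_hz=f.get("cutoff_hz", 4.0),
                order=f.get("order", 4),
                mode=f.get("mode", "zero_phase"),
            ),
            events=EventConfig(
                swing_threshold=e.get("swing_threshold_dps", 20.0),
                min_phase_duration=e.get("min_phase_s", 0.1),
                stride_window_factor=e.get("stride_window_factor", 1.0),
                axis_mode=e.get("axis_mode", "auto"),
            ),
            alpha=o.get("alpha", 0.98),
            trim_steps=d.get("trim_steps", 0),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class FootResult:
    """Per-foot intermediates, kept for debugging and validation."""

    trace_filtered: IMUTrace
    calibration: Any
    segmentation: Any
    events: Any
    orientation: Any
    a_global: Any
    kinematics: KinematicTrace

    @property
    def track(self) -> FootTrack:
        return FootTrack(
            events=self.events,
            kin=self.kinematics,
            anchors=stance_anchors(self.kinematics.t, self.segmentation),
        )


def process_foot(trace: IMUTrace, cfg: PipelineConfig = PipelineConfig()) -> FootResult:
    """Run all single-foot stages on one raw trace."""
    calib = calibrate_standing(
        trace, swing_threshold=cfg.events.swing_threshold
    )
    debiased = replace(trace, gyro=trace.gyro - calib.gyro_bias)
    filtered = lowpass_filter(debiased, cfg.filter)

    # the low-pass is for robust event detection; orientation and the
    # double integration consume the bias-corrected raw signals, since
    # aggressive pre-filtering distorts the impulsive heel-strike content
    # and biases integrated displacement
    seg = segment_phases(filtered, cfg.events)
    stride = estimate_stride_duration(seg)
    events = detect_heel_strikes(filtered, seg, stride, cfg.events, raw_trace=debiased)

    orient = complementary_orientation(debiased, calib, alpha=cfg.alpha)
    a_glob = to_global_linear_accel(debiased, orient)

    v_raw = integrate_velocity(a_glob, events)
    v = zupt_drift_correct(v_raw, a_glob.t, seg)
    kin = integrate_position(v, a_glob.t, events)
    return FootResult(
        trace_filtered=filtered,
        calibration=calib,
        segmentation=seg,
        events=events,
        orientation=orient,
        a_global=a_glob,
        kinematics=kin,
    )


def run_pipeline(
    left: IMUTrace,
    right: IMUTrace,
    cfg: PipelineConfig = PipelineConfig(),
) -> StepSeries:
    """Synchronise a bilateral pair, process both feet, merge into steps."""
    left_s, right_s = synchronize_pair(left, right)
    lres = process_foot(left_s, cfg)
    rres = process_foot(right_s, cfg)
    series = compute_step_series(lres.track, rres.track)
    if cfg.trim_steps > 0 and len(series) > 2 * cfg.trim_steps:
        df = series.steps.iloc[cfg.trim_steps : len(series) - cfg.trim_steps]
        series = StepSeries(df.reset_index(drop=True), series.walking_axis)
    return series


def run_pipeline_debug(
    left: IMUTrace,
    right: IMUTrace,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[StepSeries, FootResult, FootResult]:
    """As :func:`run_pipeline` but returning the per-foot intermediates."""
    left_s, right_s = synchronize_pair(left, right)
    lres = process_foot(left_s, cfg)
    rres = process_foot(right_s, cfg)
    return compute_step_series(lres.track, rres.track), lres, rres
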