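"""Simulated validation experiments: pooled straight-line walkway passes.

Laboratory validation of wearable gait systems is done in short
straight-line passes over an instrumented walkway, repeated several times,
with the per-step values pooled across passes for the agreement analysis.
This module reproduces that protocol in simulation: each pass is an
independent trial from the synthetic gait generator, processed end-to-end
by the estimation pipeline and paired step-by-step against the generator's
exact reference table; the paired steps of all passes are pooled.

Pooling short passes is not merely cosmetic: step length compares the two
feet's integrated tracks, and with independent sensors the inter-foot
registration slowly drifts (each foot's heading is unobservable), so
per-step accuracy over a walkway-length pass — not over an arbitrarily
long continuous walk — is the quantity such systems are validated on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StepSeries
from .kinematics import pair_steps
from .pipeline import PipelineConfig, run_pipeline
from .simulate import GaitSimConfig, pd_preset, simulate_gait, ya_preset

_PRESETS = {"pd": pd_preset, "ya": ya_preset}


@dataclass
class ExperimentResult:
    """Pooled paired steps from repeated simulated walkway passes."""

    measured: StepSeries
    reference: StepSeries
    pairs: pd.DataFrame
    n_passes: int
    n_unpaired: int


def run_validation_experiment(
    preset: str = "pd",
    n_passes: int = 10,
    steps_per_pass: int = 20,
    seed: int = 0,
    accel_noise_sigma: float = 0.0,
    gyro_noise_sigma: float = 0.0,
    gyro_bias_dps: float = 0.0,
    asymmetry_pct: float = 0.0,
    pipeline: PipelineConfig | None = None,
    pairing_tol: float = 0.25,
) -> ExperimentResult:
    """Simulate, process and pair ``n_passes`` walkway passes.

    Each pass uses an independent sub-seed derived from ``seed``.  Paired
    steps are pooled with a large per-pass time offset so the pooled series
    remain valid (strictly increasing strike times) and re-pairable.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    make = _PRESETS[preset]
    cfg_pipe = pipeline or PipelineConfig()

    frames = []
    n_unpaired = 0
    offset = 0.0
    for p in range(n_passes):
        cfg = make(
            n_steps=steps_per_pass,
            seed=(seed * 1009 + p) % (2**31 - 1),
            accel_noise_sigma=accel_noise_sigma,
            gyro_noise_sigma=gyro_noise_sigma,
            gyro_bias_dps=(gyro_bias_dps,) * 3,
            asymmetry_pct=asymmetry_pct,
        )
        left, right, truth = simulate_gait(cfg)
        series = run_pipeline(left, right, cfg_pipe)
        pairs = pair_steps(series, truth.steps, tol=pairing_tol)
        n_unpaired += (len(truth.steps) - len(pairs))
        pairs = pairs.copy()
        pairs["pass"] = p
        pairs["t_measured"] += offset
        pairs["t_reference"] += offset
        frames.append(pairs)
        offset += 10_000.0

    pooled = pd.concat(frames, ignore_index=True)

    def _series(which: str) -> StepSeries:
        return StepSeries.from_records(
            [
                (row["side"], row[f"t_{which}"], row[f"step_time_{which}"],
                 row[f"step_length_{which}"])
                for _, row in pooled.iterrows()
            ]
        )

    return ExperimentResult(
        measured=_series("measured"),
        reference=_series("reference"),
        pairs=pooled,
        n_passes=n_passes,
        n_unpaired=n_unpaired,
    )
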