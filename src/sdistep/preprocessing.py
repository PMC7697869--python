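"""High-frequency noise removal.

All six IMU channels are filtered independently with one set of Butterworth
low-pass coefficients (default: order 4, 4 Hz cut-off).  Offline analysis
uses zero-phase forward-backward filtering; a causal mode exists for
real-time style processing.  Edge handling for the zero-phase mode is
reflect padding ("even" extension) of one settling length so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import IMUTrace, ParameterError

ZERO_PHASE = "zero_phase"
CAUSAL = "causal"


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter settings.

    cutoff_hz : corner frequency (must lie below Nyquist), default 4 Hz —
        low enough to suppress sensor noise and impact ringing while keeping
        the gait band (< ~3 Hz fundamentals) intact.
    order : Butterworth order, default 4.
    mode : "zero_phase" (filtfilt, offline default) or "causal" (lfilter).
    """

    cutoff_hz: float = 4.0
    order: int = 4
    mode: str = ZERO_PHASE

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff_hz must be positive")
        if self.order < 1:
            raise ParameterError("order must be >= 1")
        if self.mode not in (ZERO_PHASE, CAUSAL):
            raise ParameterError(f"unknown filter mode {self.mode!r}")


def butter_coefficients(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    if spec.cutoff_hz >= fs / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz is not below Nyquist {fs / 2} Hz"
        )
    return signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs)


def lowpass_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Filter an (n,) or (n, k) array column-wise."""
    b, a = butter_coefficients(spec, fs)
    if spec.mode == ZERO_PHASE:
        padlen = 3 * (max(len(a), len(b)) - 1)
        return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)
    zi = signal.lfilter_zi(b, a)
    if x.ndim == 1:
        y, _ = signal.lfilter(b, a, x, zi=zi * x[0])
        return y
    cols = []
    for j in range(x.shape[1]):
        y, _ = signal.lfilter(b, a, x[:, j], zi=zi * x[0, j])
        cols.append(y)
    return np.column_stack(cols)


def lowpass_filter(trace: IMUTrace, spec: FilterSpec = FilterSpec()) -> IMUTrace:
    """Return a copy of ``trace`` with all six channels low-pass filtered.

    Timestamps are unchanged and the output has the input's length.  The
    trace must be uniform-rate (run :func:`sdistep.io.synchronize_pair`
    first if in doubt).
    """
    return replace(
        trace,
        t=trace.t.copy(),
        accel=lowpass_array(trace.accel, spec, trace.fs),
        gyro=lowpass_array(trace.gyro, spec, trace.fs),
    )
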