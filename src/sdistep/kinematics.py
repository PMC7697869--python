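"""Segmented double integration with per-step drift correction, and the
bilateral step-metric computation.

Velocity is the trapezoidal integral of the gravity-free global
acceleration.  Zero-velocity updates then exploit the foot-flat phases:
within each foot-flat the velocity is pinned to zero (the foot is known
stationary), and across each swing the accumulated foot-flat residual is
removed by a linear ramp, so the corrected velocity is continuous and
returns to zero at every stance.  Position is the trapezoidal integral of
the corrected velocity, with the shared quiet-standing origin as zero for
both feet.  Heel-strike positions are read at the following mid-stance
anchor — the heel is planted from strike through stance, so the two
coincide physically, and by mid-stance the track has settled through the
strike transient.

Step metrics merge the two feet's heel strikes in time order: the step
ending at strike k has duration t_k - t_(k-1) (opposite feet) and length
equal to the anterior-posterior progression between the two strike
positions.  Heading is unobservable without a magnetometer and each foot's
sensor drifts in yaw independently, so a fixed projection axis is fragile
on long trials; instead each foot's AP coordinate is its cumulative
along-track (arc-length) distance from the shared quiet-standing origin.
Stride displacement norms are invariant to slow per-foot heading drift and
to any common rotation of the traces, and for the straight-line walking
this tool targets, arc length equals the AP projection.  The merged
principal horizontal direction is still estimated and reported as the
walking axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FOOT_FLAT,
    SWING,
    DataError,
    GaitEvents,
    GlobalAccelTrace,
    InsufficientDataError,
    KinematicTrace,
    PairingError,
    PhaseSegmentation,
    StepSeries,
)

logger = logging.getLogger(__name__)


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    dt = np.diff(t)[:, None]
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * dt, axis=0)
    return out


def integrate_velocity(a: GlobalAccelTrace, events: GaitEvents) -> np.ndarray:
    """Raw (drift-contaminated) velocity by trapezoidal integration.

    Integration starts from rest at the trace start (the quiet-standing
    prelude), which is the foot-flat baseline preceding the first stride;
    drift accumulated between stances is removed afterwards by
    :func:`zupt_drift_correct`.
    """
    if events.heel_strikes.size < 2:
        raise InsufficientDataError(
            f"need >= 2 heel strikes to integrate, got {events.heel_strikes.size}"
        )
    return _cumtrapz(a.a_global, a.t)


def stance_anchors(t: np.ndarray, seg: PhaseSegmentation) -> np.ndarray:
    """Mid-stance anchor time of every foot-flat phase."""
    flats = seg.of_phase(FOOT_FLAT)
    return np.array([0.5 * (t0 + t1) for t0, t1 in flats])


def zupt_drift_correct(
    v_raw: np.ndarray, t: np.ndarray, seg: PhaseSegmentation
) -> np.ndarray:
    """Zero-velocity update.

    For each foot-flat phase the residual velocity is the mean of ``v_raw``
    over that phase.  Foot-flat samples are pinned to zero (the foot is
    known stationary there); over each inter-flat stretch the correction
    ramps linearly from the preceding flat's residual to the following
    flat's residual, so the corrected velocity is continuous and each step
    sheds exactly the drift it accrued.  Identity on input that is already
    zero at every foot-flat.
    """
    v = v_raw.copy()
    flats = seg.of_phase(FOOT_FLAT)
    if not flats:
        return v
    residuals = []
    for t0, t1 in flats:
        sel = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        if not sel.any():
            sel = np.zeros(len(t), bool)
            sel[np.argmin(np.abs(t - 0.5 * (t0 + t1)))] = True
        residuals.append(v_raw[sel].mean(axis=0))
        v[sel] = 0.0

    for k in range(len(flats)):
        t_start = flats[k][1]
        r0 = residuals[k]
        if k + 1 < len(flats):
            t_end = flats[k + 1][0]
            r1 = residuals[k + 1]
        else:
            t_end = t[-1]
            r1 = r0
        sel = (t > t_start + 1e-12) & (t < t_end - 1e-12)
        if not sel.any():
            continue
        frac = (t[sel] - t_start) / max(t_end - t_start, 1e-12)
        v[sel] = v_raw[sel] - (r0 + frac[:, None] * (r1 - r0))
    sel = t < flats[0][0] - 1e-12
    if sel.any():
        v[sel] = v_raw[sel] - residuals[0]
    return v


def integrate_position(
    v: np.ndarray, t: np.ndarray, events: GaitEvents
) -> KinematicTrace:
    """Trapezoidal integration of the corrected velocity.

    The origin is the start of the trace (the shared quiet-standing
    position, where velocity is identically zero), so both feet's tracks
    live in one coordinate system.
    """
    p = _cumtrapz(v, t)
    return KinematicTrace(t=t.copy(), v=v.copy(), p=p)


def strike_positions(
    kin: KinematicTrace,
    events: GaitEvents,
    anchors: np.ndarray | None = None,
) -> np.ndarray:
    """3-D heel position for each heel strike.

    With ``anchors`` given (mid-stance times), each strike's position is
    read at the first anchor after the strike — the heel is planted there
    and the integrated track has settled past the filter's transition
    transients.  Without anchors the position is interpolated at the strike
    instant itself.
    """
    read_at = np.asarray(events.heel_strikes, float).copy()
    if anchors is not None and len(anchors):
        anchors = np.sort(np.asarray(anchors, float))
        for i, ts in enumerate(read_at):
            later = anchors[anchors > ts]
            if later.size:
                read_at[i] = later[0]
    read_at = np.minimum(read_at, kin.t[-1])
    return np.column_stack(
        [np.interp(read_at, kin.t, kin.p[:, j]) for j in range(3)]
    )


@dataclass
class FootTrack:
    """One foot's events plus its drift-corrected kinematic track."""

    events: GaitEvents
    kin: KinematicTrace
    anchors: np.ndarray | None = None

    @property
    def side(self) -> str:
        return self.events.side


def _walking_axis(disp_xy: np.ndarray) -> np.ndarray:
    """Principal horizontal direction of the strike-to-strike displacements,
    oriented along the net progression."""
    if len(disp_xy) == 0:
        raise InsufficientDataError("no displacements to derive a walking axis")
    _, _, vt = np.linalg.svd(disp_xy - 0.0, full_matrices=False)
    axis = vt[0]
    if disp_xy.sum(axis=0) @ axis < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def compute_step_series(left: FootTrack, right: FootTrack) -> StepSeries:
    """Merge bilateral heel strikes into per-step records.

    Strikes are merged in time order and must alternate between feet;
    strikes violating alternation are dropped with a warning, and the steps
    bridging them are discarded.  Each foot's AP coordinate is its
    cumulative along-track distance from the shared quiet-standing origin
    (see module docstring); a step's length is the AP progression between
    the two strikes that bound it.
    """
    rows = []
    disp_all = []
    for track in (left, right):
        pos = strike_positions(track.kin, track.events, track.anchors)
        xy = pos[:, :2]
        # arc length from the standing origin along this foot's own track
        seg_len = np.linalg.norm(np.diff(xy, axis=0, prepend=[[0.0, 0.0]]), axis=1)
        ap = np.cumsum(seg_len)
        disp_all.append(np.diff(xy, axis=0, prepend=[[0.0, 0.0]]))
        for t_hs, s in zip(track.events.heel_strikes, ap):
            rows.append((float(t_hs), track.side, float(s)))
    if len(rows) < 2:
        raise InsufficientDataError(
            f"need >= 2 merged heel strikes, got {len(rows)}"
        )
    rows.sort(key=lambda r: r[0])

    kept = [rows[0]]
    dropped = 0
    broken = {0}
    for r in rows[1:]:
        if r[1] == kept[-1][1]:
            dropped += 1
            broken.add(len(kept))  # the next kept strike must not form a step
            continue
        kept.append(r)
    if dropped:
        logger.warning(
            "dropped %d heel strike(s) violating left/right alternation; "
            "bridging steps discarded", dropped,
        )
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 alternating heel strikes")

    axis = _walking_axis(np.vstack(disp_all))

    records = []
    for k in range(1, len(kept)):
        if k in broken:
            continue
        t_prev, _, ap_prev = kept[k - 1]
        t_k, side_k, ap_k = kept[k]
        records.append((side_k, t_k, t_k - t_prev, ap_k - ap_prev))
    if not records:
        raise InsufficientDataError("no valid steps after alternation filtering")
    series = StepSeries.from_records(records, walking_axis=axis)
    return series


def pair_steps(
    measured: StepSeries, reference: StepSeries, tol: float = 0.25
) -> pd.DataFrame:
    """Pair measured and reference steps one-to-one by strike order.

    Unmatched leading/trailing steps are dropped; a strike-time tolerance of
    ``tol`` seconds applies after aligning the two series by their best
    common offset (the median strike-time difference of order-paired steps,
    which absorbs any clock offset between the systems).  Raises
    PairingError if more than 20% of the overlapping steps fail to pair.
    """
    tm = measured.strike_times
    tr = reference.strike_times
    if tm.size == 0 or tr.size == 0:
        raise PairingError("cannot pair empty step series")

    # candidate clock offset from order-pairing the overlap at every lag
    best = None
    for lag in range(-(len(tr) - 1), len(tm)):
        i0, j0 = max(lag, 0), max(-lag, 0)
        n = min(len(tm) - i0, len(tr) - j0)
        if n < 1:
            continue
        d = tm[i0 : i0 + n] - tr[j0 : j0 + n]
        offset = np.median(d)
        ok = np.abs(d - offset) <= tol
        # prefer more pairs, then longer overlap, then smaller lag
        key = (int(ok.sum()), n, -abs(lag))
        if best is None or key > best[0]:
            best = (key, lag, offset)
    (_, _, _), lag, offset = best
    i0, j0 = max(lag, 0), max(-lag, 0)
    n = min(len(tm) - i0, len(tr) - j0)
    d = tm[i0 : i0 + n] - tr[j0 : j0 + n]
    ok = np.abs(d - offset) <= tol
    n_overlap = n
    if n_overlap and (ok.sum() / n_overlap) < 0.8:
        table = pd.DataFrame(
            {
                "measured_t": tm[i0 : i0 + n],
                "reference_t": tr[j0 : j0 + n],
                "dt_after_offset": d - offset,
                "paired": ok,
            }
        )
        raise PairingError(
            f"only {int(ok.sum())}/{n_overlap} steps paired within {tol} s:\n"
            f"{table.to_string(index=False)}"
        )
    mi = np.arange(i0, i0 + n)[ok]
    ri = np.arange(j0, j0 + n)[ok]
    return pd.DataFrame(
        {
            "side": measured.sides[mi],
            "t_measured": tm[mi],
            "t_reference": tr[ri],
            "step_time_measured": measured.step_times[mi],
            "step_time_reference": reference.step_times[ri],
            "step_length_measured": measured.step_lengths[mi],
            "step_length_reference": reference.step_lengths[ri],
        }
    )


def error_percent(
    measured: StepSeries, reference: StepSeries, tol: float = 0.25
) -> dict[str, tuple[float, float]]:
    """Per-parameter mean +/- SD of the absolute per-step percent error.

    Returns ``{"step_length": (mean, sd), "step_time": (mean, sd)}`` with
    percent error defined as 100*|measured - reference| / reference.
    """
    pairs = pair_steps(measured, reference, tol)
    out = {}
    for name in ("step_length", "step_time"):
        ref = pairs[f"{name}_reference"].to_numpy(float)
        mes = pairs[f"{name}_measured"].to_numpy(float)
        if np.any(ref == 0):
            raise DataError(f"zero reference {name}; percent error undefined")
        err = 100.0 * np.abs(mes - ref) / np.abs(ref)
        out[name] = (float(err.mean()), float(err.std(ddof=1)) if err.size > 1 else 0.0)
    return out
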