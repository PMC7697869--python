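import numpy as np
import pytest

from sdistep import (
    GaitEvents,
    GlobalAccelTrace,
    InsufficientDataError,
    KinematicTrace,
    PairingError,
    StepSeries,
    compute_step_series,
    error_percent,
    integrate_position,
    integrate_velocity,
    pair_steps,
    zupt_drift_correct,
)
from sdistep.core import FOOT_FLAT, SWING, PhaseSegmentation
from sdistep.kinematics import FootTrack, stance_anchors


def _events(side="left", strikes=(1.0, 2.0)):
    strikes = np.asarray(strikes, float)
    return GaitEvents(side=side, swing_onsets=strikes - 0.4, heel_strikes=strikes)


class TestIntegrateVelocity:
    def test_zero_accel_gives_zero_velocity(self):
        t = np.arange(512) / 128.0
        a = GlobalAccelTrace(t=t, a_global=np.zeros((512, 3)))
        v = integrate_velocity(a, _events())
        np.testing.assert_allclose(v, 0.0)

    def test_constant_accel_analytic(self):
        fs = 128.0
        t = np.arange(int(fs) + 1) / fs
        acc = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        v = integrate_velocity(GlobalAccelTrace(t=t, a_global=acc), _events())
        np.testing.assert_allclose(v[-1], [1.0, 0, 0], atol=1.0 / (2 * fs))

    def test_too_few_strikes_rejected(self):
        t = np.arange(512) / 128.0
        a = GlobalAccelTrace(t=t, a_global=np.zeros((512, 3)))
        with pytest.raises(InsufficientDataError):
            integrate_velocity(a, _events(strikes=(1.0,)))


class TestZuptDriftCorrect:
    def _seg(self):
        return PhaseSegmentation([
            (FOOT_FLAT, 0.0, 1.0),
            (SWING, 1.0, 1.5),
            (FOOT_FLAT, 1.5, 2.5),
            (SWING, 2.5, 3.0),
            (FOOT_FLAT, 3.0, 4.0),
        ])

    def test_identity_on_clean_input(self):
        t = np.arange(512) / 128.0
        v = np.zeros((512, 3))
        swing = (t > 1.0) & (t < 1.5)
        v[swing, 0] = np.sin(np.pi * (t[swing] - 1.0) / 0.5)
        out = zupt_drift_correct(v, t, self._seg())
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_flat_residual_removed_at_swing_end(self):
        """A 0.2 m/s residual at the next stance is fully shed by swing end."""
        t = np.arange(512) / 128.0
        v = np.zeros((512, 3))
        v[t >= 1.0, 0] = 0.2  # drift appears during the swing and persists
        out = zupt_drift_correct(v, t, self._seg())
        # pinned to zero inside the following flat
        flat = (t > 1.5) & (t < 2.5)
        np.testing.assert_allclose(out[flat], 0.0, atol=1e-12)
        # at the swing end the full residual has been subtracted
        i_end = np.argmin(np.abs(t - 1.5)) - 1
        assert out[i_end, 0] == pytest.approx(v[i_end, 0] - 0.2, abs=0.01)

    def test_linear_drift_injection_recovered(self):
        """Known linear drift superposed on a clean profile is removed."""
        t = np.arange(512) / 128.0
        v_true = np.zeros((512, 3))
        swing1 = (t > 1.0) & (t < 1.5)
        v_true[swing1, 0] = np.sin(np.pi * (t[swing1] - 1.0) / 0.5)
        drift = np.outer(t, [0.05, -0.02, 0.01])
        out = zupt_drift_correct(v_true + drift, t, self._seg())
        core = t <= 3.0
        assert np.max(np.abs(out[core] - v_true[core])) < 0.06

    def test_footflat_velocity_bound_after_correction(self, noisy_pd_trial):
        from sdistep.pipeline import process_foot
        left, _, _ = noisy_pd_trial
        res = process_foot(left)
        t = res.kinematics.t
        for t0, t1 in res.segmentation.of_phase(FOOT_FLAT):
            mid = np.argmin(np.abs(t - 0.5 * (t0 + t1)))
            assert np.linalg.norm(res.kinematics.v[mid]) < 0.05


class TestIntegratePosition:
    def test_zero_velocity_stays_at_origin(self):
        t = np.arange(512) / 128.0
        kin = integrate_position(np.zeros((512, 3)), t, _events())
        np.testing.assert_allclose(kin.p, 0.0)

    def test_constant_velocity_displacement(self):
        fs = 128.0
        t = np.arange(int(fs) + 1) / fs
        v = np.tile([1.2, 0.0, 0.0], (len(t), 1))
        kin = integrate_position(v, t, _events())
        np.testing.assert_allclose(kin.p[-1], [1.2, 0, 0], atol=1e-9)

    def test_stride_displacement_on_simulator(self, pd_trial):
        from sdistep.pipeline import process_foot
        from sdistep.kinematics import strike_positions
        left, _, truth = pd_trial
        res = process_foot(left)
        pos = strike_positions(res.kinematics, res.events, res.track.anchors)
        est = np.linalg.norm(np.diff(pos[:, :2], axis=0), axis=1)
        tru = np.diff(truth.strike_ap["left"])
        np.testing.assert_allclose(est, tru, rtol=0.02)


def _track_from_positions(side, strikes, ap, fs=128.0, t_end=6.0):
    """Build a FootTrack whose position steps along x at the given strikes."""
    n = int(t_end * fs)
    t = np.arange(n) / fs
    px = np.zeros(n)
    for ts, a in zip(strikes, ap):
        px[t >= ts - 0.2] = a  # settles before the strike; flat afterwards
    p = np.column_stack([px, np.zeros(n), np.zeros(n)])
    v = np.zeros_like(p)
    kin = KinematicTrace(t=t, v=v, p=p)
    anchors = np.asarray(strikes, float) + 0.3
    return FootTrack(events=_events(side, strikes), kin=kin, anchors=anchors)


class TestComputeStepSeries:
    def test_two_strike_definition(self):
        left = _track_from_positions("left", [1.0], [0.6])
        right = _track_from_positions("right", [1.55], [1.25])
        series = compute_step_series(left, right)
        assert len(series) == 1
        row = series.steps.iloc[0]
        assert row.side == "right"
        assert row.step_time == pytest.approx(0.55)
        assert row.step_length == pytest.approx(0.65, abs=1e-9)

    def test_non_alternating_strike_dropped(self):
        left = _track_from_positions("left", [1.0, 2.0], [0.6, 1.8])
        right = _track_from_positions("right", [1.5, 1.7], [1.2, 1.3])
        series = compute_step_series(left, right)
        # the strike at 1.7 violates alternation and is dropped, and the
        # step that would bridge it (ending at the 2.0 strike) is discarded
        assert list(series.sides) == ["right"]

    def test_symmetric_gait_sides_balanced(self, pd_trial):
        from sdistep.pipeline import run_pipeline
        left, right, truth = pd_trial
        series = run_pipeline(left, right)
        m_left = series.for_side("left").step_length.mean()
        m_right = series.for_side("right").step_length.mean()
        t_left = truth.steps.for_side("left").step_length.mean()
        t_right = truth.steps.for_side("right").step_length.mean()
        # recovered side difference matches the truth's realised difference
        assert (m_left - m_right) == pytest.approx(t_left - t_right, abs=0.01)

    def test_step_times_sum_to_span(self, pd_trial):
        from sdistep.pipeline import run_pipeline
        left, right, _ = pd_trial
        series = run_pipeline(left, right)
        ts = series.strike_times
        assert series.step_times[1:].sum() == pytest.approx(
            ts[-1] - ts[0], abs=1e-6
        )

    def test_ap_increments_conserve_total_displacement(self, pd_trial):
        """Summed step increments equal the net AP progression between the
        first and last merged strike."""
        from sdistep.pipeline import run_pipeline_debug
        from sdistep.kinematics import strike_positions
        left, right, _ = pd_trial
        series, lres, rres = run_pipeline_debug(left, right)
        arcs = {}
        for res in (lres, rres):
            pos = strike_positions(res.kinematics, res.events, res.track.anchors)
            ap = np.cumsum(np.linalg.norm(
                np.diff(pos[:, :2], axis=0, prepend=[[0.0, 0.0]]), axis=1
            ))
            for ts, a in zip(res.events.heel_strikes, ap):
                arcs[round(float(ts), 6)] = a
        # net progression: AP at the last merged strike minus AP at the
        # first (no strikes are dropped on this clean trial)
        ts_all = sorted(arcs)
        last_ap = arcs[round(float(series.strike_times[-1]), 6)]
        assert series.step_lengths.sum() == pytest.approx(
            last_ap - arcs[ts_all[0]], abs=1e-6
        )


class TestPairingAndError:
    def _series(self, strikes, lengths, times=None, sides=None):
        n = len(strikes)
        times = times or [0.5] * n
        sides = sides or ["left" if i % 2 == 0 else "right" for i in range(n)]
        return StepSeries.from_records(
            list(zip(sides, strikes, times, lengths))
        )

    def test_identical_series_zero_error(self):
        s = self._series([1.0, 1.5, 2.0], [0.6, 0.62, 0.61])
        res = error_percent(s, s)
        assert res["step_length"] == (0.0, 0.0)
        assert res["step_time"] == (0.0, 0.0)

    def test_single_step_percent_arithmetic(self):
        m = self._series([1.0, 1.5], [0.63, 0.63])
        r = self._series([1.0, 1.5], [0.60, 0.60])
        res = error_percent(m, r)
        assert res["step_length"][0] == pytest.approx(5.0)

    def test_clock_offset_absorbed(self):
        m = self._series([11.0, 11.5, 12.0], [0.6, 0.62, 0.61])
        r = self._series([1.0, 1.5, 2.0], [0.6, 0.62, 0.61])
        pairs = pair_steps(m, r)
        assert len(pairs) == 3

    def test_unmatched_leading_steps_dropped(self):
        m = self._series([1.0, 1.5, 2.0, 2.5], [0.6, 0.62, 0.61, 0.6])
        r = self._series([1.52, 2.01, 2.49], [0.62, 0.61, 0.6])
        pairs = pair_steps(m, r)
        assert len(pairs) == 3

    def test_gross_mismatch_raises_with_table(self):
        m = self._series([1.0, 1.9, 3.1, 4.4], [0.6] * 4)
        r = self._series([1.0, 1.4, 2.2, 2.6], [0.6] * 4)
        with pytest.raises(PairingError, match="paired"):
            pair_steps(m, r)
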