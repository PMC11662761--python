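import numpy as np
import pytest

from eaequant import kinematics
from eaequant.kinematics import (
    JointAngleSeries,
    PhaseParams,
    PhaseSegmentation,
    RepresentativeCycle,
    average_angle,
    detect_phases,
    joint_angle_series,
    normalize_phase,
    representative_cycle,
    rms_difference,
)
from eaequant.pose_io import LANDMARKS, CalibratedTrack
from eaequant.synthetic import GaitSimParams, gen_gait_recording

from conftest import process_recording


def _track_from_points(**points):
    """CalibratedTrack with each landmark fixed at a given (x, y) cm point."""
    defaults = {
        "iliac_crest": (0.0, 3.0), "hip": (0.0, 2.0), "knee": (0.0, 1.0),
        "ankle": (0.0, 0.0), "mtp": (2.0, -0.5), "toe": (2.5, -0.5),
    }
    defaults.update(points)
    x = {m: np.array([defaults[m][0]]) for m in LANDMARKS}
    y = {m: np.array([defaults[m][1]]) for m in LANDMARKS}
    return CalibratedTrack(fps=250.0, x_cm=x, y_cm=y)


def _cycle(values, n_phase=100):
    v = np.asarray(values, dtype=float)
    return RepresentativeCycle(
        n_phase=n_phase, hip_deg=v.copy(), knee_deg=v.copy(),
        ankle_deg=v.copy(), n_cycles_averaged=1,
    )


class TestJointAngles:
    @pytest.mark.parametrize(
        "hip,knee,ankle,expected",
        [
            ((0, 2), (0, 1), (0, 0), 180.0),  # collinear leg
            ((0, 1), (0, 0), (1, 0), 90.0),
            ((0, 1), (0, 0), (1, 1), 45.0),
        ],
    )
    def test_knee_interior_angle(self, hip, knee, ankle, expected):
        track = _track_from_points(hip=hip, knee=knee, ankle=ankle)
        series = joint_angle_series(track)
        assert series.knee_deg[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_generator_waveforms(self, clean_recording):
        track, truth = clean_recording
        ctrack, angles, _, _ = process_recording(track, truth)
        np.testing.assert_allclose(angles.knee_deg, truth.knee_deg, atol=1e-9)
        np.testing.assert_allclose(angles.ankle_deg, truth.ankle_deg, atol=1e-9)
        np.testing.assert_allclose(angles.hip_deg, truth.hip_deg, atol=1e-9)


class TestDetectPhases:
    def test_recovers_cycles_and_boundaries(self, clean_recording):
        track, truth = clean_recording
        _, _, seg, _ = process_recording(track, truth)
        assert 4 <= seg.n_cycles <= 6
        for s, e, ws, we in seg.cycles:
            ref = min(truth.boundaries, key=lambda b: abs(b[0] - s))
            assert abs(s - ref[0]) <= 2
            assert abs(e - ref[1]) <= 2
            assert abs(we - ref[2]) <= 2

    def test_duty_factor_recovered(self, clean_recording):
        track, truth = clean_recording
        _, _, seg, _ = process_recording(track, truth)
        assert seg.duty_factor() == pytest.approx(truth.duty_factor, abs=0.02)

    def test_constant_forward_motion_yields_no_cycles(self):
        n = 500
        x = {m: 1.0 + np.arange(n) * 0.02 for m in LANDMARKS}
        y = {m: np.full(n, 1.0) for m in LANDMARKS}
        track = CalibratedTrack(fps=250.0, x_cm=x, y_cm=y)
        with pytest.warns(UserWarning):
            seg = detect_phases(track, auto_orient=False)
        assert seg.n_cycles == 0

    def test_short_track_is_fatal(self):
        x = {m: np.arange(15.0) for m in LANDMARKS}
        y = {m: np.zeros(15) for m in LANDMARKS}
        track = CalibratedTrack(fps=250.0, x_cm=x, y_cm=y)
        with pytest.raises(ValueError, match="too short"):
            detect_phases(track, PhaseParams(min_phase=10))

    def test_mirrored_animal_detected(self, clean_recording):
        track, truth = clean_recording
        ctrack, _, seg_fwd, _ = process_recording(track, truth)
        mirrored = CalibratedTrack(
            fps=ctrack.fps,
            x_cm={m: 8.0 - ctrack.x_cm[m] for m in LANDMARKS},
            y_cm={m: ctrack.y_cm[m].copy() for m in LANDMARKS},
        )
        seg = detect_phases(mirrored)
        assert seg.mirrored
        assert seg.n_cycles == seg_fwd.n_cycles


class TestNormalizePhase:
    def test_identity_when_length_matches(self):
        v = np.random.default_rng(0).normal(size=100)
        np.testing.assert_array_equal(normalize_phase(v, 100), v)

    def test_linear_ramp_stays_linear(self):
        ramp = np.linspace(0.0, 1.0, 50)
        out = normalize_phase(ramp, 100)
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.abs(out - np.linspace(0, 1, 100)).max() < 1e-12

    def test_sine_interpolation_error_bound(self):
        x = np.linspace(0.0, 2 * np.pi, 73)
        out = normalize_phase(np.sin(x), 100)
        analytic = np.sin(np.linspace(0.0, 2 * np.pi, 100))
        h = 2 * np.pi / 72  # sample spacing in radians
        assert np.abs(out - analytic).max() < h**2 / 8

    def test_too_short_input_is_fatal(self):
        with pytest.raises(ValueError):
            normalize_phase(np.array([1.0]), 100)


class TestRepresentativeCycle:
    def _series_from_cycles(self, cycles, duty=0.5):
        """Concatenate per-cycle waveforms into a JointAngleSeries + segmentation."""
        values = np.concatenate(cycles)
        n = values.size
        seg = []
        start = 0
        for c in cycles:
            L = c.size
            mid = start + int(duty * L)
            seg.append((start, mid, mid, start + L))
            start += L
        series = JointAngleSeries(
            fps=250.0, hip_deg=values.copy(), knee_deg=values.copy(),
            ankle_deg=values.copy(), toe_y_cm=np.zeros(n), ankle_y_cm=np.zeros(n),
        )
        return series, PhaseSegmentation(cycles=seg)

    def test_single_cycle_has_printed_length(self):
        rng = np.random.default_rng(1)
        series, seg = self._series_from_cycles([80 + 20 * rng.random(60)])
        out = representative_cycle(series, seg)
        assert out.knee_deg.size == 200
        assert out.n_cycles_averaged == 1

    def test_identical_cycles_average_to_single_cycle(self):
        rng = np.random.default_rng(2)
        wave = 90 + 30 * rng.random(60)
        series1, seg1 = self._series_from_cycles([wave])
        one = representative_cycle(series1, seg1)
        seriesk, segk = self._series_from_cycles([wave] * 5)
        many = representative_cycle(seriesk, segk)
        np.testing.assert_allclose(many.knee_deg, one.knee_deg, atol=1e-12)

    def test_zero_sum_offsets_cancel(self):
        rng = np.random.default_rng(3)
        wave = 100 + 20 * rng.random(60)
        cycles = [wave + d for d in (2.0, -2.0, 1.0, -1.0)]
        series, seg = self._series_from_cycles(cycles)
        base_series, base_seg = self._series_from_cycles([wave])
        out = representative_cycle(series, seg)
        base = representative_cycle(base_series, base_seg)
        np.testing.assert_allclose(out.knee_deg, base.knee_deg, atol=1e-9)

    def test_empty_segmentation_is_fatal(self):
        series, _ = self._series_from_cycles([np.full(60, 90.0)])
        with pytest.raises(ValueError, match="no complete step cycles"):
            representative_cycle(series, PhaseSegmentation(cycles=[]))

    @pytest.mark.parametrize("cadence,duty", [(1.0, 0.55), (2.0, 0.65)])
    def test_length_independent_of_cadence_and_duty(self, cadence, duty):
        track, truth = gen_gait_recording(
            GaitSimParams(seed=9, cadence_hz=cadence, duty_factor=duty)
        )
        _, _, seg, cycle = process_recording(track, truth)
        assert cycle.knee_deg.size == 200


class TestMetrics:
    def test_average_of_constant_cycle(self):
        assert average_angle(_cycle(np.full(200, 120.0)), "knee") == 120.0

    def test_average_of_two_level_cycle(self):
        v = np.concatenate([np.full(100, 100.0), np.full(100, 140.0)])
        assert average_angle(_cycle(v), "knee") == pytest.approx(120.0)

    def test_unknown_joint_is_fatal(self):
        with pytest.raises(ValueError, match="unknown joint"):
            average_angle(_cycle(np.full(200, 1.0)), "elbow")

    def test_rms_identity_and_offset(self):
        rng = np.random.default_rng(4)
        c = _cycle(90 + 30 * rng.random(200))
        assert rms_difference(c, c, "knee") == 0.0
        shifted = _cycle(c.knee_deg + 5.0)
        assert rms_difference(shifted, c, "knee") == pytest.approx(5.0)

    def test_rms_toy_arithmetic(self):
        a = _cycle(np.array([10.0, 20.0, 30.0, 40.0]), n_phase=2)
        b = _cycle(np.array([12.0, 18.0, 33.0, 39.0]), n_phase=2)
        assert rms_difference(a, b, "knee") == pytest.approx(np.sqrt(4.5), abs=1e-9)

    def test_rms_is_a_metric(self):
        rng = np.random.default_rng(5)
        a, b, c = (_cycle(90 + 30 * rng.random(200)) for _ in range(3))
        dab = rms_difference(a, b, "knee")
        dba = rms_difference(b, a, "knee")
        assert dab == dba
        assert dab <= rms_difference(a, c, "knee") + rms_difference(c, b, "knee") + 1e-12

    def test_mismatched_lengths_fatal(self):
        with pytest.raises(ValueError):
            rms_difference(_cycle(np.zeros(200)), _cycle(np.zeros(100), n_phase=50), "knee")


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("delta", [-20.0, -10.0, -5.0])
    def test_knee_offset_recovered(self, delta):
        base_track, base_truth = gen_gait_recording(GaitSimParams(seed=7))
        off_track, off_truth = gen_gait_recording(
            GaitSimParams(seed=7, knee_offset_deg=delta)
        )
        _, _, _, base_cycle = process_recording(base_track, base_truth)
        _, _, _, off_cycle = process_recording(off_track, off_truth)
        measured = average_angle(base_cycle, "knee") - average_angle(off_cycle, "knee")
        assert measured == pytest.approx(-delta, abs=1.0)

    def test_noise_monotonically_increases_rms(self):
        """More cycle-to-cycle angle noise -> larger median knee RMS vs baseline."""
        base_track, base_truth = gen_gait_recording(GaitSimParams(seed=100))
        _, _, _, base_cycle = process_recording(base_track, base_truth)
        medians = []
        for sd in (0.5, 2.0):
            vals = []
            for seed in range(20):
                t, tr = gen_gait_recording(
                    GaitSimParams(seed=200 + seed, cycle_noise_sd_deg=sd)
                )
                _, _, _, cyc = process_recording(t, tr)
                vals.append(rms_difference(cyc, base_cycle, "knee"))
            medians.append(np.median(vals))
        assert medians[1] > medians[0]
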