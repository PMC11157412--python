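import numpy as np
import pytest
from scipy import stats

import locokinetics as lk
from locokinetics import (
    StimEpoch, angular_velocity, body_orientation_angle, compute_speed,
    head_rotation_angle, paired_comparison_gate, peristimulus_average,
    segment_locomotion, trajectory_vectors,
)
from locokinetics.synthetic import (
    BoutSpec, NoiseSpec, SimConfig, StimSpec, TurnSpec, simulate_openfield,
)

from conftest import make_track, calibrated


def openfield_track(cfg, arena_cal):
    track, truth = simulate_openfield(cfg)
    return calibrated(track, arena_cal), truth


class TestComputeSpeed:
    def test_stationary_point_zero_speed(self):
        track = make_track({"body_center": np.tile([5.0, 5.0], (60, 1))})
        sp = compute_speed(track)
        np.testing.assert_allclose(sp.speed[:-3], 0.0, atol=1e-12)

    def test_constant_velocity_line(self):
        n, fps, v = 90, 30.0, 10.0
        x = v * np.arange(n) / fps
        track = make_track({"body_center": np.stack([x, np.zeros(n)], axis=1)},
                           fps=fps)
        sp = compute_speed(track, smooth_frames=5)
        np.testing.assert_allclose(sp.speed[3:-4], v, atol=1e-6)

    def test_generator_bout_recovered_under_jitter(self, arena_cal):
        cfg = SimConfig(seed=11, fps=30, duration_s=20,
                        bouts=[BoutSpec(5, 10, 15.0)],
                        noise=NoiseSpec(jitter_px=1.0))
        track, truth = openfield_track(cfg, arena_cal)
        sp = compute_speed(track)
        sel = slice(int(5.5 * 30), int(14.5 * 30))
        mae = np.nanmean(np.abs(sp.speed[sel] - truth.speed_cm_s[sel]))
        assert mae < 0.5

    def test_too_few_frames_rejected(self):
        track = make_track({"body_center": np.zeros((1, 2))})
        with pytest.raises(ValueError, match="2 valid frames"):
            compute_speed(track)


class TestSegmentLocomotion:
    def _speed(self, values, fps=30.0):
        from locokinetics.openfield import SpeedTrace
        v = np.asarray(values, dtype=float)
        return SpeedTrace(speed=v, raw=v, fps=fps, smooth_frames=1,
                          times=np.arange(len(v)) / fps)

    def test_all_zero_is_immobile(self):
        b = segment_locomotion(self._speed(np.zeros(300)))
        assert b.n_initiations == 0
        assert b.time_immobile_s == pytest.approx(10.0)
        assert b.time_locomoting_s == 0.0

    def test_square_wave_three_plateaus(self):
        fps = 30
        v = np.zeros(30 * fps)
        for start in (5, 12, 19):  # three 2-s plateaus at 10 cm/s
            v[start * fps:(start + 2) * fps] = 10.0
        b = segment_locomotion(self._speed(v, fps))
        assert b.n_initiations == 3
        assert b.time_locomoting_s == pytest.approx(6.0, abs=2 / fps)
        assert b.time_locomoting_s + b.time_immobile_s == pytest.approx(30.0)

    def test_sub_minimum_plateau_ignored(self):
        fps = 30
        v = np.zeros(10 * fps)
        v[150:160] = 10.0  # 0.33 s < min_duration 0.5 s
        b = segment_locomotion(self._speed(v, fps))
        assert b.n_initiations == 0

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError, match="speed_off"):
            segment_locomotion(self._speed(np.zeros(100)), speed_on=1.0,
                               speed_off=3.0)

    def test_invariant_to_time_shift(self):
        fps = 30
        v = np.zeros(20 * fps)
        v[5 * fps:9 * fps] = 8.0
        b1 = segment_locomotion(self._speed(v, fps))
        b2 = segment_locomotion(self._speed(np.roll(v, 3 * fps), fps))
        assert b1.n_initiations == b2.n_initiations
        assert b1.time_locomoting_s == pytest.approx(b2.time_locomoting_s,
                                                     abs=1 / fps)


class TestAngularVelocity:
    def test_straight_line_zero(self):
        n = 60
        x = np.arange(n) * 0.5
        track = make_track({"body_center": np.stack([x, np.zeros(n)], axis=1),
                            "tail_base": np.stack([x - 3, np.zeros(n)], axis=1)})
        om = angular_velocity(track)
        np.testing.assert_allclose(om.omega[:-1], 0.0, atol=1e-9)

    def test_circular_path_matches_closed_form(self):
        # radius 10 cm at 10 cm/s: omega = v/R = 1 rad/s = 57.2958 deg/s
        fps, R, v = 30.0, 10.0, 10.0
        n = 120
        ang = (v / R) * np.arange(n) / fps  # rad, body center along circle
        center = np.stack([R * np.cos(ang), R * np.sin(ang)], axis=1)
        tail_ang = ang - 0.3                # tail trails on the circle
        tail = np.stack([R * np.cos(tail_ang), R * np.sin(tail_ang)], axis=1)
        track = make_track({"body_center": center, "tail_base": tail}, fps=fps)
        om = angular_velocity(track)
        np.testing.assert_allclose(np.abs(om.omega[:-1]), 57.29577951,
                                   atol=1e-6)

    def test_generator_clockwise_turn_sign_and_magnitude(self, arena_cal):
        cfg = SimConfig(seed=4, fps=30, duration_s=10,
                        turns=[TurnSpec(2, 4, 90.0)])
        track, _ = openfield_track(cfg, arena_cal)
        om = angular_velocity(track)
        sel = slice(int(2.2 * 30), int(5.8 * 30))
        assert np.nanmean(om.omega[sel]) == pytest.approx(90.0, abs=2.0)

    def test_reflection_flips_sign(self, arena_cal):
        cfg = SimConfig(seed=4, fps=30, duration_s=6,
                        turns=[TurnSpec(1, 4, 60.0)])
        track, _ = openfield_track(cfg, arena_cal)
        flipped = track.copy()
        flipped.xy[:, :, 1] *= -1.0  # mirror about the x axis
        om = angular_velocity(track)
        om_f = angular_velocity(flipped)
        sel = slice(int(1.5 * 30), int(4.5 * 30))
        assert np.nanmean(om_f.omega[sel]) == pytest.approx(
            -np.nanmean(om.omega[sel]), abs=1e-6)

    def test_zero_length_vector_flagged(self):
        n = 10
        p = np.tile([5.0, 5.0], (n, 1))
        track = make_track({"body_center": p, "tail_base": p})
        om = angular_velocity(track)
        assert np.isnan(om.omega[:5]).all()


class TestOrientationAngles:
    def test_motionless_alpha_zero(self, arena_cal):
        cfg = SimConfig(seed=0, fps=30, duration_s=10,
                        stims=[StimSpec(onset_s=3, duration_s=5)])
        track, truth = openfield_track(cfg, arena_cal)
        out = body_orientation_angle(track, truth.stim_epochs[0])
        np.testing.assert_allclose(np.nan_to_num(out.alpha), 0.0, atol=1e-9)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_full_rotation_accumulates_with_unwrap(self, sign, arena_cal):
        # 36 deg/s for 10 s from onset: alpha(10 s) = +/-360, beyond +/-180
        cfg = SimConfig(seed=0, fps=30, duration_s=12,
                        turns=[TurnSpec(1, 10, sign * 36.0)],
                        stims=[StimSpec(onset_s=1, duration_s=10)])
        track, truth = openfield_track(cfg, arena_cal)
        out = body_orientation_angle(track, truth.stim_epochs[0])
        i = int(11.0 * 30) - 1
        assert out.alpha[i] == pytest.approx(sign * 360.0, abs=2.0)

    def test_beta_zero_when_ears_symmetric(self):
        n, fps = 60, 30.0
        em = np.tile([10.0, 5.0], (n, 1))
        track = make_track({
            "tail_base": np.tile([0.0, 5.0], (n, 1)),
            "ear_left": em + [0.0, -1.0],
            "ear_right": em + [0.0, 1.0],
        }, fps=fps)
        out = head_rotation_angle(track, StimEpoch(1.0, 1.5))
        np.testing.assert_allclose(np.nan_to_num(out.beta), 0.0, atol=1e-9)

    def test_head_only_yaw_recovered(self):
        n, fps, yaw = 90, 30.0, 20.0
        t = np.arange(n) / fps
        gamma = np.where(t >= 1.0, np.deg2rad(yaw), 0.0)
        em = np.tile([10.0, 5.0], (n, 1))
        # image coords, head axis at +gamma (clockwise on screen)
        e = np.stack([-np.sin(gamma), np.cos(gamma)], axis=1)
        track = make_track({
            "tail_base": np.tile([0.0, 5.0], (n, 1)),
            "ear_left": em - e, "ear_right": em + e,
        }, fps=fps)
        out = head_rotation_angle(track, StimEpoch(1.0, 2.0))
        assert np.nanmean(out.beta[int(1.5 * fps):]) == pytest.approx(
            yaw, abs=0.5)

    def test_whole_body_rotation_leaves_beta_flat(self, arena_cal):
        cfg = SimConfig(seed=0, fps=30, duration_s=8,
                        turns=[TurnSpec(2, 4, 45.0)],
                        stims=[StimSpec(onset_s=2, duration_s=4)])
        track, truth = openfield_track(cfg, arena_cal)
        alpha = body_orientation_angle(track, truth.stim_epochs[0]).alpha
        beta = head_rotation_angle(track, truth.stim_epochs[0]).beta
        assert np.nanmax(np.abs(beta)) < 0.5
        assert alpha[int(6.5 * 30)] == pytest.approx(180.0, abs=2.0)

    def test_insufficient_baseline_rejected(self, arena_cal):
        cfg = SimConfig(seed=0, fps=30, duration_s=5,
                        stims=[StimSpec(onset_s=0.2, duration_s=2)])
        track, truth = openfield_track(cfg, arena_cal)
        with pytest.raises(ValueError, match="baseline"):
            body_orientation_angle(track, truth.stim_epochs[0])


class TestPeristimulusAverage:
    def test_single_trial_mean_is_the_trial(self):
        fps = 30.0
        v = np.arange(300, dtype=float)
        out = peristimulus_average(v, fps, [StimEpoch(4.0, 6.0)],
                                   pre_s=1.0, post_s=3.0)
        assert out.sem is None
        np.testing.assert_allclose(out.mean, v[90:210])

    def test_identical_trials_sem_zero(self):
        fps = 30.0
        v = np.tile(np.sin(np.arange(60) / 10.0), 10)
        eps = [StimEpoch(2.0 + 2 * k, 3.0 + 2 * k) for k in range(3)]
        out = peristimulus_average(v, fps, eps, pre_s=1.0, post_s=1.0)
        np.testing.assert_allclose(out.sem, 0.0, atol=1e-12)
        assert out.n_trials == 3

    def test_step_response_recovered_across_trials(self):
        fps, pre, dur = 30.0, 2.0, 10.0
        rng = np.random.default_rng(5)
        period = 80.0
        n = int(12 * period * fps)
        v = np.full(n, 2.0) + rng.normal(0, 0.3, n)
        eps = []
        for k in range(10):
            onset = 40.0 + k * period
            a, b = int(onset * fps), int((onset + dur) * fps)
            v[a:b] += 16.0
            eps.append(StimEpoch(onset, onset + dur))
        out = peristimulus_average(v, fps, eps, pre_s=pre, post_s=dur)
        grid = out.grid_s
        assert out.mean[(grid > 0.5) & (grid < 9.5)].mean() == pytest.approx(
            18.0, abs=0.5)
        assert out.mean[grid < -0.1].mean() == pytest.approx(2.0, abs=0.5)

    def test_no_epochs_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            peristimulus_average(np.zeros(100), 30.0, [], 1.0, 1.0)


class TestTrajectoryVectors:
    def test_stationary_all_zero(self):
        track = make_track({"body_center": np.tile([3.0, 3.0], (20, 1))})
        np.testing.assert_allclose(trajectory_vectors(track), 0.0)

    def test_constant_step_along_motion(self):
        n, fps, v = 40, 30.0, 10.0
        x = v * np.arange(n) / fps
        track = make_track({"body_center": np.stack([x, np.zeros(n)], axis=1)},
                           fps=fps)
        vecs = trajectory_vectors(track)
        np.testing.assert_allclose(vecs, np.tile([1 / 3, 0.0], (n - 1, 1)),
                                   atol=1e-9)

    def test_magnitudes_reproduce_raw_speed(self, arena_cal):
        cfg = SimConfig(seed=9, fps=30, duration_s=8,
                        bouts=[BoutSpec(1, 5, 12.0)],
                        noise=NoiseSpec(jitter_px=1.0))
        track, _ = openfield_track(cfg, arena_cal)
        vecs = trajectory_vectors(track)
        sp = compute_speed(track, smooth_frames=1)
        np.testing.assert_allclose(np.linalg.norm(vecs, axis=1) * 30.0,
                                   sp.raw[:-1], atol=1e-9)


class TestPairedComparisonGate:
    def test_identical_samples_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_comparison_gate(a, a.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_normal_shift_uses_paired_t(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 10)
        b = a + 5.0 + rng.normal(0, 1, 10)
        res = paired_comparison_gate(b, a)
        assert res.test == "paired t"
        assert res.p_value < 1e-3

    def test_heavy_tails_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        a = rng.standard_cauchy(30) * 100
        b = a + rng.standard_cauchy(30) * 100
        # verify the gate premise on this draw, then the choice
        assert stats.shapiro(a - b).pvalue < 0.05
        res = paired_comparison_gate(a, b)
        assert res.test == "wilcoxon"

    def test_unpaired_normal_uses_t(self):
        rng = np.random.default_rng(8)
        res = paired_comparison_gate(rng.normal(0, 1, 12),
                                     rng.normal(0.2, 1, 15), paired=False)
        assert res.test in ("t", "welch t")

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal n"):
            paired_comparison_gate([1, 2, 3], [1, 2, 3, 4])


class TestRigidInvariance:
    def test_speed_invariant_under_rotation_and_translation(self, arena_cal):
        # bout short enough that no wall reflection occurs (a reflection is
        # a 180-deg heading jump, where the signed angle is ill-defined)
        cfg = SimConfig(seed=13, fps=30, duration_s=6,
                        bouts=[BoutSpec(1, 1.5, 9.0)])
        track, _ = openfield_track(cfg, arena_cal)
        moved = track.copy()
        th = np.deg2rad(35.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved.xy = track.xy @ rot.T + np.array([7.0, -4.0])
        np.testing.assert_allclose(compute_speed(moved).speed,
                                   compute_speed(track).speed,
                                   atol=1e-9, equal_nan=True)
        np.testing.assert_allclose(angular_velocity(moved).omega,
                                   angular_velocity(track).omega,
                                   atol=1e-9, equal_nan=True)

    def test_omega_integral_matches_body_axis_change(self, arena_cal):
        cfg = SimConfig(seed=2, fps=30, duration_s=8,
                        turns=[TurnSpec(2, 3, 40.0)],
                        stims=[StimSpec(onset_s=2, duration_s=3)])
        track, truth = openfield_track(cfg, arena_cal)
        om = angular_velocity(track)
        a, b = int(2 * 30), int(5 * 30)
        integral = np.nansum(om.theta[a:b])
        alpha = body_orientation_angle(track, truth.stim_epochs[0]).alpha
        assert integral == pytest.approx(alpha[b] - alpha[a], abs=1.0)
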