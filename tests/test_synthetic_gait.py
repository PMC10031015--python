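import numpy as np
import pytest

from gaitgrf.body_model import GRAVITY
from gaitgrf.synthetic_gait import (
    GaitPatternParams,
    add_kinematic_noise,
    ankle_dorsiflexion,
    construct_ground_truth_grfm,
    generate_gait_pattern,
    knee_flexion,
)

from conftest import interior


def _phase_mask(traj, side, lo, hi):
    T = traj.metadata["stride_period"]
    offset = 0.0 if side == "left" else 0.5
    p = (traj.time / T - offset) % 1.0
    return (p >= lo) & (p < hi)


class TestGeneratorContracts:
    def test_unknown_pattern_lists_valid_names(self):
        with pytest.raises(ValueError, match="typical"):
            GaitPatternParams(pattern="waddle")

    def test_cadence_sets_stride_duration(self):
        # 120 steps/min = 2 steps/s -> one stride (2 steps) per second
        assert GaitPatternParams(cadence=120.0).stride_period == pytest.approx(1.0)

    def test_deterministic_bitwise(self, model):
        p = GaitPatternParams(pattern="type3_equinus_jumpknee", noise_sd=0.005,
                              seed=42, n_strides=1)
        a = generate_gait_pattern(p, model)
        b = generate_gait_pattern(p, model)
        assert np.array_equal(a.q, b.q)

    def test_periodic_across_strides(self, model, typical_trial):
        traj, _, _ = typical_trial
        per = int(round(traj.metadata["stride_period"] * traj.sample_rate))
        dq = traj.q[per, 3:] - traj.q[0, 3:]
        assert np.abs(dq).max() < 1e-6

    def test_base_advances_one_stride_per_stride(self, model, typical_trial):
        traj, _, _ = typical_trial
        per = int(round(traj.metadata["stride_period"] * traj.sample_rate))
        dx = traj.q[per, 0] - traj.q[0, 0]
        assert dx == pytest.approx(traj.metadata["stride_length"], abs=1e-9)

    def test_stance_foot_anchored_and_slow(self, model, typical_trial):
        # flat-foot phase (before the push-off heel rise, when the foot
        # rotates about its stationary distal edge)
        traj, kin, _ = typical_trial
        mask = _phase_mask(traj, "left", 0.1, 0.42)
        v = np.linalg.norm(kin.vel["foot_l"][mask], axis=1)
        z = kin.pos["foot_l"][mask, 2]
        assert v.max() < 0.12
        assert np.abs(z - model.ankle_height).max() < 5e-3

    @pytest.mark.parametrize("pattern", ["type2A_equinus",
                                         "type2B_equinus_recurvatum",
                                         "type3_equinus_jumpknee",
                                         "type4_equinus_jumpknee_hip"])
    def test_equinus_keeps_affected_ankle_plantarflexed_in_stance(self, model,
                                                                  pattern):
        traj = generate_gait_pattern(GaitPatternParams(pattern=pattern,
                                                       n_strides=1), model)
        mask = _phase_mask(traj, "right", 0.0, 0.6)
        assert ankle_dorsiflexion(traj, "right")[mask].max() < 0.0

    def test_recurvatum_hyperextends_the_knee_in_stance(self, model):
        traj = generate_gait_pattern(
            GaitPatternParams(pattern="type2B_equinus_recurvatum", n_strides=1),
            model)
        mask = _phase_mask(traj, "right", 0.0, 0.6)
        assert knee_flexion(traj, "right")[mask].min() < 0.0

    def test_dropfoot_reduces_midswing_dorsiflexion(self, model, typical_trial):
        typ, _, _ = typical_trial
        drop = generate_gait_pattern(
            GaitPatternParams(pattern="type1_dropfoot", n_strides=2), model)
        m_t = _phase_mask(typ, "right", 0.75, 0.85)
        m_d = _phase_mask(drop, "right", 0.75, 0.85)
        assert (ankle_dorsiflexion(drop, "right")[m_d].mean()
                < ankle_dorsiflexion(typ, "right")[m_t].mean() - 0.05)

    def test_jump_knee_increases_knee_flexion_at_initial_contact(self, model,
                                                                 typical_trial):
        typ, _, _ = typical_trial
        jump = generate_gait_pattern(
            GaitPatternParams(pattern="type3_equinus_jumpknee", n_strides=2), model)
        def at_ic(traj):
            i = np.argmin(np.abs(traj.time / traj.metadata["stride_period"] - 0.5))
            return knee_flexion(traj, "right")[i]
        assert at_ic(jump) > at_ic(typ) + 0.1

    def test_type4_adds_anterior_pelvic_tilt(self, model):
        t4 = generate_gait_pattern(
            GaitPatternParams(pattern="type4_equinus_jumpknee_hip", n_strides=1),
            model)
        assert t4.column("pelvis_ry").mean() > 0.1


class TestGroundTruthKinetics:
    def test_quiet_standing_splits_weight_evenly(self, model, standing_trial):
        _, kin, gt = standing_trial
        inner = interior(kin.n_frames)
        half = model.body_weight / 2.0
        for side in ("left", "right"):
            assert np.allclose(gt.wrench[side].force[inner, 2], half, rtol=1e-9)

    def test_force_closure_against_independent_segment_sum(self, model,
                                                           typical_trial):
        traj, kin, gt = typical_trial
        # independent oracle: brute-force sum of m_i (a_i - g) per segment
        dt = kin.dt
        total = np.zeros((kin.n_frames, 3))
        for name, seg in model.segments.items():
            com = kin.pos[name] + np.einsum("nij,j->ni", kin.rot[name],
                                            seg.com_offset)
            v = np.gradient(com, dt, axis=0, edge_order=1)
            a = np.gradient(v, dt, axis=0, edge_order=1)
            total += seg.mass * (a - GRAVITY)
        got = gt.wrench["left"].force + gt.wrench["right"].force
        inner = interior(kin.n_frames)
        assert np.abs(got[inner] - total[inner]).max() < 1e-8

    def test_moment_closure_exact(self, typical_trial):
        _, _, gt = typical_trial
        sum_m = gt.wrench["left"].moment + gt.wrench["right"].moment
        scale = np.abs(gt.total.moment).max()
        assert np.abs(sum_m - gt.total.moment).max() < 1e-8 * max(scale, 1.0)

    def test_swing_foot_wrench_identically_zero(self, typical_trial):
        traj, _, gt = typical_trial
        for side in ("left", "right"):
            swing = ~gt.stance[side]
            assert np.all(gt.wrench[side].force[swing] == 0.0)
            assert np.all(gt.wrench[side].moment[swing] == 0.0)

    def test_vertical_forces_nonnegative(self, typical_trial):
        _, _, gt = typical_trial
        for side in ("left", "right"):
            assert gt.wrench[side].force[:, 2].min() >= -1e-9

    def test_no_stance_raises(self, model):
        q = np.zeros((30, model.ndof))
        q[:, 2] = 5.0  # airborne
        from gaitgrf.synthetic_gait import JointTrajectories
        traj = JointTrajectories(np.arange(30) / 150.0, q, model.coord_names,
                                 150.0, {})
        with pytest.raises(ValueError, match="stance"):
            construct_ground_truth_grfm(traj, model)


class TestKinematicNoise:
    def test_zero_noise_is_identity(self, typical_trial):
        traj, _, _ = typical_trial
        out = add_kinematic_noise(traj, 0.0, seed=1)
        assert np.array_equal(out.q, traj.q)

    def test_sample_sd_matches_request(self, model):
        p = GaitPatternParams(n_strides=10, noise_sd=0.0)
        traj = generate_gait_pattern(p, model)
        noisy = add_kinematic_noise(traj, 0.01, seed=3)
        d = noisy.q - traj.q
        rot = [i for i, n in enumerate(traj.coord_names)
               if not n.endswith(("_tx", "_ty", "_tz"))]
        sds = d[:, rot].std(axis=0)
        assert np.all(np.abs(sds - 0.01) < 0.002)
        assert np.abs(d[:, :3]).max() == 0.0  # translations untouched

    def test_noise_band_limited(self, model):
        traj = generate_gait_pattern(GaitPatternParams(n_strides=6), model)
        noisy = add_kinematic_noise(traj, 0.01, seed=5)
        d = (noisy.q - traj.q)[:, 6]
        w = np.hanning(len(d))
        spec = np.abs(np.fft.rfft(d * w)) ** 2
        freqs = np.fft.rfftfreq(len(d), 1 / traj.sample_rate)
        # 4th-order low-pass at 10 Hz: the bulk of the power sits below the
        # cutoff, with only the filter roll-off beyond it
        assert spec[freqs <= 10.0].sum() / spec.sum() > 0.90
        assert spec[freqs <= 15.0].sum() / spec.sum() > 0.98

    def test_same_seed_same_noise(self, typical_trial):
        traj, _, _ = typical_trial
        a = add_kinematic_noise(traj, 0.01, seed=9)
        b = add_kinematic_noise(traj, 0.01, seed=9)
        assert np.array_equal(a.q, b.q)
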