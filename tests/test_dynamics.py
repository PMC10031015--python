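import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitgrf.body_model import GRAVITY
from gaitgrf.dynamics import (
    Wrench,
    compute_segment_kinematics,
    inverse_dynamics,
    pelvis_residual_summary,
    total_required_wrench,
)
from gaitgrf.synthetic_gait import JointTrajectories, make_standing_trajectory

from conftest import interior


def _traj(model, q, rate=150.0):
    n = q.shape[0]
    return JointTrajectories(np.arange(n) / rate, q, model.coord_names, rate, {})


class TestSegmentKinematics:
    def test_static_pose_has_zero_rates(self, model):
        traj = make_standing_trajectory(model, duration=0.1)
        kin = compute_segment_kinematics(traj, model)
        for seg in model.segments:
            assert np.abs(kin.vel[seg]).max() < 1e-10
            assert np.abs(kin.acc_com[seg]).max() < 1e-10
            assert np.abs(kin.omega[seg]).max() < 1e-10

    def test_constant_base_velocity(self, model):
        n, rate = 30, 150.0
        q = np.zeros((n, model.ndof))
        q[:, 2] = model.neutral_pelvis_height()
        q[:, 0] = np.arange(n) / rate * 1.0  # 1 m/s along X
        kin = compute_segment_kinematics(_traj(model, q), model)
        assert np.allclose(kin.vel["pelvis"][1:-1], [1.0, 0.0, 0.0], atol=1e-8)
        assert np.abs(kin.acc_com["pelvis"][2:-2]).max() < 1e-6

    def test_hinge_constant_rate_angular_speed(self, model):
        n, rate, omega = 40, 150.0, 2.0
        q = np.zeros((n, model.ndof))
        q[:, 2] = model.neutral_pelvis_height()
        q[:, model.coord_index("knee_l")] = omega * np.arange(n) / rate
        kin = compute_segment_kinematics(_traj(model, q), model)
        speed = np.linalg.norm(kin.omega["shank_l"][1:-1], axis=1)
        assert np.allclose(speed, omega, atol=1e-6)

    def test_nonuniform_time_rejected(self, model):
        traj = make_standing_trajectory(model, duration=0.1)
        traj.time[3] += 1e-3
        with pytest.raises(ValueError, match="uniform"):
            compute_segment_kinematics(traj, model)

    def test_velocity_consistent_with_positions(self, typical_trial, model):
        _, kin, _ = typical_trial
        dt = kin.dt
        for seg in ("thigh_l", "foot_r"):
            p = kin.pos[seg]
            v_num = (p[2:] - p[:-2]) / (2 * dt)
            assert np.allclose(v_num, kin.vel[seg][1:-1], atol=1e-12)


class TestTotalRequiredWrench:
    def test_static_standing_supports_weight(self, model, standing_trial):
        _, kin, _ = standing_trial
        w = total_required_wrench(kin, model)
        inner = interior(kin.n_frames)
        assert np.allclose(w.force[inner, 2], model.body_weight, rtol=1e-9)
        assert np.abs(w.force[inner, :2]).max() < 1e-9

    def test_free_fall_needs_no_force(self, model):
        n, rate = 30, 150.0
        t = np.arange(n) / rate
        q = np.zeros((n, model.ndof))
        q[:, 2] = 5.0 + 0.5 * GRAVITY[2] * t ** 2
        kin = compute_segment_kinematics(_traj(model, q), model)
        w = total_required_wrench(kin, model)
        inner = interior(n)
        assert np.abs(w.force[inner]).max() < 1e-6
        assert np.abs(w.moment[inner]).max() < 1e-6

    def test_vertical_sinusoid_matches_closed_form(self, model):
        # whole body in prescribed vertical oscillation: F_z = M (g + z..)
        n, rate, A, f = 60, 150.0, 0.05, 2.0
        t = np.arange(n) / rate
        q = np.zeros((n, model.ndof))
        z = model.neutral_pelvis_height() + A * np.sin(2 * np.pi * f * t)
        q[:, 2] = z
        kin = compute_segment_kinematics(_traj(model, q), model)
        w = total_required_wrench(kin, model)
        # oracle uses the same central-difference scheme as the implementation
        v = np.gradient(z, 1 / rate, edge_order=1)
        zdd = np.gradient(v, 1 / rate, edge_order=1)
        expected = model.body_mass * (zdd + 9.81)
        inner = interior(n)
        assert np.allclose(w.force[inner, 2], expected[inner], rtol=1e-9)

    def test_moment_reference_point_transport(self, typical_trial, model):
        _, kin, _ = typical_trial
        w0 = total_required_wrench(kin, model, about=(0, 0, 0))
        w1 = total_required_wrench(kin, model, about=(1.0, -0.5, 0.3))
        assert np.allclose(w0.about((1.0, -0.5, 0.3)).moment, w1.moment, atol=1e-9)


class TestWrench:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_transport_round_trip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        w = Wrench(rng.normal(size=3) * 100, rng.normal(size=3) * 10,
                   rng.normal(size=3))
        p = rng.normal(size=3)
        back = w.about(p).about(w.point)
        assert np.allclose(back.moment, w.moment, atol=1e-12)
        assert np.allclose(back.force, w.force, atol=1e-12)


class TestInverseDynamics:
    def test_consistent_externals_null_the_residual(self, model, typical_trial):
        traj, kin, gt = typical_trial
        gf = inverse_dynamics(kin, model, external=gt.wrench)
        res = gf.residual_wrench()
        inner = interior(kin.n_frames)
        mean_f = np.mean(np.linalg.norm(res.force[inner], axis=1))
        assert mean_f / model.body_mass < 1e-6  # N/kg

    def test_static_no_externals_residual_is_gravity(self, model, standing_trial):
        _, kin, _ = standing_trial
        gf = inverse_dynamics(kin, model, external=None)
        res = gf.residual_wrench()
        inner = interior(kin.n_frames)
        assert np.allclose(res.force[inner], [0, 0, model.body_weight], rtol=1e-9)

    def test_superposition_in_externals(self, model, typical_trial):
        traj, kin, gt = typical_trial
        tau0 = inverse_dynamics(kin, model, None).tau
        tau1 = inverse_dynamics(kin, model, {"left": gt.wrench["left"],
                                             "right": None}).tau
        tau2 = inverse_dynamics(kin, model, {"left": None,
                                             "right": gt.wrench["right"]}).tau
        tau12 = inverse_dynamics(kin, model, gt.wrench).tau
        assert np.allclose(tau12 - tau0, (tau1 - tau0) + (tau2 - tau0), atol=1e-8)

    def test_unknown_wrench_frame_rejected(self, model, standing_trial):
        _, kin, _ = standing_trial
        bad = Wrench(np.zeros((kin.n_frames, 3)), np.zeros((kin.n_frames, 3)),
                     np.zeros(3), frame="plate1")
        with pytest.raises(ValueError, match="frame"):
            inverse_dynamics(kin, model, {"left": bad, "right": None})

    def test_static_single_point_load_gives_closed_form_ankle_torque(self, model):
        # quiet standing, all load on the left foot at a point d anterior to
        # the ankle: the ankle hinge torque equals the external moment about
        # the hinge minus the foot's own gravity moment
        traj = make_standing_trajectory(model, duration=0.1)
        kin = compute_segment_kinematics(traj, model)
        n = kin.n_frames
        d = 0.05
        ankle = kin.pos["foot_l"][0]
        cop = ankle + [d, 0.0, -ankle[2]]
        W = model.body_weight
        ext = {"left": Wrench(np.tile([0, 0, W], (n, 1)), np.zeros((n, 3)), cop),
               "right": None}
        gf = inverse_dynamics(kin, model, ext)
        tau_ankle = gf.tau[5, kin.model.coord_index("ankle_l")]
        foot = model.segments["foot_l"]
        com_w = kin.com["foot_l"][0]
        # required hinge torque = (inertial-minus-gravity load moment)
        # minus (external moment), Y component about the ankle
        expected = (np.cross(com_w - ankle, foot.mass * (-GRAVITY))
                    - np.cross(cop - ankle, [0, 0, W]))[1]
        assert tau_ankle == pytest.approx(expected, abs=1e-9)


class TestPelvisResidualSummary:
    def test_zero_series(self, model, standing_trial):
        _, kin, gt = standing_trial
        gf = inverse_dynamics(kin, model, external=gt.wrench)
        rf, rm = pelvis_residual_summary(gf, model.body_mass)
        assert rf < 1e-9 and rm < 1e-9

    def test_constructed_constant_residual_magnitude(self, model, standing_trial):
        # a constant unbalanced force of 0.81 N/kg must be reported as such
        _, kin, gt = standing_trial
        gf = inverse_dynamics(kin, model, external=gt.wrench)
        gf.tau[:, 0] += 0.81 * model.body_mass
        rf, _ = pelvis_residual_summary(gf, model.body_mass)
        assert rf == pytest.approx(0.81, abs=1e-9)

    def test_matches_brute_force_mean_of_norms(self, model, standing_trial):
        _, kin, gt = standing_trial
        gf = inverse_dynamics(kin, model, external=gt.wrench)
        rng = np.random.default_rng(7)
        gf.tau[:, 0:3] = rng.normal(size=(kin.n_frames, 3))
        res = gf.residual_wrench()
        brute = np.mean([np.linalg.norm(res.force[i]) for i in range(kin.n_frames)])
        rf, _ = pelvis_residual_summary(gf, model.body_mass)
        assert rf == pytest.approx(brute / model.body_mass, rel=1e-12)
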