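"""Differential kinematics and Newton-Euler inverse dynamics.

Forward kinematics propagates generalized coordinates through the model
tree; velocities and accelerations are obtained by central differences
(one-sided at the endpoints), with rotations differenced on the rotation
manifold (relative-rotation logarithm), never per Euler component.

Generalized inverse dynamics is evaluated in virtual-work form: for every
degree of freedom k with world-frame axis a_k through point p_k,

    tau_k = sum_i [ (a_k x (r_i - p_k)) . m_i (a_i - g)
                    + a_k . (I_i alpha_i + omega_i x I_i omega_i) ]
            - (contribution of external wrenches),

which is algebraically equivalent to a recursive Newton-Euler sweep over
the tree.  The first six components are the floating-base residuals: the
net external wrench (about the pelvis origin) that would be required to
realize the motion beyond the supplied external forces.

Sign convention: ground reactions are expressed as forces ON the body,
vertical positive up (force-plate convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .body_model import BodyModel

__all__ = [
    "Wrench",
    "SegmentKinematics",
    "GeneralizedForces",
    "forward_kinematics",
    "compute_segment_kinematics",
    "total_required_wrench",
    "inverse_dynamics",
    "pelvis_residual_summary",
]


@dataclass
class Wrench:
    """Force + moment about a reference point, in a named frame.

    ``force`` and ``moment`` may be single 3-vectors or (N, 3) series.
    """

    force: np.ndarray
    moment: np.ndarray
    point: np.ndarray
    frame: str = "lab"

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, float)
        self.moment = np.asarray(self.moment, float)
        self.point = np.asarray(self.point, float)

    def about(self, new_point) -> "Wrench":
        """Re-express about a new reference point: M' = M + (p - p') x F."""
        new_point = np.asarray(new_point, float)
        shift = np.cross(self.point - new_point, self.force)
        return Wrench(self.force.copy(), self.moment + shift, new_point, self.frame)


def _euler_xyz_axes(angles: np.ndarray) -> np.ndarray:
    """World axes of intrinsic X-Y-Z Euler rates for R = Rx(a) Ry(b) Rz(c).

    Returns (N, 3, 3) with axes as rows: a1 = ex, a2 = Rx ey, a3 = Rx Ry ez.
    """
    a, b = angles[..., 0], angles[..., 1]
    n = angles.shape[0]
    axes = np.zeros((n, 3, 3))
    axes[:, 0] = [1.0, 0.0, 0.0]
    axes[:, 1, 1] = np.cos(a)
    axes[:, 1, 2] = np.sin(a)
    # Rx(a) Ry(b) ez = Rx(a) @ (sin b, 0, cos b)
    axes[:, 2, 0] = np.sin(b)
    axes[:, 2, 1] = -np.sin(a) * np.cos(b)
    axes[:, 2, 2] = np.cos(a) * np.cos(b)
    return axes


def forward_kinematics(model: BodyModel, q: np.ndarray):
    """Pose of every segment plus per-DoF world axes/points, vectorized over frames.

    Returns ``(pos, rot, dof_axes, dof_points, dof_is_rot, seg_dofs)`` where
    ``pos[seg]`` is (N, 3), ``rot[seg]`` is (N, 3, 3); ``dof_axes``/
    ``dof_points`` are (N, ndof, 3); ``seg_dofs[seg]`` lists the coordinate
    indices that move the segment.
    """
    q = np.atleast_2d(np.asarray(q, float))
    n = q.shape[0]
    if q.shape[1] != model.ndof:
        raise ValueError(f"q has {q.shape[1]} columns, model has {model.ndof} DoFs")

    pos: dict[str, np.ndarray] = {}
    rot: dict[str, np.ndarray] = {}
    dof_axes = np.zeros((n, model.ndof, 3))
    dof_points = np.zeros((n, model.ndof, 3))
    dof_is_rot = np.ones(model.ndof, bool)
    seg_dofs: dict[str, list[int]] = {}

    pos["pelvis"] = q[:, 0:3]
    rot["pelvis"] = Rotation.from_euler("XYZ", q[:, 3:6]).as_matrix()
    for k in range(3):
        dof_is_rot[k] = False
        dof_axes[:, k, k] = 1.0
    dof_axes[:, 3:6] = _euler_xyz_axes(q[:, 3:6])
    dof_points[:, 3:6] = q[:, None, 0:3]
    seg_dofs["pelvis"] = list(range(6))

    idx = 6
    for joint in model.joints:
        pp, rp = pos[joint.parent], rot[joint.parent]
        jp = pp + np.einsum("nij,j->ni", rp, joint.parent_offset)
        chain = list(seg_dofs[joint.parent])
        if joint.kind == "fixed":
            rc = rp
        elif joint.kind == "hinge":
            rj = Rotation.from_rotvec(np.outer(q[:, idx], joint.axis)).as_matrix()
            rc = np.einsum("nij,njk->nik", rp, rj)
            dof_axes[:, idx] = np.einsum("nij,j->ni", rp, joint.axis)
            dof_points[:, idx] = jp
            chain.append(idx)
            idx += 1
        else:  # ball, intrinsic XYZ
            angles = q[:, idx:idx + 3]
            rj = Rotation.from_euler("XYZ", angles).as_matrix()
            rc = np.einsum("nij,njk->nik", rp, rj)
            local_axes = _euler_xyz_axes(angles)
            dof_axes[:, idx:idx + 3] = np.einsum("nij,nkj->nki", rp, local_axes)
            dof_points[:, idx:idx + 3] = jp[:, None, :]
            chain += [idx, idx + 1, idx + 2]
            idx += 3
        pos[joint.child] = jp
        rot[joint.child] = rc
        seg_dofs[joint.child] = chain

    return pos, rot, dof_axes, dof_points, dof_is_rot, seg_dofs


def _diff(x: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    d[0] = (x[1] - x[0]) / dt
    d[-1] = (x[-1] - x[-2]) / dt
    return d


def _angular_velocity(R: np.ndarray, dt: float) -> np.ndarray:
    om = np.empty((R.shape[0], 3))
    rel = np.einsum("nij,nkj->nik", R[2:], R[:-2])
    om[1:-1] = Rotation.from_matrix(rel).as_rotvec() / (2.0 * dt)
    om[0] = Rotation.from_matrix(R[1] @ R[0].T).as_rotvec() / dt
    om[-1] = Rotation.from_matrix(R[-1] @ R[-2].T).as_rotvec() / dt
    return om


@dataclass
class SegmentKinematics:
    """Per-frame poses and derivatives of all segments + DoF frame data."""

    time: np.ndarray
    dt: float
    model: BodyModel
    pos: dict[str, np.ndarray]
    rot: dict[str, np.ndarray]
    com: dict[str, np.ndarray]
    vel: dict[str, np.ndarray]        # segment-origin linear velocity
    vel_com: dict[str, np.ndarray]
    omega: dict[str, np.ndarray]
    acc_com: dict[str, np.ndarray]
    alpha: dict[str, np.ndarray]
    dof_axes: np.ndarray              # (N, ndof, 3)
    dof_points: np.ndarray            # (N, ndof, 3)
    dof_is_rot: np.ndarray            # (ndof,)
    seg_dofs: dict[str, list[int]]

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def point_velocity(self, seg: str, pts: np.ndarray) -> np.ndarray:
        """Velocity of points rigidly attached to ``seg``; pts is (N, P, 3) world."""
        v = self.vel[seg][:, None, :]
        om = self.omega[seg][:, None, :]
        return v + np.cross(om, pts - self.pos[seg][:, None, :])

    def local_to_world(self, seg: str, local_pts: np.ndarray) -> np.ndarray:
        """Map (P, 3) segment-frame points to (N, P, 3) world coordinates."""
        return (self.pos[seg][:, None, :]
                + np.einsum("nij,pj->npi", self.rot[seg], np.asarray(local_pts, float)))


def compute_segment_kinematics(traj, model: BodyModel) -> SegmentKinematics:
    """Forward kinematics + numeric differentiation for a whole trial."""
    time = np.asarray(traj.time, float)
    if len(time) < 5:
        raise ValueError("need at least 5 frames")
    dt = time[1] - time[0]
    if np.max(np.abs(np.diff(time) - dt)) > 1e-9:
        raise ValueError("time vector must be uniformly sampled")

    pos, rot, dof_axes, dof_points, dof_is_rot, seg_dofs = forward_kinematics(model, traj.q)
    com, vel, vel_com, omega, acc_com, alpha = {}, {}, {}, {}, {}, {}
    for name, seg in model.segments.items():
        com[name] = pos[name] + np.einsum("nij,j->ni", rot[name], seg.com_offset)
        vel[name] = _diff(pos[name], dt)
        vel_com[name] = _diff(com[name], dt)
        acc_com[name] = _diff(vel_com[name], dt)
        omega[name] = _angular_velocity(rot[name], dt)
        alpha[name] = _diff(omega[name], dt)
    return SegmentKinematics(time, dt, model, pos, rot, com, vel, vel_com,
                             omega, acc_com, alpha,
                             dof_axes, dof_points, dof_is_rot, seg_dofs)


def _segment_loads(kin: SegmentKinematics, seg_name: str):
    """Inertial-minus-gravity force and rotational load of one segment."""
    seg = kin.model.segments[seg_name]
    g = kin.model.gravity
    f = seg.mass * (kin.acc_com[seg_name] - g)
    R = kin.rot[seg_name]
    Iw = np.einsum("nij,jk,nlk->nil", R, seg.inertia, R)
    n = (np.einsum("nij,nj->ni", Iw, kin.alpha[seg_name])
         + np.cross(kin.omega[seg_name], np.einsum("nij,nj->ni", Iw, kin.omega[seg_name])))
    return f, n


def total_required_wrench(kin: SegmentKinematics, model: BodyModel,
                          about=(0.0, 0.0, 0.0)) -> Wrench:
    """Net external wrench (force on body) required by Newton-Euler.

    force = sum_i m_i (a_i - g); moment about ``about`` adds the moment of
    those forces plus each segment's rotational load I alpha + omega x I omega.
    """
    p = np.asarray(about, float)
    F = np.zeros((kin.n_frames, 3))
    M = np.zeros((kin.n_frames, 3))
    for name in model.segments:
        f, nrot = _segment_loads(kin, name)
        F += f
        M += np.cross(kin.com[name] - p, f) + nrot
    return Wrench(F, M, p)


@dataclass
class GeneralizedForces:
    """Per-frame generalized forces: 6 base residual components + joint torques."""

    tau: np.ndarray                 # (N, ndof)
    coord_names: tuple[str, ...]
    base_axes: np.ndarray           # (N, 3, 3) rows = base-rotation world axes
    pelvis_origin: np.ndarray       # (N, 3)

    def residual_wrench(self) -> Wrench:
        """Base residuals as a force/moment wrench about the pelvis origin."""
        force = self.tau[:, 0:3]
        moment = np.linalg.solve(self.base_axes, self.tau[:, 3:6, None])[..., 0]
        return Wrench(force, moment, self.pelvis_origin)

    def joint_torques(self) -> np.ndarray:
        return self.tau[:, 6:]


def inverse_dynamics(kin: SegmentKinematics, model: BodyModel,
                     external: dict[str, Wrench] | None = None) -> GeneralizedForces:
    """Generalized forces required to realize the motion.

    ``external`` maps foot side (``"left"``/``"right"``) to a lab-frame
    Wrench series applied to that foot (force ON the body); its
    contribution is subtracted from the required actuation.
    """
    n, nd = kin.n_frames, model.ndof
    tau = np.zeros((n, nd))
    axes, pts, isrot = kin.dof_axes, kin.dof_points, kin.dof_is_rot
    for name in model.segments:
        f, nrot = _segment_loads(kin, name)
        for k in kin.seg_dofs[name]:
            if isrot[k]:
                arm = np.cross(axes[:, k], kin.com[name] - pts[:, k])
                tau[:, k] += np.einsum("ni,ni->n", arm, f)
                tau[:, k] += np.einsum("ni,ni->n", axes[:, k], nrot)
            else:
                tau[:, k] += np.einsum("ni,ni->n", axes[:, k], f)
    if external:
        for side, w in external.items():
            if w is None:
                continue
            if w.frame != "lab":
                raise ValueError(f"external wrench frame {w.frame!r} unknown; expected 'lab'")
            seg = model.foot_segment(side)
            F = np.broadcast_to(np.atleast_2d(w.force), (n, 3))
            M = np.broadcast_to(np.atleast_2d(w.moment), (n, 3))
            ref = np.broadcast_to(np.atleast_2d(w.point), (n, 3))
            for k in kin.seg_dofs[seg]:
                if isrot[k]:
                    arm = np.cross(axes[:, k], ref - pts[:, k])
                    tau[:, k] -= np.einsum("ni,ni->n", arm, F)
                    tau[:, k] -= np.einsum("ni,ni->n", axes[:, k], M)
                else:
                    tau[:, k] -= np.einsum("ni,ni->n", axes[:, k], F)
    return GeneralizedForces(tau, model.coord_names, kin.dof_axes[:, 3:6].copy(),
                             kin.pos["pelvis"].copy())


def pelvis_residual_summary(gf: GeneralizedForces, body_mass: float) -> tuple[float, float]:
    """Trial-mean magnitudes of the pelvis residual force and moment, per kg.

    Returns ``(mean |F| / m, mean |M| / m)`` in N/kg and N m/kg.
    """
    w = gf.residual_wrench()
    return (float(np.mean(np.linalg.norm(w.force, axis=-1))) / body_mass,
            float(np.mean(np.linalg.norm(w.moment, axis=-1))) / body_mass)
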