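"""Prediction of ground reaction forces and moments from kinematics alone.

The method embeds a conditional foot-ground contact model in the actuator
recruitment problem.  Under each foot, 25 contact nodes on a 5x5 grid span
the sole.  Each node carries five unilateral force actuators: one purely
vertical generator (0, 0, 1) and four paired friction generators
(+-mu, 0, 1) and (0, +-mu, 1), a generator-based approximation of the
static Coulomb friction cone with mu = 0.5.  The strength available to a
node depends on its height above the floor and its speed:

    c_p,i = N_max * z_smooth(z_ratio) * v_smooth(v_ratio)

with z_ratio = p_z / z_lim, v_ratio = |p_vel| / v_lim.  Each factor equals
1 below its knee (0.8 for height, 0.15 for velocity), falls along the
half-cosine (1 + cos((ratio - knee) pi / (1 - knee))) / 2 on (knee, 1],
and is 0 above 1; N_max = 40% of body weight, z_lim = 0.03 m,
v_lim = 0.8 m/s.  A node can therefore only push, and only when it is
close to the floor and nearly stationary.

Per frame, contact actuators are recruited together with one bidirectional
constant-strength torque actuator per joint DoF and six weak residual
actuators at the pelvis, by minimizing the sum of squared activities
(force / strength)^2 subject to the generalized Newton-Euler equations.
The residual actuators exist only for numerical feasibility; the solver
treats them lexicographically (their activity is minimized first, then the
contact and joint effort), so whenever the required wrench is achievable
through the contact cone — in particular throughout single support — the
predicted ground reactions match the equations of motion exactly.

With the free joint-torque and residual variables eliminated, each stage
is exactly a nonnegative least-squares problem, solved with a
deterministic active-set method (scipy.optimize.nnls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .body_model import BodyModel
from .dynamics import (SegmentKinematics, Wrench, compute_segment_kinematics,
                       inverse_dynamics)

__all__ = [
    "StrengthProfileParams",
    "RecruitmentSettings",
    "RecruitmentProblem",
    "RecruitmentSolution",
    "PredictedGRFM",
    "build_node_grid",
    "strength_profile",
    "assemble_frame_problem",
    "solve_recruitment",
    "predict_trial",
]


@dataclass(frozen=True)
class StrengthProfileParams:
    """Parameters of the conditional contact-strength profile."""

    z_lim: float = 0.03      # m, maximal node height for contact detection
    v_lim: float = 0.8       # m/s, maximal node speed for contact detection
    z_knee: float = 0.8      # height ratio below which strength is maximal
    v_knee: float = 0.15     # velocity ratio below which strength is maximal
    n_max: float | None = None  # N; None -> 0.4 * body weight at use
    mu: float = 0.5          # Coulomb friction coefficient

    def __post_init__(self) -> None:
        if not (0.0 < self.z_knee < 1.0 and 0.0 < self.v_knee < 1.0):
            raise ValueError("knee thresholds must lie in (0, 1)")
        for name in ("z_lim", "v_lim", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_max is not None and self.n_max <= 0:
            raise ValueError("n_max must be positive")

    def resolve_n_max(self, body_weight: float) -> float:
        return 0.4 * body_weight if self.n_max is None else self.n_max


@dataclass(frozen=True)
class RecruitmentSettings:
    """Actuator strengths and numerical knobs of the recruitment solve."""

    joint_strength_per_mass: float = 3.0   # N m per kg body mass, per joint DoF
    residual_force_fraction: float = 0.01  # of body weight
    residual_moment_fraction: float = 0.01  # of body weight x 1 m
    eps_strength_fraction: float = 1e-6    # contact actuators below this are dropped
    equality_weight: float = 1e6           # stage-2 equality enforcement weight
    cop_force_threshold: float = 5.0       # N, minimum Fz for a defined CoP


def build_node_grid(sole_outline: dict[str, float]) -> np.ndarray:
    """Deterministic 5x5 node grid spanning the sole, in the foot frame.

    Returns (25, 3) local positions at sole height.
    """
    xs = np.linspace(sole_outline["x_min"], sole_outline["x_max"], 5)
    ys = np.linspace(-sole_outline["half_width"], sole_outline["half_width"], 5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(),
                     np.full(25, sole_outline["z"])], axis=1)
    return grid


def _smooth_factor(ratio: np.ndarray, knee: float) -> np.ndarray:
    r = np.asarray(ratio, float)
    out = np.where(r <= knee, 1.0,
                   np.where(r >= 1.0, 0.0,
                            0.5 * (1.0 + np.cos((r - knee) * np.pi / (1.0 - knee)))))
    return np.clip(out, 0.0, 1.0)


def strength_profile(p_z, p_vel, params: StrengthProfileParams,
                     body_weight: float | None = None) -> np.ndarray:
    """Available strength c_p,i (N) of nodes at heights ``p_z`` and speeds ``p_vel``.

    Vectorized; negative heights are clamped to zero (node below floor) with
    a warning.
    """
    p_z = np.asarray(p_z, float)
    p_vel = np.asarray(p_vel, float)
    if np.any(p_z < -1e-12):
        warnings.warn("contact node below floor level; height clamped to 0",
                      stacklevel=2)
    z_ratio = np.clip(p_z, 0.0, None) / params.z_lim
    v_ratio = np.abs(p_vel) / params.v_lim
    n_max = params.n_max
    if n_max is None:
        if body_weight is None:
            raise ValueError("body_weight required when n_max is not set")
        n_max = 0.4 * body_weight
    return n_max * _smooth_factor(z_ratio, params.z_knee) * _smooth_factor(v_ratio, params.v_knee)


def _generators(mu: float) -> np.ndarray:
    """Five unilateral force generators per node (rows), unit normal component."""
    return np.array([
        [+mu, 0.0, 1.0],
        [-mu, 0.0, 1.0],
        [0.0, +mu, 1.0],
        [0.0, -mu, 1.0],
        [0.0, 0.0, 1.0],
    ])


@dataclass
class RecruitmentProblem:
    """One frame of the recruitment problem, ready for the solver."""

    A_contact: np.ndarray      # (ndof, n_c) generalized-force columns
    strengths: np.ndarray      # (n_c,)
    b: np.ndarray              # (ndof,) required generalized forces
    R_base: np.ndarray         # (6, 6) residual-actuator columns on base rows
    s_res: np.ndarray          # (6,) residual strengths (N, N, N, Nm, Nm, Nm)
    s_joint: float             # joint-torque actuator strength (N m)
    meta: dict                 # node positions / generator dirs / foot labels
    settings: RecruitmentSettings

    @property
    def n_contacts(self) -> int:
        return self.A_contact.shape[1]


@dataclass
class RecruitmentSolution:
    f: np.ndarray              # (n_c,) contact actuator forces, >= 0
    tau: np.ndarray            # (n_joint,) joint actuator torques
    residual: np.ndarray       # (6,) residual actuator components (F then M)
    activities: np.ndarray     # contact activities f / strength
    objective: float
    eq_residual_rel: float     # relative equality-constraint residual
    status: str                # "ok" | "infeasible-residual" | "solver-failed"


def _node_world_kinematics(kin: SegmentKinematics, model: BodyModel, side: str):
    grid = build_node_grid(model.sole_outline[side])
    seg = model.foot_segment(side)
    pts = kin.local_to_world(seg, grid)          # (N, 25, 3)
    vel = kin.point_velocity(seg, pts)           # (N, 25, 3)
    return pts, vel


def assemble_frame_problem(
    frame: int,
    kin: SegmentKinematics,
    model: BodyModel,
    b_required: np.ndarray,
    node_pos: dict[str, np.ndarray],
    node_strength: dict[str, np.ndarray],
    params: StrengthProfileParams,
    settings: RecruitmentSettings,
) -> RecruitmentProblem:
    """Assemble one frame's recruitment problem.

    Contact columns map node generator forces to generalized forces through
    the contact-point Jacobian transpose; actuators whose strength is below
    the epsilon filter are dropped.  Residual columns are a pure force and a
    pure moment at the pelvis origin.
    """
    nd = model.ndof
    bw = model.body_weight
    eps = settings.eps_strength_fraction * bw
    gens = _generators(params.mu)
    axes = kin.dof_axes[frame]       # (ndof, 3)
    pts_dof = kin.dof_points[frame]  # (ndof, 3)
    isrot = kin.dof_is_rot

    cols, strengths, meta_nodes, meta_dirs, meta_side, meta_node_idx = [], [], [], [], [], []
    for side in ("left", "right"):
        c = node_strength[side][frame]
        active = np.flatnonzero(c >= eps)
        if len(active) == 0:
            continue
        p = node_pos[side][frame][active]        # (na, 3)
        seg = model.foot_segment(side)
        dofs = kin.seg_dofs[seg]
        # jacobian of node points wrt the foot's chain: (ndof, na, 3)
        J = np.zeros((nd, len(active), 3))
        for k in dofs:
            if isrot[k]:
                J[k] = np.cross(axes[k], p - pts_dof[k])
            else:
                J[k] = axes[k]
        # columns for all 5 generators of each active node: (ndof, na, 5)
        block = np.einsum("knj,gj->kng", J, gens)
        cols.append(block.reshape(nd, -1))
        strengths.append(np.repeat(c[active], 5))
        meta_nodes.append(np.repeat(p, 5, axis=0))
        meta_dirs.append(np.tile(gens, (len(active), 1)))
        meta_side += [side] * (5 * len(active))
        meta_node_idx.append(np.repeat(active, 5))

    if cols:
        A = np.concatenate(cols, axis=1)
        strengths = np.concatenate(strengths)
        meta = {
            "points": np.concatenate(meta_nodes),
            "dirs": np.concatenate(meta_dirs),
            "side": np.array(meta_side),
            "node_index": np.concatenate(meta_node_idx),
        }
    else:
        A = np.zeros((nd, 0))
        strengths = np.zeros(0)
        meta = {"points": np.zeros((0, 3)), "dirs": np.zeros((0, 3)),
                "side": np.array([], dtype="<U5"), "node_index": np.zeros(0, int)}

    # residual actuators: pure force + pure moment at the pelvis origin.
    # Base-translation rows see the force directly; base-rotation rows see
    # the moment projected on the Euler-rate axes (the force has no moment
    # about the pelvis origin itself).
    R = np.zeros((6, 6))
    R[0:3, 0:3] = np.eye(3)
    R[3:6, 3:6] = kin.dof_axes[frame, 3:6]
    s_res = np.concatenate([
        np.full(3, settings.residual_force_fraction * bw),
        np.full(3, settings.residual_moment_fraction * bw),
    ])
    s_joint = settings.joint_strength_per_mass * model.body_mass
    return RecruitmentProblem(A, strengths, np.asarray(b_required, float),
                              R, s_res, s_joint, meta, settings)


def solve_recruitment(problem: RecruitmentProblem) -> RecruitmentSolution:
    """Two-stage (lexicographic) solve of one frame's recruitment problem.

    Stage 1 finds the smallest achievable residual-actuator activity given
    the unilateral contact cone; stage 2 minimizes the contact plus joint
    activity subject to that residual, via a heavily weighted equality
    penalty inside a single NNLS.  Deterministic for fixed inputs.
    """
    A, c, b = problem.A_contact, problem.strengths, problem.b
    R, s_res = problem.R_base, problem.s_res
    sj = problem.s_joint
    set_ = problem.settings
    nd = len(b)
    n_c = problem.n_contacts
    b_base, b_joint = b[:6], b[6:]
    A_base, A_joint = A[:6], A[6:]
    Rinv = np.linalg.inv(R)
    status = "ok"

    # stage 1: minimal residual activity, lexicographically by block --
    # force residuals are eliminated first (a required force inside the
    # friction cone is always achievable during support), then moment
    # residuals are minimized subject to that force balance.  An
    # unachievable required moment (e.g. a free vertical moment beyond what
    # the friction generators can supply) therefore never leaks into the
    # predicted forces.
    if n_c:
        M1 = (Rinv @ A_base) / s_res[:, None]
        v1 = (Rinv @ b_base) / s_res
        w_lex = np.ones(6)
        w_lex[:3] = 1e4
        try:
            f1, _ = nnls(M1 * w_lex[:, None], v1 * w_lex)
        except Exception:
            f1 = np.zeros(n_c)
            status = "solver-failed"
        r_star = Rinv @ (b_base - A_base @ f1)
        rho = float(np.linalg.norm(r_star / s_res))
    else:
        r_star = Rinv @ b_base
        rho = float(np.linalg.norm(r_star / s_res))
    if rho > 1e-6:
        status = "infeasible-residual" if status == "ok" else status

    # stage 2: minimal contact + joint activity at that residual
    if n_c:
        target = b_base - R @ r_star
        scale = np.maximum(np.abs(target), np.max(s_res))
        W = set_.equality_weight / scale
        rows = [np.diag(1.0 / c)]
        rhs = [np.zeros(n_c)]
        if nd > 6:
            rows.append(A_joint / sj)
            rhs.append(b_joint / sj)
        rows.append(A_base * W[:, None])
        rhs.append(target * W)
        M2 = np.concatenate(rows, axis=0)
        v2 = np.concatenate(rhs)
        try:
            f, _ = nnls(M2, v2, maxiter=max(50 * n_c, 1000))
        except Exception:
            f = f1
            status = "solver-failed"
    else:
        f = np.zeros(0)

    tau = b_joint - A_joint @ f
    residual = Rinv @ (b_base - A_base @ f)
    act = f / c if n_c else np.zeros(0)
    objective = float(act @ act + (tau / sj) @ (tau / sj)
                      + (residual / s_res) @ (residual / s_res))
    gap = b_base - A_base @ f - R @ residual
    eq_rel = float(np.linalg.norm(gap)
                   / max(np.linalg.norm(b_base), np.max(s_res)))
    return RecruitmentSolution(f, tau, residual, act, objective, eq_rel, status)


@dataclass
class PredictedGRFM:
    """Predicted per-foot ground reaction wrenches about the lab origin."""

    time: np.ndarray
    wrench: dict[str, Wrench]
    cop: dict[str, np.ndarray]          # NaN where Fz below threshold
    residual: Wrench                    # residual-actuator wrench at the pelvis
    status: np.ndarray                  # per-frame solver status strings
    activities_max: np.ndarray          # per-frame max contact activity
    node_forces: dict[str, np.ndarray]  # (N, 25, 3) per-node force vectors


def predict_trial(traj, model: BodyModel,
                  params: StrengthProfileParams | None = None,
                  settings: RecruitmentSettings | None = None,
                  kin: SegmentKinematics | None = None) -> PredictedGRFM:
    """Predict per-foot GRF&Ms for a whole trial from kinematics alone.

    Runs the per-frame recruitment solve and aggregates node forces into
    per-foot wrenches about the lab origin.  The centre of pressure is
    reported only where the predicted vertical force exceeds the CoP force
    threshold.  Raw (unfiltered) output; apply the same low-pass filter as
    for measured kinetics before curve comparisons.
    """
    params = params or StrengthProfileParams()
    settings = settings or RecruitmentSettings()
    if kin is None:
        kin = compute_segment_kinematics(traj, model)
    n = kin.n_frames
    bw = model.body_weight

    b_all = inverse_dynamics(kin, model, external=None).tau  # (N, ndof)
    node_pos, node_strength = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grazing frames: nodes clamp at floor
        for side in ("left", "right"):
            pts, vel = _node_world_kinematics(kin, model, side)
            speed = np.linalg.norm(vel, axis=-1)
            node_pos[side] = pts
            node_strength[side] = strength_profile(pts[..., 2], speed, params, bw)

    forces = {s: np.zeros((n, 3)) for s in ("left", "right")}
    moments = {s: np.zeros((n, 3)) for s in ("left", "right")}
    node_forces = {s: np.zeros((n, 25, 3)) for s in ("left", "right")}
    res_force = np.zeros((n, 3))
    res_moment = np.zeros((n, 3))
    status = np.full(n, "ok", dtype="<U24")
    act_max = np.zeros(n)

    for i in range(n):
        prob = assemble_frame_problem(i, kin, model, b_all[i], node_pos,
                                      node_strength, params, settings)
        sol = solve_recruitment(prob)
        status[i] = sol.status
        act_max[i] = sol.activities.max() if len(sol.activities) else 0.0
        res_force[i] = sol.residual[:3]
        res_moment[i] = sol.residual[3:]
        if prob.n_contacts:
            fvec = sol.f[:, None] * prob.meta["dirs"]
            mvec = np.cross(prob.meta["points"], fvec)
            for side in ("left", "right"):
                m = prob.meta["side"] == side
                forces[side][i] = fvec[m].sum(axis=0)
                moments[side][i] = mvec[m].sum(axis=0)
                np.add.at(node_forces[side][i], prob.meta["node_index"][m], fvec[m])

    wrench, cop = {}, {}
    for side in ("left", "right"):
        wrench[side] = Wrench(forces[side], moments[side], np.zeros(3))
        c = np.full((n, 3), np.nan)
        fz = forces[side][:, 2]
        okm = fz > settings.cop_force_threshold
        c[okm, 0] = -moments[side][okm, 1] / fz[okm]
        c[okm, 1] = +moments[side][okm, 0] / fz[okm]
        c[okm, 2] = 0.0
        cop[side] = c
    residual = Wrench(res_force, res_moment, kin.pos["pelvis"].copy())
    return PredictedGRFM(kin.time.copy(), wrench, cop, residual, status,
                         act_max, node_forces)
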