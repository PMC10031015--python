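"""Synthetic marker layer and inverse kinematics.

Markers are synthesized from segment poses (rigid transform of fixed
segment-frame positions plus optional isotropic Gaussian noise) and the
generalized coordinates are recovered per frame by nonlinear weighted
least squares, warm-started from the previous frame.  The mean marker
tracking error — the mean distance between measured and model-reconstructed
markers — quantifies how well the rigid model reproduces the marker cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .body_model import BodyModel
from .dynamics import forward_kinematics
from .synthetic_gait import JointTrajectories

__all__ = [
    "MarkerSet",
    "default_marker_layout",
    "generate_markers",
    "inverse_kinematics",
    "mean_marker_tracking_error",
    "smooth_markers",
]

#: per-axis sigma for a 3-D isotropic Gaussian whose mean vector norm is 1
_SIGMA_PER_MEAN_DISTANCE = float(np.sqrt(np.pi / 8.0))


@dataclass
class MarkerSet:
    """Marker names, parentage, segment-frame positions and trajectories."""

    names: tuple[str, ...]
    parents: tuple[str, ...]
    local_positions: np.ndarray      # (M, 3) m, segment frame
    trajectories: np.ndarray         # (N, M, 3) m, lab frame; NaN = missing
    rate: float
    units: str = "m"

    @property
    def n_frames(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.names)

    def missing(self) -> np.ndarray:
        """(N, M) mask of frames/markers flagged missing."""
        return np.isnan(self.trajectories).any(axis=2)


def default_marker_layout(model: BodyModel) -> dict[str, tuple[str, np.ndarray]]:
    """A simplified full-body layout: >= 3 non-collinear markers per body.

    Positions are plausible surface offsets scaled with stature; the layout
    is synthetic and makes no claim of matching any clinical marker set.
    """
    H = model.anthropometrics.height
    lt = model.segments["thigh_l"].length
    ls = model.segments["shank_l"].length
    lf = model.segments["foot_l"].length
    layout: dict[str, tuple[str, np.ndarray]] = {
        "SACR": ("pelvis", np.array([-0.08 * H / 1.7, 0.0, 0.02])),
        "LASI": ("pelvis", np.array([0.06 * H / 1.7, 0.10, 0.03])),
        "RASI": ("pelvis", np.array([0.06 * H / 1.7, -0.10, 0.03])),
        "C7": ("trunk_lumped", np.array([-0.05, 0.0, 0.42 * H / 1.7])),
        "STRN": ("trunk_lumped", np.array([0.08, 0.0, 0.30 * H / 1.7])),
        "CLAV": ("trunk_lumped", np.array([0.06, 0.0, 0.38 * H / 1.7])),
    }
    for side, sgn in (("L", +1.0), ("R", -1.0)):
        c = side.lower()
        layout[f"{side}THI"] = (f"thigh_{c}", np.array([0.03, sgn * 0.05, -0.45 * lt]))
        layout[f"{side}THA"] = (f"thigh_{c}", np.array([0.05, sgn * 0.02, -0.25 * lt]))
        layout[f"{side}KNE"] = (f"thigh_{c}", np.array([0.0, sgn * 0.06, -0.98 * lt]))
        layout[f"{side}TIB"] = (f"shank_{c}", np.array([0.02, sgn * 0.04, -0.45 * ls]))
        layout[f"{side}TIA"] = (f"shank_{c}", np.array([0.04, sgn * 0.01, -0.25 * ls]))
        layout[f"{side}ANK"] = (f"shank_{c}", np.array([0.0, sgn * 0.04, -0.98 * ls]))
        layout[f"{side}HEE"] = (f"foot_{c}", np.array([-0.22 * lf, 0.0, -0.02]))
        layout[f"{side}TOE"] = (f"foot_{c}", np.array([0.70 * lf, 0.0, -0.03]))
        layout[f"{side}MT5"] = (f"foot_{c}", np.array([0.35 * lf, sgn * -0.04, -0.03]))
    return layout


def _check_layout(model: BodyModel, layout) -> None:
    per_seg: dict[str, list[np.ndarray]] = {}
    for name, (seg, pos) in layout.items():
        if seg not in model.segments:
            raise ValueError(f"marker {name}: unknown parent segment {seg!r}")
        per_seg.setdefault(seg, []).append(np.asarray(pos, float))
    tracked = {j.child for j in model.joints if j.ndof > 0} | {"pelvis"}
    for seg in tracked:
        # the trunk is rigid with the pelvis, so their markers pool together
        group = per_seg.get(seg, [])
        if seg == "pelvis":
            group = group + per_seg.get("trunk_lumped", [])
        if seg == "trunk_lumped":
            continue
        pts = np.array(group) if group else np.zeros((0, 3))
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise ValueError(f"segment {seg} needs >= 3 non-collinear markers")


def generate_markers(model: BodyModel, traj: JointTrajectories,
                     layout: dict | None = None, noise_sd_m: float = 0.0,
                     seed: int = 0) -> MarkerSet:
    """Synthesize marker trajectories from segment poses.

    Marker world position = segment pose applied to the fixed local
    position, plus direction-isotropic Gaussian noise.  ``noise_sd_m``
    specifies the *mean 3-D perturbation distance* in metres (the same
    scale as the mean marker tracking error); the corresponding per-axis
    standard deviation is ``noise_sd_m * sqrt(pi/8)``.
    """
    layout = default_marker_layout(model) if layout is None else layout
    _check_layout(model, layout)
    pos, rot, *_ = forward_kinematics(model, traj.q)
    names = tuple(layout)
    parents = tuple(layout[k][0] for k in names)
    locals_ = np.array([layout[k][1] for k in names])
    world = np.stack([pos[p] + np.einsum("nij,j->ni", rot[p], l)
                      for p, l in zip(parents, locals_)], axis=1)
    if noise_sd_m > 0:
        rng = np.random.default_rng(seed)
        world = world + rng.standard_normal(world.shape) * (
            noise_sd_m * _SIGMA_PER_MEAN_DISTANCE)
    return MarkerSet(names, parents, locals_, world, traj.sample_rate)


def _model_markers(model: BodyModel, q: np.ndarray, parents, locals_) -> np.ndarray:
    pos, rot, *_ = forward_kinematics(model, np.atleast_2d(q))
    return np.stack([pos[p][0] + rot[p][0] @ l for p, l in zip(parents, locals_)])


def inverse_kinematics(markers: MarkerSet, model: BodyModel,
                       q0: np.ndarray | None = None, max_nfev: int = 100,
                       tol: float = 1e-12) -> JointTrajectories:
    """Recover generalized coordinates by per-frame marker least squares.

    Minimizes the sum of squared distances between measured and
    model-predicted markers (uniform weights) over all coordinates, warm
    started from the previous frame's solution.  Frames that fail to
    converge, or in which all markers of a moving segment are missing, are
    flagged in ``metadata['ik_flags']`` rather than silently filled.
    """
    for p in markers.parents:
        if p not in model.segments:
            raise ValueError(f"marker parent segment {p!r} not in model")
    n = markers.n_frames
    q = np.zeros((n, model.ndof))
    flags = np.zeros(n, dtype=bool)
    guess = np.zeros(model.ndof) if q0 is None else np.asarray(q0, float).copy()
    if q0 is None:
        # crude initialisation: put the pelvis at the pelvis-marker centroid
        pel = [i for i, p in enumerate(markers.parents) if p == "pelvis"]
        if pel:
            guess[0:3] = np.nanmean(markers.trajectories[0, pel], axis=0)
    missing = markers.missing()
    moving = {j.child for j in model.joints if j.ndof > 0} | {"pelvis"}

    for i in range(n):
        present = ~missing[i]
        lost_segment = False
        for seg in moving:
            grp = [k for k, p in enumerate(markers.parents)
                   if (p == seg or (seg == "pelvis" and p == "trunk_lumped"))]
            if grp and not present[[*grp]].any():
                lost_segment = True
        meas = markers.trajectories[i, present]
        parents = tuple(np.array(markers.parents)[present])
        locals_ = markers.local_positions[present]

        def residual(x):
            return (_model_markers(model, x, parents, locals_) - meas).ravel()

        sol = least_squares(residual, guess, method="lm", xtol=tol, ftol=tol,
                            gtol=tol, max_nfev=max_nfev)
        q[i] = sol.x
        flags[i] = lost_segment or not sol.success
        if not flags[i]:
            guess = sol.x.copy()
    time = np.arange(n) / markers.rate
    return JointTrajectories(time, q, model.coord_names, markers.rate,
                             {"source": "inverse_kinematics",
                              "ik_flags": flags})


def mean_marker_tracking_error(markers: MarkerSet, model: BodyModel,
                               q: np.ndarray) -> float:
    """Mean distance (m) between measured and model-reconstructed markers.

    Averaged over all frames and markers (missing entries excluded).
    """
    pos, rot, *_ = forward_kinematics(model, q)
    recon = np.stack([pos[p] + np.einsum("nij,j->ni", rot[p], l)
                      for p, l in zip(markers.parents, markers.local_positions)],
                     axis=1)
    d = np.linalg.norm(markers.trajectories - recon, axis=2)
    return float(np.nanmean(d))


def smooth_markers(markers: MarkerSet, cutoff: float = 6.0) -> MarkerSet:
    """Optional low-pass smoothing of marker trajectories (Butterworth, zero phase).

    A pragmatic stand-in for generalized cross-validated spline smoothing of
    noisy marker data; the cut-off plays the role of the smoothing
    parameter.
    """
    from .gait_stats import butterworth_filter
    smoothed = markers.trajectories.copy()
    flat = smoothed.reshape(markers.n_frames, -1)
    ok = ~np.isnan(flat).any(axis=0)
    flat[:, ok] = butterworth_filter(flat[:, ok], markers.rate, cutoff)
    return MarkerSet(markers.names, markers.parents, markers.local_positions,
                     smoothed, markers.rate, markers.units)
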