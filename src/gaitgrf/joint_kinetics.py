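"""Clinically reported joint moments from inverse dynamics.

Hip, knee and ankle intersegmental moments are computed by Newton-Euler
summation over the distal subtree, expressed about the joint centre, and
projected onto the proximal segment's axes (hip: pelvis frame, knee: thigh
frame, ankle: shank frame).  Internal-moment sign convention: extensor and
plantarflexor moments are positive in the sagittal plane; abductor moments
are positive in the frontal plane (side-symmetric).  All curves are
normalized to body mass (N m/kg).

The computation is a pure function of the kinematics and the external foot
wrenches: running it once with measured (ground-truth) and once with
predicted ground reactions quantifies how prediction errors propagate into
joint kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyModel
from .dynamics import SegmentKinematics, Wrench, _segment_loads
from . import gait_stats

__all__ = ["JointMomentCurves", "joint_moments", "moment_deltas"]

#: (joint, plane) -> (proximal segment giving the projection axes, axis
#: index in that frame, sign for the left side).  The frontal sign flips
#: with side so that abduction is positive bilaterally.
_PLANES = {
    ("hip", "sagittal"): ("pelvis", 1, +1.0, False),
    ("hip", "frontal"): ("pelvis", 0, -1.0, True),
    ("knee", "sagittal"): ("thigh", 1, -1.0, False),
    ("knee", "frontal"): ("thigh", 0, -1.0, True),
    ("ankle", "sagittal"): ("shank", 1, +1.0, False),
}


@dataclass
class JointMomentCurves:
    """Mass-normalized joint moment time series per joint/plane/side."""

    time: np.ndarray
    curves: dict[tuple[str, str, str], np.ndarray]  # (joint, plane, side) -> N m/kg
    source: str = "measured"

    def keys(self):
        return self.curves.keys()


def _distal_segments(model: BodyModel, joint_name: str) -> list[str]:
    children = {}
    for j in model.joints:
        children.setdefault(j.parent, []).append(j)
    root = model.joint_by_name(joint_name).child
    out, stack = [], [root]
    while stack:
        seg = stack.pop()
        out.append(seg)
        stack += [j.child for j in children.get(seg, [])]
    return out


def joint_moments(kin: SegmentKinematics, model: BodyModel,
                  external: dict[str, Wrench | None], body_mass: float,
                  source: str = "measured") -> JointMomentCurves:
    """Internal hip/knee/ankle moments in clinical conventions, per side.

    ``external`` maps each side to the ground reaction wrench applied to
    that foot (force ON the body, any reference point), or None for a swing
    trial segment.  The intersegmental moment at a joint equals the sum of
    the distal segments' inertial-minus-gravity loads minus the external
    wrench moments, all taken about the joint centre.
    """
    for side in ("left", "right"):
        if side not in external:
            raise ValueError(f"external wrench attribution missing for {side!r} foot")
    n = kin.n_frames
    loads = {name: _segment_loads(kin, name) for name in model.segments}
    curves: dict[tuple[str, str, str], np.ndarray] = {}
    for side in ("left", "right"):
        c = side[0]
        sgn_side = +1.0 if side == "left" else -1.0
        ext = external[side]
        for (joint, plane), (prox, axis_idx, sgn, side_flip) in _PLANES.items():
            jname = f"{joint}_{c}"
            jpoint = kin.pos[model.joint_by_name(jname).child]
            M = np.zeros((n, 3))
            for seg in _distal_segments(model, jname):
                f, nrot = loads[seg]
                M += np.cross(kin.com[seg] - jpoint, f) + nrot
            if ext is not None:
                F = np.broadcast_to(np.atleast_2d(ext.force), (n, 3))
                Mx = np.broadcast_to(np.atleast_2d(ext.moment), (n, 3))
                ref = np.broadcast_to(np.atleast_2d(ext.point), (n, 3))
                M = M - np.cross(ref - jpoint, F) - Mx
            prox_seg = "pelvis" if prox == "pelvis" else f"{prox}_{c}"
            axes = kin.rot[prox_seg][:, :, axis_idx]
            comp = np.einsum("ni,ni->n", axes, M)
            s = sgn * (sgn_side if side_flip else 1.0)
            curves[(joint, plane, side)] = s * comp / body_mass
    return JointMomentCurves(kin.time.copy(), curves, source)


def moment_deltas(measured: JointMomentCurves, predicted: JointMomentCurves,
                  events: dict[str, "gait_stats.GaitEvents"] | None = None
                  ) -> dict[tuple[str, str, str], "gait_stats.ComparisonMetrics"]:
    """Agreement metrics between measured- and predicted-based joint moments.

    If per-side gait events are given, each curve pair is first
    time-normalized over every complete ipsilateral gait cycle and the
    metrics averaged across cycles; otherwise the full overlapping series
    are compared directly.  Metric arithmetic defers to :mod:`gait_stats`.
    """
    if set(measured.curves) != set(predicted.curves):
        raise ValueError("measured and predicted curve sets differ")
    if len(measured.time) != len(predicted.time) or np.max(
            np.abs(measured.time - predicted.time)) > 1e-9:
        raise ValueError("measured and predicted curves are on different grids")
    out = {}
    for key in measured.curves:
        a, b = measured.curves[key], predicted.curves[key]
        if events is not None:
            side = key[2]
            cyc = events[side].cycles()
            if not cyc:
                raise ValueError(f"no complete gait cycle for {side} foot")
            per_cycle = []
            for (t0, t1) in cyc:
                an = gait_stats.time_normalize(a, measured.time, t0, t1)
                bn = gait_stats.time_normalize(b, predicted.time, t0, t1)
                per_cycle.append(gait_stats.compare_curves(an, bn))
            out[key] = _average_metrics(per_cycle)
        else:
            out[key] = gait_stats.compare_curves(a, b)
    return out


def _average_metrics(metrics) -> "gait_stats.ComparisonMetrics":
    if len(metrics) == 1:
        return metrics[0]
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in metrics]))
    r = mean("pcc")
    cat = gait_stats.pcc_category(r)
    flags = tuple(f for m in metrics for f in m.flags)
    return gait_stats.ComparisonMetrics(mean("rmsd_abs"), mean("rmsd_pct_max"),
                                        r, cat, mean("xcorr_max"),
                                        mean("xcorr_lag_pct"), flags)
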