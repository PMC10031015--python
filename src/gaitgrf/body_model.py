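"""Anthropometrically scaled articulated rigid-body model of the walking body.

The model is an 8-segment, pelvis-rooted tree: a pelvis carrying a lumped
trunk (trunk + head + arms, rigidly attached) and two legs, each with a
3-DoF ball-and-socket hip, a 1-DoF hinge knee and a 1-DoF hinge ankle
(talocrural).  An optional subtalar hinge can be enabled, in which case a
massless talus segment is inserted between shank and foot.  Segment masses,
lengths, centre-of-mass locations and radii of gyration are linear
fractions of total body mass and stature taken from the classical
anthropometric literature (Winter, *Biomechanics and Motor Control of Human
Movement*, 4th ed., Table 4.1, with head/arms/trunk lumped so the mass
fractions close to exactly 1).

Conventions (used throughout the package):

* Lab frame: X = walking (antero-posterior) direction, Y = medio-lateral
  (positive left), Z = vertical up.  Right-handed, SI units.
* In the neutral pose (all generalized coordinates zero) every segment
  frame is aligned with the lab frame, the pelvis origin sits at the
  mid-point between the hip joint centres, and both foot soles lie exactly
  on the floor plane z = 0.
* Hinge joints rotate about the segment-frame Y axis; ball joints use an
  intrinsic X-Y-Z Euler sequence (ab/adduction, flexion component,
  internal rotation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

GRAVITY = np.array([0.0, 0.0, -9.81])

__all__ = [
    "Anthropometrics",
    "Segment",
    "Joint",
    "BodyModel",
    "default_scaling_table",
    "build_scaled_model",
    "model_to_config",
    "model_from_config",
    "GRAVITY",
]


class ModelValidationError(ValueError):
    """Raised when anthropometrics or model invariants are violated."""


@dataclass(frozen=True)
class Anthropometrics:
    """Subject-level inputs for model scaling.

    Parameters
    ----------
    body_mass:
        Total body mass in kg.
    height:
        Stature in m.
    foot_length, foot_width:
        Foot sole dimensions in m.  Defaults scale with stature
        (0.152 * height and 0.35 * foot_length respectively).
    segment_lengths:
        Optional per-segment length overrides in m (keys as in the
        scaling table, e.g. ``"thigh"``).
    """

    body_mass: float
    height: float
    foot_length: float | None = None
    foot_width: float | None = None
    segment_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("body_mass", "height"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ModelValidationError(f"{name} must be strictly positive, got {v!r}")
        if self.foot_length is None:
            object.__setattr__(self, "foot_length", 0.152 * self.height)
        if self.foot_width is None:
            object.__setattr__(self, "foot_width", 0.40 * self.foot_length)
        for name in ("foot_length", "foot_width"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ModelValidationError(f"{name} must be strictly positive, got {v!r}")
        if not self.foot_width < self.foot_length:
            raise ModelValidationError(
                f"foot_width ({self.foot_width}) must be smaller than "
                f"foot_length ({self.foot_length})"
            )
        for key, v in self.segment_lengths.items():
            if not np.isfinite(v) or v <= 0:
                raise ModelValidationError(f"segment_lengths[{key!r}] must be positive")


@dataclass(frozen=True)
class Segment:
    """Rigid segment: mass, COM offset and inertia tensor in its own frame."""

    name: str
    mass: float
    com_offset: np.ndarray  # (3,) m, segment frame
    inertia: np.ndarray  # (3,3) kg m^2 about COM, segment frame
    length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "com_offset", np.asarray(self.com_offset, float))
        object.__setattr__(self, "inertia", np.asarray(self.inertia, float))
        if self.mass < 0:
            raise ModelValidationError(f"segment {self.name}: mass must be >= 0")
        I = self.inertia
        if not np.allclose(I, I.T, atol=1e-12):
            raise ModelValidationError(f"segment {self.name}: inertia not symmetric")
        eig = np.linalg.eigvalsh(I)
        if eig[0] < -1e-12:
            raise ModelValidationError(f"segment {self.name}: inertia not PSD")
        a, b, c = np.sort(eig)
        if c > a + b + 1e-12:
            raise ModelValidationError(
                f"segment {self.name}: principal moments violate triangle inequality"
            )


@dataclass(frozen=True)
class Joint:
    """Connection between a parent and child segment.

    ``kind`` is one of ``"ball"`` (3 DoF, intrinsic XYZ Euler), ``"hinge"``
    (1 DoF about ``axis``) or ``"fixed"`` (0 DoF, rigid attachment).  The
    floating base of the pelvis is implicit and not represented as a Joint.
    ``parent_offset`` locates the joint centre (= child frame origin) in
    the parent segment frame.
    """

    name: str
    kind: str
    parent: str
    child: str
    parent_offset: np.ndarray
    axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_offset", np.asarray(self.parent_offset, float))
        if self.kind not in ("ball", "hinge", "fixed"):
            raise ModelValidationError(f"joint {self.name}: unknown kind {self.kind!r}")
        if self.kind == "hinge":
            if self.axis is None:
                raise ModelValidationError(f"hinge joint {self.name} requires an axis")
            ax = np.asarray(self.axis, float)
            n = np.linalg.norm(ax)
            if not np.isclose(n, 1.0, atol=1e-9):
                raise ModelValidationError(f"joint {self.name}: hinge axis must be unit norm")
            object.__setattr__(self, "axis", ax)

    @property
    def ndof(self) -> int:
        return {"ball": 3, "hinge": 1, "fixed": 0}[self.kind]


@dataclass(frozen=True)
class BodyModel:
    """Scaled articulated model consumed by every downstream stage."""

    segments: dict[str, Segment]
    joints: tuple[Joint, ...]
    coord_names: tuple[str, ...]
    sole_outline: dict[str, dict[str, float]]  # side -> x_min,x_max,half_width,z (foot frame)
    hip_half_width: float
    ankle_height: float
    anthropometrics: Anthropometrics
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())

    def __post_init__(self) -> None:
        total = sum(s.mass for s in self.segments.values())
        if abs(total - self.anthropometrics.body_mass) > 1e-9 * self.anthropometrics.body_mass:
            raise ModelValidationError(
                f"segment masses sum to {total}, expected {self.anthropometrics.body_mass}"
            )
        if self.ndof != 6 + sum(j.ndof for j in self.joints):
            raise ModelValidationError("coordinate count inconsistent with joint DoFs")
        children = [j.child for j in self.joints]
        if len(set(children)) != len(children):
            raise ModelValidationError("a segment has more than one parent joint")
        non_root = set(self.segments) - {"pelvis"}
        if set(children) != non_root:
            raise ModelValidationError("every non-pelvis segment needs exactly one parent joint")
        for side in ("left", "right"):
            if side not in self.sole_outline:
                raise ModelValidationError(f"missing sole outline for {side} foot")

    @property
    def ndof(self) -> int:
        return len(self.coord_names)

    @property
    def body_mass(self) -> float:
        return self.anthropometrics.body_mass

    @property
    def body_weight(self) -> float:
        return self.anthropometrics.body_mass * 9.81

    def joint_by_name(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def coord_index(self, name: str) -> int:
        return self.coord_names.index(name)

    def foot_segment(self, side: str) -> str:
        return f"foot_{side[0]}"

    def neutral_pelvis_height(self) -> float:
        """Pelvis origin height in the neutral pose (soles exactly on floor)."""
        return (
            self.ankle_height
            + self.segments["thigh_l"].length
            + self.segments["shank_l"].length
        )


# --- scaling -----------------------------------------------------------------

#: Mass fractions of body mass, length fractions of stature, COM position
#: along the segment long axis (fraction of segment length from the proximal
#: joint) and transverse/longitudinal radii of gyration (fractions of segment
#: length about the COM), per Winter's anthropometric table.  ``trunk_lumped``
#: collects trunk + head + both arms; its mass fraction closes the sum to 1.
_WINTER_TABLE = {
    #                 mass     length   com     rg_t    rg_l
    "pelvis":       (0.142,    0.145,   0.35,   0.31,   0.31),
    "trunk_lumped": (0.536,    0.470,   0.45,   0.40,   0.25),
    "thigh":        (0.100,    0.245,   0.433,  0.323,  0.15),
    "shank":        (0.0465,   0.246,   0.433,  0.302,  0.12),
    "foot":         (0.0145,   0.152,   0.50,   0.475,  0.25),
}


def default_scaling_table() -> dict[str, dict[str, float]]:
    """Return the documented 8-segment mass/length fraction table.

    Keys are generic segment names (``thigh``/``shank``/``foot`` apply to
    both sides; their mass fraction is *per side*).  Mass fractions sum to
    exactly 1 over the 8 segments.
    """
    table = {}
    for name, (mf, lf, com, rgt, rgl) in _WINTER_TABLE.items():
        table[name] = {
            "mass_fraction": mf,
            "length_fraction": lf,
            "com_fraction": com,
            "rg_transverse": rgt,
            "rg_longitudinal": rgl,
        }
    return table


def _check_table(table: dict[str, dict[str, float]]) -> None:
    expected = set(_WINTER_TABLE)
    if set(table) != expected:
        raise ModelValidationError(
            f"scaling table must define segments {sorted(expected)}, got {sorted(table)}"
        )
    total = sum(
        table[n]["mass_fraction"] * (2 if n in ("thigh", "shank", "foot") else 1)
        for n in table
    )
    if abs(total - 1.0) > 1e-9:
        raise ModelValidationError(f"mass fractions must sum to 1, got {total}")


def _segment(name: str, key: str, mass: float, length: float, com: np.ndarray,
             rg_t: float, rg_l: float) -> Segment:
    # transverse axes X,Y; longitudinal axis Z for long segments.  The foot's
    # long axis is X; its inertia is permuted accordingly.
    it = mass * (rg_t * length) ** 2
    il = mass * (rg_l * length) ** 2
    if key == "foot":
        inertia = np.diag([il, it, it])
    else:
        inertia = np.diag([it, it, il])
    return Segment(name=name, mass=mass, com_offset=com, inertia=inertia, length=length)


def build_scaled_model(
    anthro: Anthropometrics,
    scaling_table: dict[str, dict[str, float]] | None = None,
    subtalar: bool = False,
) -> BodyModel:
    """Build the scaled 8-segment model from anthropometrics.

    Segment masses are ``mass_fraction * body_mass``; lengths are
    ``length_fraction * height`` unless overridden per segment; inertia
    entries scale as mass * length**2.
    """
    table = default_scaling_table() if scaling_table is None else scaling_table
    _check_table(table)
    M, H = anthro.body_mass, anthro.height

    def seg_length(key: str) -> float:
        if key in anthro.segment_lengths:
            return anthro.segment_lengths[key]
        if key == "foot":
            return anthro.foot_length
        return table[key]["length_fraction"] * H

    hip_half_width = 0.05 * H
    ankle_height = 0.039 * H
    foot_len = seg_length("foot")

    segments: dict[str, Segment] = {}
    for key in ("pelvis", "trunk_lumped"):
        t = table[key]
        L = seg_length(key)
        com = np.array([0.0, 0.0, t["com_fraction"] * L])
        segments[key] = _segment(key, key, t["mass_fraction"] * M, L, com,
                                 t["rg_transverse"], t["rg_longitudinal"])
    for key in ("thigh", "shank"):
        t = table[key]
        L = seg_length(key)
        com = np.array([0.0, 0.0, -t["com_fraction"] * L])
        for side in "lr":
            segments[f"{key}_{side}"] = _segment(f"{key}_{side}", key,
                                                 t["mass_fraction"] * M, L, com,
                                                 t["rg_transverse"], t["rg_longitudinal"])
    t = table["foot"]
    # foot frame origin at the ankle; the sole spans [-0.25, +0.75] segment
    # lengths fore-aft, at z = -ankle_height
    foot_com = np.array([(t["com_fraction"] - 0.25) * foot_len, 0.0, -0.5 * ankle_height])
    for side in "lr":
        segments[f"foot_{side}"] = _segment(f"foot_{side}", "foot",
                                            t["mass_fraction"] * M, foot_len, foot_com,
                                            t["rg_transverse"], t["rg_longitudinal"])

    joints: list[Joint] = [
        Joint("trunk", "fixed", "pelvis", "trunk_lumped",
              parent_offset=[0.0, 0.0, segments["pelvis"].length]),
    ]
    coord_names = ["pelvis_tx", "pelvis_ty", "pelvis_tz",
                   "pelvis_rx", "pelvis_ry", "pelvis_rz"]
    y_axis = np.array([0.0, 1.0, 0.0])
    x_axis = np.array([1.0, 0.0, 0.0])
    for side, sgn in (("l", +1.0), ("r", -1.0)):
        joints.append(Joint(f"hip_{side}", "ball", "pelvis", f"thigh_{side}",
                            parent_offset=[0.0, sgn * hip_half_width, 0.0]))
        coord_names += [f"hip_{side}_rx", f"hip_{side}_ry", f"hip_{side}_rz"]
        joints.append(Joint(f"knee_{side}", "hinge", f"thigh_{side}", f"shank_{side}",
                            parent_offset=[0.0, 0.0, -segments[f"thigh_{side}"].length],
                            axis=y_axis))
        coord_names.append(f"knee_{side}")
        if subtalar:
            talus = Segment(f"talus_{side}", 0.0, np.zeros(3), np.zeros((3, 3)), 0.0)
            segments[f"talus_{side}"] = talus
            joints.append(Joint(f"ankle_{side}", "hinge", f"shank_{side}", f"talus_{side}",
                                parent_offset=[0.0, 0.0, -segments[f"shank_{side}"].length],
                                axis=y_axis))
            coord_names.append(f"ankle_{side}")
            joints.append(Joint(f"subtalar_{side}", "hinge", f"talus_{side}", f"foot_{side}",
                                parent_offset=[0.0, 0.0, 0.0], axis=x_axis))
            coord_names.append(f"subtalar_{side}")
        else:
            joints.append(Joint(f"ankle_{side}", "hinge", f"shank_{side}", f"foot_{side}",
                                parent_offset=[0.0, 0.0, -segments[f"shank_{side}"].length],
                                axis=y_axis))
            coord_names.append(f"ankle_{side}")

    outline = {
        side: {
            "x_min": -0.25 * foot_len,
            "x_max": 0.75 * foot_len,
            "half_width": 0.5 * anthro.foot_width,
            "z": -ankle_height,
        }
        for side in ("left", "right")
    }
    return BodyModel(
        segments=segments,
        joints=tuple(joints),
        coord_names=tuple(coord_names),
        sole_outline=outline,
        hip_half_width=hip_half_width,
        ankle_height=ankle_height,
        anthropometrics=anthro,
    )


# --- plain-text config serialization ----------------------------------------

def model_to_config(model: BodyModel) -> str:
    """Serialize the model's defining inputs to a YAML config string."""
    a = model.anthropometrics
    cfg = {
        "anthropometrics": {
            "body_mass_kg": float(a.body_mass),
            "height_m": float(a.height),
            "foot_length_m": float(a.foot_length),
            "foot_width_m": float(a.foot_width),
            "segment_length_overrides_m": {k: float(v) for k, v in a.segment_lengths.items()},
        },
        "joints": {"subtalar_enabled": any(j.name.startswith("subtalar") for j in model.joints)},
    }
    return yaml.safe_dump(cfg, sort_keys=True)


_CONFIG_KEYS = {"anthropometrics", "joints"}
_ANTHRO_KEYS = {"body_mass_kg", "height_m", "foot_length_m", "foot_width_m",
                "segment_length_overrides_m"}


def model_from_config(text: str) -> BodyModel:
    """Rebuild a model from :func:`model_to_config` output (fail-fast schema)."""
    cfg = yaml.safe_load(io.StringIO(text))
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ModelValidationError(f"unknown config keys: {sorted(unknown)}")
    ac = cfg.get("anthropometrics", {})
    unknown = set(ac) - _ANTHRO_KEYS
    if unknown:
        raise ModelValidationError(f"unknown anthropometrics keys: {sorted(unknown)}")
    anthro = Anthropometrics(
        body_mass=ac["body_mass_kg"],
        height=ac["height_m"],
        foot_length=ac.get("foot_length_m"),
        foot_width=ac.get("foot_width_m"),
        segment_lengths=ac.get("segment_length_overrides_m", {}) or {},
    )
    subtalar = bool(cfg.get("joints", {}).get("subtalar_enabled", False))
    return build_scaled_model(anthro, subtalar=subtalar)


def cohort_mean_anthropometrics() -> Anthropometrics:
    """Cohort-mean subject used as the default synthetic study condition.

    Grand means over the five hemiplegic-gait subgroups of the emulated
    cohort: stature 1.47 m, mass 41.8 kg.
    """
    return Anthropometrics(body_mass=41.8, height=1.47)
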