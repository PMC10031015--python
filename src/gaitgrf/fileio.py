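"""Plain-text motion-capture file formats and the pipeline configuration.

Two classic tab-delimited dialects are supported:

* TRC for marker trajectories: two header lines (file type / metadata
  fields with the sampling rate and units), a column-header row naming each
  marker over its X/Y/Z triple, then one row per frame of ``Frame#  Time``
  followed by the marker coordinates.  Missing samples are written as empty
  fields and read back as NaN.
* MOT/STO for named time series (generalized coordinates, ground reaction
  wrenches, joint moments): a small key=value header terminated by
  ``endheader``, a units comment line, a column-name row starting with
  ``time``, then the data.

Both round-trip losslessly to well below 1e-9.  The pipeline configuration
is a flat YAML schema (units encoded in key names) with unknown keys
rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import yaml

from .body_model import Anthropometrics
from .marker_kinematics import MarkerSet

__all__ = [
    "write_trc", "read_trc",
    "write_mot", "read_mot",
    "TrialBundle", "PipelineConfig", "load_config", "dump_config",
]

_FMT = "%.17g"  # lossless float round-trip


# --- TRC ----------------------------------------------------------------------

def write_trc(path, markers: MarkerSet) -> None:
    n, m = markers.n_frames, markers.n_markers
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\n")
        fh.write(f"{markers.rate:g}\t{markers.rate:g}\t{n}\t{m}\t{markers.units}\n")
        head = ["Frame#", "Time"]
        for name in markers.names:
            head += [name, "", ""]
        fh.write("\t".join(head) + "\n")
        sub = ["", ""]
        for k in range(1, m + 1):
            sub += [f"X{k}", f"Y{k}", f"Z{k}"]
        fh.write("\t".join(sub) + "\n")
        for i in range(n):
            row = [str(i + 1), _FMT % (i / markers.rate)]
            for j in range(m):
                for c in range(3):
                    v = markers.trajectories[i, j, c]
                    row.append("" if np.isnan(v) else _FMT % v)
            fh.write("\t".join(row) + "\n")


def read_trc(path, model=None) -> MarkerSet:
    """Read a TRC file; marker parentage/local positions are unknown from
    file alone and set to placeholders unless a layout can be matched."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise ValueError("malformed TRC header (line 1)")
    fields = lines[1].split("\t")
    values = lines[2].split("\t")
    try:
        meta = dict(zip(fields, values))
        rate = float(meta["DataRate"])
        n = int(meta["NumFrames"])
        m = int(meta["NumMarkers"])
        units = meta.get("Units", "m")
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed TRC header (line 3): {exc}") from None
    names = [s for s in lines[3].split("\t")[2:] if s]
    if len(names) != m:
        raise ValueError(f"malformed TRC column header (line 4): "
                         f"{len(names)} names, expected {m}")
    traj = np.full((n, m, 3), np.nan)
    for i, line in enumerate(lines[5:5 + n]):
        cells = line.split("\t")[2:]
        for k, cell in enumerate(cells[:3 * m]):
            if cell.strip():
                traj[i, k // 3, k % 3] = float(cell)
    return MarkerSet(tuple(names), tuple("unknown" for _ in names),
                     np.zeros((m, 3)), traj, rate, units)


# --- MOT/STO ------------------------------------------------------------------

def write_mot(path, time: np.ndarray, columns: dict[str, np.ndarray],
              units: dict[str, str] | None = None, name: str = "gaitgrf") -> None:
    time = np.asarray(time, float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time column must be strictly increasing")
    cols = list(columns)
    units = units or {}
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={len(time)}\nnColumns={len(cols) + 1}\n")
        fh.write("inDegrees=no\n")
        fh.write("units=" + "\t".join(["s"] + [units.get(c, "1") for c in cols]) + "\n")
        fh.write("endheader\n")
        fh.write("\t".join(["time"] + cols) + "\n")
        data = np.column_stack([time] + [np.asarray(columns[c], float) for c in cols])
        for row in data:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


_KNOWN_UNITS = {"s", "1", "m", "rad", "deg", "N", "Nm", "N/kg", "Nm/kg", "m/s"}


def read_mot(path):
    """Read a MOT/STO file -> (time, columns dict, units dict)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = lines.index("endheader")
    except ValueError:
        raise ValueError("malformed MOT/STO file: no endheader line") from None
    units_line = next((l for l in lines[:end] if l.startswith("units=")), None)
    header = lines[end + 1].split("\t")
    if header[0] != "time":
        raise ValueError("first column must be 'time'")
    data = np.array([[float(v) for v in l.split("\t")]
                     for l in lines[end + 2:] if l.strip()])
    time = data[:, 0]
    if np.any(np.diff(time) <= 0):
        raise ValueError("non-monotonic time column")
    units = {}
    if units_line:
        tags = units_line[len("units="):].split("\t")
        for col, tag in zip(header, tags):
            if tag not in _KNOWN_UNITS:
                raise ValueError(f"unknown unit tag {tag!r} for column {col!r}")
            units[col] = tag
    columns = {c: data[:, k + 1] for k, c in enumerate(header[1:])}
    return time, columns, units


def grf_columns(wrench: dict, cop: dict) -> tuple[dict, dict]:
    """Per-foot GRF&M columns (force, CoP, free vertical moment) for MOT output."""
    cols, units = {}, {}
    for side in ("left", "right"):
        w = wrench[side]
        c = np.nan_to_num(cop[side])
        tz = w.moment[:, 2] - (c[:, 0] * w.force[:, 1] - c[:, 1] * w.force[:, 0])
        for k, ax in enumerate("xyz"):
            cols[f"{side}_force_{ax}"] = w.force[:, k]
            units[f"{side}_force_{ax}"] = "N"
            cols[f"{side}_cop_{ax}"] = cop[side][:, k] if cop[side].shape[1] == 3 else c[:, k]
            units[f"{side}_cop_{ax}"] = "m"
        cols[f"{side}_free_moment_z"] = tz
        units[f"{side}_free_moment_z"] = "Nm"
    return cols, units


def grf_wrenches_from_columns(columns: dict) -> dict:
    """Rebuild per-foot wrenches about the lab origin from GRF MOT columns."""
    from .dynamics import Wrench
    out = {}
    for side in ("left", "right"):
        F = np.stack([columns[f"{side}_force_{ax}"] for ax in "xyz"], axis=1)
        c = np.nan_to_num(
            np.stack([columns[f"{side}_cop_{ax}"] for ax in "xyz"], axis=1))
        M = np.cross(c, F)
        M[:, 2] += columns[f"{side}_free_moment_z"]
        out[side] = Wrench(F, M, np.zeros(3))
    return out


# --- configuration ------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat pipeline configuration with units in the key names."""

    body_mass_kg: float = 41.8
    height_m: float = 1.47
    foot_length_m: float | None = None
    foot_width_m: float | None = None
    pattern: str = "typical"
    affected_side: str = "right"
    cadence_steps_per_min: float = 112.5
    stride_length_m: float | None = None
    double_support_fraction: float = 0.10
    n_strides: int = 2
    sample_rate_hz: float = 150.0
    kinetic_rate_hz: float = 1500.0
    noise_sd_rad: float = 0.0
    marker_noise_m: float = 0.0
    seed: int = 0
    subtalar_enabled: bool = False
    # contact-model and recruitment parameters
    contact_z_lim_m: float = 0.03
    contact_v_lim_m_per_s: float = 0.8
    contact_n_max_n: float | None = None       # None -> 40% body weight
    friction_mu: float = 0.5
    joint_strength_nm_per_kg: float = 3.0
    residual_strength_fraction_bw: float = 0.01

    def anthropometrics(self) -> Anthropometrics:
        return Anthropometrics(self.body_mass_kg, self.height_m,
                               self.foot_length_m, self.foot_width_m)

    def strength_params(self):
        from .grf_prediction import StrengthProfileParams
        return StrengthProfileParams(z_lim=self.contact_z_lim_m,
                                     v_lim=self.contact_v_lim_m_per_s,
                                     n_max=self.contact_n_max_n,
                                     mu=self.friction_mu)

    def recruitment_settings(self):
        from .grf_prediction import RecruitmentSettings
        return RecruitmentSettings(
            joint_strength_per_mass=self.joint_strength_nm_per_kg,
            residual_force_fraction=self.residual_strength_fraction_bw,
            residual_moment_fraction=self.residual_strength_fraction_bw)


def load_config(path_or_text) -> PipelineConfig:
    import os
    s = str(path_or_text)
    text = open(s).read() if ("\n" not in s and os.path.exists(s)) else s
    cfg = yaml.safe_load(io.StringIO(text)) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**cfg)


def dump_config(cfg: PipelineConfig) -> str:
    d = {k: getattr(cfg, k) for k in PipelineConfig.__dataclass_fields__}
    return yaml.safe_dump(d, sort_keys=True)


@dataclass
class TrialBundle:
    """On-disk artifact set for one trial."""

    config: PipelineConfig
    trajectories_path: str
    grf_truth_path: str
    markers_path: str | None = None
    kinematic_rate_hz: float = 150.0
    kinetic_rate_hz: float = 1500.0
    units: str = "SI"
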