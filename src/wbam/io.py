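"""Readers and writers for the package's plain-text interchange formats.

* Segment kinematics CSV — long format with columns ``time_s, segment,
  px, py, pz[, wx, wy, wz]`` (positions in metres, angular velocity in
  rad/s).  The sample rate defaults to 120 Hz unless a leading comment
  line ``# sample_rate_hz: <value>`` is present.
* Vertical GRF CSV — ``time_s, fz`` (N), 1200 Hz unless the same header
  comment overrides it.
* TRC marker files — the standard mocap header; marker input is mapped
  to segments through an endpoint convention: markers named
  ``<Segment>_PROX`` and ``<Segment>_DIST`` give each segment's axis,
  the CoM sits at the tabulated proximal ratio along it, and the
  frontal-plane angular velocity comes from finite-differencing the
  axis angle in the lateral-vertical plane.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import SEGMENT_NAMES, SegmentInertial, build_body_model
from .kinematics import GaitTrial, SegmentKinematics, finite_difference

DEFAULT_KINEMATICS_RATE = 120.0
DEFAULT_GRF_RATE = 1200.0


def _read_commented_csv(path, default_rate: float) -> tuple[pd.DataFrame, float]:
    text = Path(path).read_text()
    rate = default_rate
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("sample_rate_hz"):
                rate = float(stripped.split(":", 1)[1])
        else:
            body_lines.append(line)
    frame = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    return frame, rate


def read_kinematics_csv(path) -> tuple[dict[str, SegmentKinematics], float]:
    """Load long-format segment kinematics; returns (segments, sample_rate)."""
    frame, rate = _read_commented_csv(path, DEFAULT_KINEMATICS_RATE)
    required = {"time_s", "segment", "px", "py", "pz"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"kinematics CSV missing columns: {sorted(missing)}")
    has_omega = {"wx", "wy", "wz"} <= set(frame.columns)
    segments = {}
    for name, sub in frame.groupby("segment", sort=False):
        sub = sub.sort_values("time_s")
        pos = sub[["px", "py", "pz"]].to_numpy(dtype=float)
        omega = sub[["wx", "wy", "wz"]].to_numpy(dtype=float) if has_omega else None
        segments[str(name)] = SegmentKinematics(
            com_position=pos, sample_rate=rate, angular_velocity=omega
        )
    return segments, rate


def write_kinematics_csv(path, segments: dict[str, SegmentKinematics]) -> None:
    rate = next(iter(segments.values())).sample_rate
    frames = []
    for name, kin in segments.items():
        n = len(kin)
        frame = pd.DataFrame(
            {
                "time_s": np.arange(n) / rate,
                "segment": name,
                "px": kin.com_position[:, 0],
                "py": kin.com_position[:, 1],
                "pz": kin.com_position[:, 2],
                "wx": kin.angular_velocity[:, 0],
                "wy": kin.angular_velocity[:, 1],
                "wz": kin.angular_velocity[:, 2],
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {rate}\n")
        out.to_csv(fh, index=False)


def read_grf_csv(path) -> tuple[np.ndarray, float]:
    """Load a vertical GRF series; returns (fz, sample_rate)."""
    frame, rate = _read_commented_csv(path, DEFAULT_GRF_RATE)
    if "fz" not in frame.columns:
        raise ValueError("GRF CSV needs an 'fz' column")
    return frame["fz"].to_numpy(dtype=float), rate


def write_grf_csv(path, fz: np.ndarray, rate: float = DEFAULT_GRF_RATE) -> None:
    fz = np.asarray(fz, dtype=float)
    frame = pd.DataFrame({"time_s": np.arange(len(fz)) / rate, "fz": fz})
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {rate}\n")
        frame.to_csv(fh, index=False)


def load_trial(
    kinematics_path,
    subject_mass: float,
    subject_height: float,
    walking_speed: float,
    paretic_side: str,
    grf_path=None,
    inertials: dict[str, SegmentInertial] | None = None,
) -> GaitTrial:
    """Assemble a :class:`GaitTrial` from CSV inputs.

    Segment inertial parameters default to the packaged anthropometric
    table scaled to the subject.
    """
    segments, _ = read_kinematics_csv(kinematics_path)
    if inertials is None:
        inertials = build_body_model(subject_mass, subject_height)
    grf = None
    grf_rate = DEFAULT_GRF_RATE
    if grf_path is not None:
        grf, grf_rate = read_grf_csv(grf_path)
    return GaitTrial(
        segments=segments,
        inertials=inertials,
        paretic_side=paretic_side,
        subject_mass=subject_mass,
        subject_height=subject_height,
        walking_speed=walking_speed,
        grf=grf,
        grf_rate=grf_rate,
    )


# ---------------------------------------------------------------------------
# TRC marker input (endpoint convention)
# ---------------------------------------------------------------------------

def read_trc(path) -> tuple[dict[str, np.ndarray], float]:
    """Parse a standard TRC marker file; returns ({marker: (T, 3)}, rate)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError("not a TRC file: too few header lines")
    meta = dict(zip(lines[1].split("\t"), lines[2].split("\t")))
    rate = float(meta.get("DataRate", DEFAULT_KINEMATICS_RATE))
    units = meta.get("Units", "m").strip()
    scale = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(units, 1.0)
    marker_row = lines[3].split("\t")
    markers = [m for m in marker_row[2:] if m.strip()]
    data_rows = [ln.split("\t") for ln in lines[5:] if ln.strip()]
    values = np.array(
        [[float(v) if v.strip() else np.nan for v in row[2 : 2 + 3 * len(markers)]]
         for row in data_rows]
    )
    out = {}
    for i, name in enumerate(markers):
        out[name.strip()] = values[:, 3 * i : 3 * i + 3] * scale
    return out, rate


def segments_from_trc_markers(
    markers: dict[str, np.ndarray],
    rate: float,
    inertials: dict[str, SegmentInertial],
) -> dict[str, SegmentKinematics]:
    """Endpoint-convention segment kinematics from ``*_PROX`` / ``*_DIST`` markers.

    Segment CoM = prox + com_offset * (dist - prox); the angular velocity
    about the anterior axis is the finite-differenced angle of the
    segment axis projected on the lateral-vertical plane.  Out-of-plane
    angular velocity components are not recoverable from two markers and
    are set to zero.
    """
    upper = {k.upper(): k for k in markers}
    segments = {}
    for name in SEGMENT_NAMES:
        key_p = f"{name}_PROX".upper()
        key_d = f"{name}_DIST".upper()
        if key_p not in upper or key_d not in upper:
            continue
        prox = markers[upper[key_p]]
        dist = markers[upper[key_d]]
        ratio = inertials[name].com_offset
        com = prox + ratio * (dist - prox)
        axis = dist - prox
        angle = np.unwrap(np.arctan2(axis[:, 2], axis[:, 1]))
        wx = finite_difference(angle[:, None], rate)[:, 0]
        omega = np.column_stack([wx, np.zeros_like(wx), np.zeros_like(wx)])
        segments[name] = SegmentKinematics(
            com_position=com, sample_rate=rate, angular_velocity=omega
        )
    if not segments:
        raise ValueError("no <Segment>_PROX/<Segment>_DIST marker pairs found")
    return segments
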