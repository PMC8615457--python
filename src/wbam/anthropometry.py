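"""Body segment inertial parameters for the 12-segment whole-body model.

The model comprises trunk, pelvis, and paretic (P-) / non-paretic (N-)
upper arms, forearms, thighs, shanks and feet — i.e. a head- and hand-less
walking model whose segment masses, centre-of-mass locations and radii of
gyration are obtained by scaling a packaged anthropometric table to a
subject's total body mass and stature.

Default scaling coefficients follow the adult regressions of Dumas,
Cheze & Verriest (2007, J. Biomech. 40:543-553), rounded to 2-3
significant figures; any other table with the same columns can be
supplied instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical segment labels of the 12-segment model, P = paretic side.
SEGMENT_NAMES: tuple[str, ...] = (
    "Trunk",
    "Pelvis",
    "P-upperarm",
    "P-forearm",
    "P-thigh",
    "P-shank",
    "P-foot",
    "N-upperarm",
    "N-forearm",
    "N-thigh",
    "N-shank",
    "N-foot",
)


@dataclass(frozen=True)
class SegmentInertial:
    """Inertial properties of one body segment.

    Parameters
    ----------
    name:
        One of :data:`SEGMENT_NAMES`.
    mass:
        Segment mass in kg (> 0).
    inertia_about_frontal_axis:
        Moment of inertia about the segment-frame axis parallel to the
        lab anterior-posterior axis, kg m^2 (>= 0).  Used directly for
        the spin term when no full tensor is given.
    com_offset:
        Centre-of-mass position as a fraction of segment length measured
        from the proximal endpoint (used by marker/endpoint input).
    inertia_tensor:
        Optional full 3x3 segment-frame inertia tensor, kg m^2.  When a
        segment's orientation time series is available the tensor is
        rotated into the lab frame sample by sample.
    """

    name: str
    mass: float
    inertia_about_frontal_axis: float
    com_offset: float = 0.5
    inertia_tensor: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"segment {self.name!r}: mass must be > 0")
        if self.inertia_about_frontal_axis < 0:
            raise ValueError(f"segment {self.name!r}: inertia must be >= 0")
        if self.inertia_tensor is not None:
            t = np.asarray(self.inertia_tensor, dtype=float)
            if t.shape != (3, 3):
                raise ValueError("inertia_tensor must be 3x3")
            object.__setattr__(self, "inertia_tensor", t)


def load_parameter_table(path: str | None = None) -> pd.DataFrame:
    """Load an anthropometric scaling table (packaged default if ``path`` is None).

    Columns: segment, mass_fraction (of body mass), length_fraction (of
    stature), com_ratio (proximal->distal), gyration_ratio_frontal
    (radius of gyration / segment length, about the anterior-posterior axis).
    """
    if path is None:
        ref = importlib.resources.files("wbam.data") / "segment_parameters.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {
        "segment",
        "mass_fraction",
        "length_fraction",
        "com_ratio",
        "gyration_ratio_frontal",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return table


def build_body_model(
    subject_mass: float,
    subject_height: float,
    table: pd.DataFrame | None = None,
) -> dict[str, SegmentInertial]:
    """Scale the anthropometric table to a subject.

    Segment mass is ``mass_fraction * subject_mass``; the frontal-axis
    moment of inertia is ``m * (gyration_ratio * L)^2`` with segment
    length ``L = length_fraction * subject_height``.

    Returns a dict keyed by segment name containing exactly the 12
    canonical segments.
    """
    if subject_mass <= 0 or subject_height <= 0:
        raise ValueError("subject mass and height must be positive")
    if table is None:
        table = load_parameter_table()
    table = table.set_index("segment")
    unknown = set(table.index) - set(SEGMENT_NAMES)
    if unknown:
        raise ValueError(f"unknown segment labels in table: {sorted(unknown)}")
    missing = set(SEGMENT_NAMES) - set(table.index)
    if missing:
        raise ValueError(f"parameter table lacks segments: {sorted(missing)}")
    model: dict[str, SegmentInertial] = {}
    for name in SEGMENT_NAMES:
        row = table.loc[name]
        mass = float(row["mass_fraction"]) * subject_mass
        length = float(row["length_fraction"]) * subject_height
        gyration = float(row["gyration_ratio_frontal"]) * length
        model[name] = SegmentInertial(
            name=name,
            mass=mass,
            inertia_about_frontal_axis=mass * gyration**2,
            com_offset=float(row["com_ratio"]),
        )
    return model
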