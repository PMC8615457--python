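"""Frontal-plane whole-body angular momentum (WBAM) from segment kinematics.

The quantity of interest is the angular momentum of the whole body about
its own centre of mass, summed over the 12 segments:

    L(t) = sum_i [ (r_i - r_com) x m_i (v_i - v_com) + I_i w_i ]

where r_i, v_i are the i-th segment's centre-of-mass position/velocity,
r_com, v_com the mass-weighted whole-body values, and I_i w_i the
segment's spin (local) angular momentum.  The frontal-plane component is
the projection on the anterior-posterior lab axis.  Lab frame convention:
right-handed, X anterior, Y to the subject's left, Z up.

The per-cycle summary statistic is the WBAM *range*: max - min over one
gait cycle (paretic foot contact to next paretic foot contact), after
time normalisation to 0-100% of the cycle and normalisation by body mass
x height x walking speed, which renders it dimensionless.  The sign
convention is positive toward the non-paretic side, so series of
right-paretic subjects are mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .anthropometry import SEGMENT_NAMES, SegmentInertial
from .filters import butterworth_lowpass

FRONTAL_AXIS = 0  # lab X (anterior-posterior)


class AlignmentError(ValueError):
    """Time series of mismatched lengths."""


class ModelIncompleteError(ValueError):
    """A required body segment is missing from the trial."""


class NoCycleError(ValueError):
    """No gait cycle could be delimited."""


@dataclass
class SegmentKinematics:
    """Centre-of-mass motion and angular velocity of one segment.

    ``com_velocity`` may be omitted, in which case it is derived from
    the positions by central finite differences at the sample rate.
    ``angular_velocity`` defaults to zero (pure translation).
    ``orientation`` (T x 3 x 3 rotation matrices, segment->lab) is only
    needed when the segment's full inertia tensor should be rotated into
    the lab frame for the spin term.
    """

    com_position: np.ndarray
    sample_rate: float = 120.0
    com_velocity: np.ndarray | None = None
    angular_velocity: np.ndarray | None = None
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.com_position = np.atleast_2d(np.asarray(self.com_position, dtype=float))
        n = self.com_position.shape[0]
        if n < 2 or self.com_position.shape[1] != 3:
            raise ValueError("com_position must be a (T>=2, 3) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.com_velocity is None:
            self.com_velocity = finite_difference(self.com_position, self.sample_rate)
        else:
            self.com_velocity = np.asarray(self.com_velocity, dtype=float)
        if self.angular_velocity is None:
            self.angular_velocity = np.zeros((n, 3))
        else:
            self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        for name in ("com_velocity", "angular_velocity"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise AlignmentError(f"{name} shape {arr.shape} != com_position {(n, 3)}")
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != (n, 3, 3):
                raise AlignmentError("orientation must be (T, 3, 3)")

    def __len__(self) -> int:
        return self.com_position.shape[0]


@dataclass
class GaitTrial:
    """One walking trial: segment kinematics plus subject metadata.

    ``grf`` is an optional vertical ground-reaction-force series (N) at
    ``grf_rate`` Hz used for paretic foot-contact detection.
    """

    segments: dict[str, SegmentKinematics]
    inertials: dict[str, SegmentInertial]
    paretic_side: str
    subject_mass: float
    subject_height: float
    walking_speed: float
    grf: np.ndarray | None = None
    grf_rate: float = 1200.0

    def __post_init__(self) -> None:
        if self.paretic_side not in ("left", "right"):
            raise ValueError("paretic_side must be 'left' or 'right'")
        if min(self.subject_mass, self.subject_height, self.walking_speed) <= 0:
            raise ValueError("subject mass, height and walking speed must be positive")
        lengths = {len(seg) for seg in self.segments.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"segments have differing lengths: {sorted(lengths)}")
        missing = set(self.segments) - set(self.inertials)
        if missing:
            raise ModelIncompleteError(f"no inertial parameters for: {sorted(missing)}")
        if self.grf is not None:
            self.grf = np.asarray(self.grf, dtype=float).ravel()

    @property
    def sample_rate(self) -> float:
        return next(iter(self.segments.values())).sample_rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.segments.values())))


@dataclass(frozen=True)
class WbamSeries:
    """Frontal WBAM over one time-normalised gait cycle (101 samples).

    Positive values point toward the non-paretic side.  ``normalized``
    marks division by body mass x height x walking speed (dimensionless);
    otherwise values are in kg m^2 / s.
    """

    values: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (101,):
            raise ValueError(f"a gait-cycle series has exactly 101 samples, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite WBAM values")
        object.__setattr__(self, "values", values)


def finite_difference(x: np.ndarray, fs: float) -> np.ndarray:
    """Central finite differences (one-sided at the ends) at rate ``fs``."""
    return np.gradient(np.asarray(x, dtype=float), 1.0 / fs, axis=0, edge_order=1)


def body_com(trial: GaitTrial) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted whole-body centre-of-mass position and velocity, (T, 3) each."""
    masses = np.array([trial.inertials[name].mass for name in trial.segments])
    pos = np.stack([trial.segments[name].com_position for name in trial.segments])
    vel = np.stack([trial.segments[name].com_velocity for name in trial.segments])
    total = masses.sum()
    weights = masses[:, None, None] / total
    return (weights * pos).sum(axis=0), (weights * vel).sum(axis=0)


def segment_angular_momentum(
    kin: SegmentKinematics,
    inertial: SegmentInertial,
    body_com_position: np.ndarray,
    body_com_velocity: np.ndarray,
) -> np.ndarray:
    """Angular momentum (T, 3) of one segment about the body centre of mass.

    Transfer term ``(r_i - r_com) x m (v_i - v_com)`` plus the spin term.
    The spin term uses, in order of preference: the full inertia tensor
    rotated by the segment's orientation series; the tensor as-is (segment
    frame assumed lab-aligned); or the scalar frontal-axis inertia applied
    isotropically.
    """
    body_com_position = np.asarray(body_com_position, dtype=float)
    body_com_velocity = np.asarray(body_com_velocity, dtype=float)
    n = len(kin)
    if body_com_position.shape != (n, 3) or body_com_velocity.shape != (n, 3):
        raise AlignmentError("body CoM series not aligned with segment series")
    rel_pos = kin.com_position - body_com_position
    rel_vel = kin.com_velocity - body_com_velocity
    transfer = np.cross(rel_pos, inertial.mass * rel_vel)
    w = kin.angular_velocity
    if inertial.inertia_tensor is not None:
        if kin.orientation is not None:
            rotation = kin.orientation
            lab_tensor = np.einsum("tij,jk,tlk->til", rotation, inertial.inertia_tensor, rotation)
            local = np.einsum("tij,tj->ti", lab_tensor, w)
        else:
            local = w @ inertial.inertia_tensor.T
    else:
        local = inertial.inertia_about_frontal_axis * w
    return transfer + local


def whole_body_angular_momentum(trial: GaitTrial, require_full: bool = True) -> np.ndarray:
    """Raw frontal WBAM series, kg m^2 / s, positive toward the non-paretic side.

    Sums each segment's angular momentum about the whole-body centre of
    mass and projects on the anterior-posterior axis.  With the lab Y
    axis pointing to the subject's left, the projection is mirrored for
    right-paretic subjects so that the positive direction is always the
    non-paretic side.

    ``require_full=False`` permits partial body models (test rigs,
    sensitivity studies); the default enforces all 12 segments.
    """
    if require_full:
        missing = set(SEGMENT_NAMES) - set(trial.segments)
        if missing:
            raise ModelIncompleteError(f"missing segments: {sorted(missing)}")
    com_pos, com_vel = body_com(trial)
    total = np.zeros((trial.n_samples, 3))
    for name, kin in trial.segments.items():
        total += segment_angular_momentum(kin, trial.inertials[name], com_pos, com_vel)
    frontal = total[:, FRONTAL_AXIS]
    if trial.paretic_side == "right":
        frontal = -frontal
    return frontal


def detect_paretic_contacts(trial: GaitTrial, threshold: float = 20.0) -> np.ndarray:
    """Paretic foot-contact sample indices (kinematics time base).

    With a vertical GRF series: rising edges through ``threshold`` N.
    Without one: local minima of the paretic foot's vertical CoM
    trajectory.  Consecutive indices delimit one gait cycle.
    """
    if trial.grf is not None:
        fz = trial.grf
        above = fz >= threshold
        edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
        ratio = trial.sample_rate / trial.grf_rate
        contacts = np.unique(np.round(edges * ratio).astype(int))
        contacts = contacts[contacts < trial.n_samples]
    else:
        foot = "P-foot" if "P-foot" in trial.segments else None
        if foot is None:
            raise NoCycleError("no GRF and no paretic foot segment for fallback detection")
        height = trial.segments[foot].com_position[:, 2]
        span = height.max() - height.min()
        if span <= 0:
            raise NoCycleError("flat foot-height trajectory; cannot detect contacts")
        contacts, _ = find_peaks(-height, prominence=0.1 * span)
    if len(contacts) == 0:
        raise NoCycleError("no paretic foot contact found")
    return np.asarray(contacts, dtype=int)


def time_normalize_cycle(series: np.ndarray, cycle_start: int, cycle_end: int) -> np.ndarray:
    """Linearly resample ``series[cycle_start:cycle_end]`` onto the 0..100% grid.

    Returns 101 samples with the endpoints preserved exactly.
    """
    series = np.asarray(series, dtype=float)
    if not 0 <= cycle_start < cycle_end < len(series):
        raise ValueError("cycle indices out of bounds")
    if cycle_end <= cycle_start + 1:
        raise ValueError("degenerate gait cycle: need at least 2 samples")
    grid = np.linspace(cycle_start, cycle_end, 101)
    out = np.interp(grid, np.arange(len(series)), series)
    out[0] = series[cycle_start]
    out[-1] = series[cycle_end]
    return out


def normalize_wbam(
    series: np.ndarray, mass: float, height: float, speed: float
) -> np.ndarray:
    """Divide raw WBAM by body mass (kg) x height (m) x walking speed (m/s)."""
    if min(mass, height, speed) <= 0:
        raise ValueError("mass, height and speed must all be positive")
    return np.asarray(series, dtype=float) / (mass * height * speed)


def wbam_range(series: np.ndarray | WbamSeries) -> float:
    """Max minus min of the frontal WBAM over one gait cycle (>= 0)."""
    if isinstance(series, WbamSeries):
        series = series.values
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to form a range")
    return float(series.max() - series.min())


@dataclass
class TrialResult:
    """Per-cycle outputs of :func:`analyze_trial`."""

    cycles: list[WbamSeries]
    ranges: list[float]
    contacts: np.ndarray
    raw_frontal: np.ndarray = field(repr=False, default=None)

    @property
    def mean_range(self) -> float:
        return float(np.mean(self.ranges))


def filter_trial(
    trial: GaitTrial, position_cutoff: float = 6.0, grf_cutoff: float = 80.0
) -> GaitTrial:
    """Low-pass the trial's marker-derived signals (zero-phase, 4th order).

    Segment CoM positions are smoothed at ``position_cutoff`` Hz and
    velocities re-derived by finite differences; the vertical GRF, when
    present, is smoothed at ``grf_cutoff`` Hz.  Angular velocities and
    orientations are passed through unchanged.
    """
    segments = {}
    for name, kin in trial.segments.items():
        pos = butterworth_lowpass(kin.com_position, kin.sample_rate, position_cutoff)
        segments[name] = SegmentKinematics(
            com_position=pos,
            sample_rate=kin.sample_rate,
            angular_velocity=kin.angular_velocity,
            orientation=kin.orientation,
        )
    grf = trial.grf
    if grf is not None:
        grf = butterworth_lowpass(grf, trial.grf_rate, grf_cutoff)
    return GaitTrial(
        segments=segments,
        inertials=trial.inertials,
        paretic_side=trial.paretic_side,
        subject_mass=trial.subject_mass,
        subject_height=trial.subject_height,
        walking_speed=trial.walking_speed,
        grf=grf,
        grf_rate=trial.grf_rate,
    )


def analyze_trial(
    trial: GaitTrial,
    lowpass: bool = True,
    position_cutoff: float = 6.0,
    grf_cutoff: float = 80.0,
    contact_threshold: float = 20.0,
    require_full: bool = True,
) -> TrialResult:
    """Full per-trial pipeline: filter, WBAM, cycles, normalise, range.

    Each pair of consecutive paretic foot contacts yields one
    time-normalised, dimensionless :class:`WbamSeries` and its range.
    """
    work = filter_trial(trial, position_cutoff, grf_cutoff) if lowpass else trial
    raw = whole_body_angular_momentum(work, require_full=require_full)
    contacts = detect_paretic_contacts(work, threshold=contact_threshold)
    if len(contacts) < 2:
        raise NoCycleError(f"need >= 2 paretic contacts, found {len(contacts)}")
    cycles: list[WbamSeries] = []
    ranges: list[float] = []
    for start, end in zip(contacts[:-1], contacts[1:]):
        cycle = time_normalize_cycle(raw, int(start), int(end))
        normalized = normalize_wbam(
            cycle, trial.subject_mass, trial.subject_height, trial.walking_speed
        )
        series = WbamSeries(values=normalized)
        cycles.append(series)
        ranges.append(wbam_range(series))
    return TrialResult(cycles=cycles, ranges=ranges, contacts=contacts, raw_frontal=raw)
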