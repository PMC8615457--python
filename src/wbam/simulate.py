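"""Seeded synthetic cohorts and gait trials.

Two generators stand in for the unreleased clinical data:

* :func:`generate_cohort` draws trial-level pre/post WBAM-range datasets
  from the same generative law the effect models assume — a per-patient
  pre-rehabilitation "bias" sets the scale of that patient's WBAM range,
  patient-level effect multipliers (optionally dispersed across patients)
  map pre to post, and Gaussian trial noise is added.  The drawn truths
  are returned as a ledger so parameter recovery can be scored.

* :func:`generate_synthetic_gait` builds segment-level sinusoidal gait
  kinematics whose frontal WBAM has an exactly evaluable analytic form,
  so the whole kinematics pipeline can be validated end to end.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .anthropometry import SEGMENT_NAMES, build_body_model
from .dataset import RangeDataset, RangeObservation
from .kinematics import GaitTrial, SegmentKinematics

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# cohort-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic pre/post cohort.

    Defaults mirror the trial that motivates the package: 8 patients per
    arm, 5 paired gait trials each, a treadmill effect near 1 (no change)
    and a feedback effect near -0.21 (a ~21% reduction).  Pre-range
    biases are log-normal spanning roughly 0.01-0.1 (dimensionless,
    mass-height-speed normalized WBAM range).  ``sigma_ct``/``sigma_af``
    disperse the effects across patients (0 = the non-hierarchical
    truth); ``sigma_obs`` is the trial-level noise s.d. of the post
    value; ``trial_noise`` spreads a patient's pre values
    multiplicatively around the bias.
    """

    n_af: int = 8
    n_ct: int = 8
    trials_per_patient: int | tuple[int, ...] = 5
    pre_bias_meanlog: float = math.log(0.0316)
    pre_bias_sdlog: float = 0.576
    true_beta_ct: float = 1.046
    true_beta_af: float = -0.209
    sigma_ct: float = 0.0
    sigma_af: float = 0.0
    sigma_obs: float = 0.005
    trial_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_af < 1 or self.n_ct < 1:
            raise ValueError("need at least one patient per arm")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be > 0")
        if min(self.sigma_ct, self.sigma_af) < 0 or self.trial_noise < 0:
            raise ValueError("dispersion parameters must be >= 0")

    def trials_for(self, k: int, n_patients: int) -> int:
        if isinstance(self.trials_per_patient, int):
            n = self.trials_per_patient
        else:
            if len(self.trials_per_patient) != n_patients:
                raise ValueError("per-patient trial list length mismatch")
            n = self.trials_per_patient[k]
        if n < 1:
            raise ValueError("each patient needs >= 1 trial")
        return n


def block_randomize(
    patient_ids: list[str],
    strata: dict[str, str] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Assign AF/CT balanced within strata (block size 2), seeded.

    Within every stratum the AF and CT counts differ by at most one.
    """
    if not patient_ids:
        raise ValueError("empty patient list")
    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list[str]] = {}
    for pid in patient_ids:
        by_stratum.setdefault(strata[pid] if strata else "all", []).append(pid)
    assignment: dict[str, str] = {}
    for stratum in sorted(by_stratum):
        ids = list(by_stratum[stratum])
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        for start in range(0, len(shuffled), 2):
            block = shuffled[start : start + 2]
            labels = ["AF", "CT"] if rng.random() < 0.5 else ["CT", "AF"]
            for pid, lab in zip(block, labels):
                assignment[pid] = lab
    return assignment


def generate_cohort(config: CohortConfig) -> tuple[RangeDataset, dict]:
    """Draw a synthetic pre/post cohort plus its truth ledger.

    Per patient j: bias b_j ~ LogNormal; per trial i: pre = b_j (1 + eps),
    eps ~ N(0, trial_noise); patient effects beta_CT,j ~ N(true_beta_ct,
    sigma_ct) and (AF arm) beta_AF,j ~ N(true_beta_af, sigma_af); then
    post = (beta_CT,j + g beta_AF,j) pre + N(0, sigma_obs), redrawing the
    rare noise realisations that would take a range negative (a range is
    non-negative by construction).
    """
    rng = np.random.default_rng(config.seed)
    patients = [("AF", f"AF-{k + 1:02d}") for k in range(config.n_af)]
    patients += [("CT", f"CT-{k + 1:02d}") for k in range(config.n_ct)]
    observations: list[RangeObservation] = []
    truth_patients = []
    for k, (group, pid) in enumerate(patients):
        n_trials = config.trials_for(k, len(patients))
        bias = float(rng.lognormal(config.pre_bias_meanlog, config.pre_bias_sdlog))
        beta_ct_j = float(rng.normal(config.true_beta_ct, config.sigma_ct))
        beta_af_j = (
            float(rng.normal(config.true_beta_af, config.sigma_af)) if group == "AF" else 0.0
        )
        multiplier = beta_ct_j + beta_af_j
        trials = []
        for i in range(1, n_trials + 1):
            pre = bias * (1.0 + config.trial_noise * rng.standard_normal())
            while pre <= 0:  # pragma: no cover - vanishing probability at defaults
                pre = bias * (1.0 + config.trial_noise * rng.standard_normal())
            post = multiplier * pre + config.sigma_obs * rng.standard_normal()
            while post < 0:
                post = multiplier * pre + config.sigma_obs * rng.standard_normal()
            observations.append(RangeObservation(pid, group, "pre", i, float(pre)))
            observations.append(RangeObservation(pid, group, "post", i, float(post)))
            trials.append({"trial": i, "pre": float(pre), "post": float(post)})
        truth_patients.append(
            {
                "patient_id": pid,
                "group": group,
                "bias": bias,
                "beta_ct_j": beta_ct_j,
                "beta_af_j": beta_af_j if group == "AF" else None,
                "trials": trials,
            }
        )
    truth = {"config": asdict(config), "patients": truth_patients}
    return RangeDataset(observations), truth


# ---------------------------------------------------------------------------
# gait-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentOscillation:
    """Sinusoidal frontal-plane motion of one segment's centre of mass.

    y(t) = y0 + amp_y cos(2 pi f t + phase)
    z(t) = z0 + amp_z sin(2 pi f t + phase)
    plus a spin about the anterior axis
    w_x(t) = spin_amp cos(2 pi f t + spin_phase).
    """

    amp_y: float = 0.0
    amp_z: float = 0.0
    freq: float = 1.0
    phase: float = 0.0
    spin_amp: float = 0.0
    spin_phase: float = 0.0


def default_gait_oscillations(cycle_duration: float) -> dict[str, SegmentOscillation]:
    """A mirror-symmetric limb oscillation set plus trunk/pelvis sway.

    The non-paretic limbs mirror the paretic ones (lateral amplitude and
    spin sign-flipped, vertical in phase), so at ``asymmetry_factor = 1``
    the limb contributions to the frontal WBAM cancel exactly and only
    the trunk/pelvis sway remains; scaling the paretic side breaks the
    mirror symmetry and widens the range, the way hemiplegic gait
    asymmetry does.
    """
    f = 1.0 / cycle_duration
    limbs = {
        "upperarm": SegmentOscillation(0.02, 0.01, f, math.pi),
        "forearm": SegmentOscillation(0.03, 0.015, f, math.pi),
        "thigh": SegmentOscillation(0.04, 0.02, f, 0.0),
        "shank": SegmentOscillation(0.05, 0.03, f, 0.2),
        "foot": SegmentOscillation(0.06, 0.04, f, 0.4, spin_amp=1.0),
    }
    out = {
        "Trunk": SegmentOscillation(0.02, 0.01, f, 0.0, spin_amp=0.5),
        "Pelvis": SegmentOscillation(0.03, 0.015, f, math.pi / 6),
    }
    for limb, osc in limbs.items():
        # paretic limbs carry the mirrored (negative-lateral) motion so that
        # scaling them up reinforces, rather than cancels, the trunk sway
        out[f"P-{limb}"] = SegmentOscillation(
            -osc.amp_y, osc.amp_z, osc.freq, osc.phase, -osc.spin_amp, osc.spin_phase
        )
        out[f"N-{limb}"] = osc
    return out


_BASE_HEIGHTS = {  # vertical CoM offsets as fractions of stature
    "Trunk": 0.70, "Pelvis": 0.55,
    "P-upperarm": 0.75, "P-forearm": 0.60, "P-thigh": 0.42,
    "P-shank": 0.20, "P-foot": 0.05,
    "N-upperarm": 0.75, "N-forearm": 0.60, "N-thigh": 0.42,
    "N-shank": 0.20, "N-foot": 0.05,
}
_BASE_LATERAL = {  # lateral offsets in metres, paretic on the left of the lab frame
    "Trunk": 0.0, "Pelvis": 0.0,
    "P-upperarm": 0.22, "P-forearm": 0.24, "P-thigh": 0.10,
    "P-shank": 0.10, "P-foot": 0.10,
    "N-upperarm": -0.22, "N-forearm": -0.24, "N-thigh": -0.10,
    "N-shank": -0.10, "N-foot": -0.10,
}


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Configuration of the synthetic gait trial.

    ``asymmetry_factor`` scales the paretic-side oscillation amplitudes
    (1 = symmetric); larger asymmetry widens the frontal WBAM range.
    """

    cycle_duration: float = 1.2
    n_cycles: int = 3
    sample_rate: float = 120.0
    grf_rate: float = 1200.0
    asymmetry_factor: float = 1.5
    subject_mass: float = 68.7
    subject_height: float = 1.69
    walking_speed: float = 1.0
    paretic_side: str = "left"
    oscillations: dict[str, SegmentOscillation] | None = None
    stance_fraction: float = 0.6
    grf_amplitude: float = 750.0
    lead_in: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_duration must be > 0 and n_cycles >= 1")
        max_freq = max(o.freq for o in self.resolved_oscillations().values())
        if self.sample_rate < 2.0 * max_freq:
            raise ValueError(
                f"sample rate {self.sample_rate} Hz below Nyquist for {max_freq} Hz oscillation"
            )

    def resolved_oscillations(self) -> dict[str, SegmentOscillation]:
        base = self.oscillations or default_gait_oscillations(self.cycle_duration)
        missing = set(SEGMENT_NAMES) - set(base)
        if missing:
            base = dict(base)
            for name in missing:
                base[name] = SegmentOscillation(freq=1.0 / self.cycle_duration)
        out = {}
        for name, osc in base.items():
            if name.startswith("P-"):
                osc = SegmentOscillation(
                    amp_y=osc.amp_y * self.asymmetry_factor,
                    amp_z=osc.amp_z * self.asymmetry_factor,
                    freq=osc.freq,
                    phase=osc.phase,
                    spin_amp=osc.spin_amp * self.asymmetry_factor,
                    spin_phase=osc.spin_phase,
                )
            out[name] = osc
        return out

    @property
    def duration(self) -> float:
        # one extra contact closes the last cycle
        return self.lead_in + (self.n_cycles + 0.5) * self.cycle_duration


def _analytic_segment_state(
    osc: SegmentOscillation, base_y: float, base_z: float, speed: float, t: np.ndarray
):
    """Exact position/velocity of one segment at times ``t`` (no differencing)."""
    arg = TWO_PI * osc.freq * t + osc.phase
    pos = np.column_stack(
        [
            speed * t,
            base_y + osc.amp_y * np.cos(arg),
            base_z + osc.amp_z * np.sin(arg),
        ]
    )
    w = TWO_PI * osc.freq
    vel = np.column_stack(
        [
            np.full_like(t, speed),
            -osc.amp_y * w * np.sin(arg),
            osc.amp_z * w * np.cos(arg),
        ]
    )
    spin = osc.spin_amp * np.cos(TWO_PI * osc.freq * t + osc.spin_phase)
    omega = np.column_stack([spin, np.zeros_like(t), np.zeros_like(t)])
    return pos, vel, omega


def analytic_frontal_wbam(config: SyntheticGaitConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form frontal WBAM of the synthetic trial at arbitrary times.

    Evaluates the defining sum directly from the analytic sinusoidal
    position/velocity expressions (continuous time, no sampling, no
    finite differences), with the same positive-toward-non-paretic sign
    convention as the pipeline.
    """
    t = np.asarray(t, dtype=float)
    inertials = build_body_model(config.subject_mass, config.subject_height)
    oscs = config.resolved_oscillations()
    masses = np.array([inertials[n].mass for n in SEGMENT_NAMES])
    states = [
        _analytic_segment_state(
            oscs[n],
            _BASE_LATERAL[n],
            _BASE_HEIGHTS[n] * config.subject_height,
            config.walking_speed,
            t,
        )
        for n in SEGMENT_NAMES
    ]
    pos = np.stack([s[0] for s in states])  # (12, T, 3)
    vel = np.stack([s[1] for s in states])
    total_mass = masses.sum()
    com_pos = np.einsum("s,stk->tk", masses, pos) / total_mass
    com_vel = np.einsum("s,stk->tk", masses, vel) / total_mass
    lx = np.zeros_like(t)
    for s, name in enumerate(SEGMENT_NAMES):
        dy = pos[s, :, 1] - com_pos[:, 1]
        dz = pos[s, :, 2] - com_pos[:, 2]
        dvy = vel[s, :, 1] - com_vel[:, 1]
        dvz = vel[s, :, 2] - com_vel[:, 2]
        lx += masses[s] * (dy * dvz - dz * dvy)
        lx += inertials[name].inertia_about_frontal_axis * states[s][2][:, 0]
    if config.paretic_side == "right":
        lx = -lx
    return lx


def analytic_wbam_range(config: SyntheticGaitConfig, resolution: int = 4001) -> float:
    """Dimensionless analytic range over one cycle on a dense grid."""
    t0 = config.lead_in
    t = np.linspace(t0, t0 + config.cycle_duration, resolution)
    lx = analytic_frontal_wbam(config, t)
    denom = config.subject_mass * config.subject_height * config.walking_speed
    return float((lx.max() - lx.min()) / denom)


def generate_synthetic_gait(config: SyntheticGaitConfig) -> tuple[GaitTrial, dict]:
    """Sample the synthetic trial and return it with its analytic truth.

    The trial carries exact analytic velocities and angular velocities
    (not finite differences) and a synthetic vertical GRF of square
    stance pulses whose rising edges mark the paretic foot contacts at
    ``lead_in + k * cycle_duration``.
    """
    n = int(round(config.duration * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate
    inertials = build_body_model(config.subject_mass, config.subject_height)
    oscs = config.resolved_oscillations()
    segments = {}
    for name in SEGMENT_NAMES:
        pos, vel, omega = _analytic_segment_state(
            oscs[name],
            _BASE_LATERAL[name],
            _BASE_HEIGHTS[name] * config.subject_height,
            config.walking_speed,
            t,
        )
        segments[name] = SegmentKinematics(
            com_position=pos,
            com_velocity=vel,
            angular_velocity=omega,
            sample_rate=config.sample_rate,
        )
    n_grf = int(round(config.duration * config.grf_rate)) + 1
    t_grf = np.arange(n_grf) / config.grf_rate
    phase = t_grf - config.lead_in
    in_stance = (phase >= 0) & (
        np.mod(phase, config.cycle_duration) < config.stance_fraction * config.cycle_duration
    ) & (phase < (config.n_cycles + 1) * config.cycle_duration)
    grf = np.where(in_stance, config.grf_amplitude, 0.0)
    trial = GaitTrial(
        segments=segments,
        inertials=inertials,
        paretic_side=config.paretic_side,
        subject_mass=config.subject_mass,
        subject_height=config.subject_height,
        walking_speed=config.walking_speed,
        grf=grf,
        grf_rate=config.grf_rate,
    )
    truth = {
        "analytic_range_dimensionless": analytic_wbam_range(config),
        "contact_times_s": [
            config.lead_in + k * config.cycle_duration for k in range(config.n_cycles + 1)
        ],
        "cycle_duration_s": config.cycle_duration,
    }
    return trial, truth
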