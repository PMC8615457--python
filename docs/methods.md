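# Methods

## Scope

`wbam` implements the analysis chain for gait-rehabilitation studies
that use the frontal-plane whole-body angular momentum (WBAM) range as
a dynamic-balance outcome, and that compare a treadmill-training control
arm (CT) against treadmill training plus an auditory plantar-pressure
biofeedback prosthesis (AF). The chain has three parts: the
biomechanical computation of the outcome from motion-capture
kinematics, a Bayesian comparison of four pre/post treatment-effect
models, and seeded synthetic-data generators that stand in for clinical
data, which are not publicly deposited for this study design.

## Whole-body angular momentum

The body is modelled as 12 rigid segments (trunk, pelvis, and paretic/
non-paretic upper arms, forearms, thighs, shanks, feet; head and hands
are excluded). The WBAM about the body's centre of mass is

    L(t) = Σᵢ [ (rᵢ − r_com) × mᵢ (vᵢ − v_com) + Iᵢ ωᵢ ],

the transfer term of each segment's CoM motion plus its spin (local)
term. Conventions fixed by the implementation, since sign tests need
them pinned down:

* Lab frame: right-handed, X anterior, Y to the subject's left, Z up.
  The frontal-plane WBAM is the X component.
* Sign: positive toward the non-paretic side. The X component is
  mirrored for right-paretic subjects so this holds universally.
* Body CoM: mass-weighted mean of segment CoMs.
* Spin term: if a segment carries a full inertia tensor and an
  orientation series, the tensor is rotated to the lab frame per sample
  (R I Rᵀ ω); with only a scalar frontal-axis inertia the spin term is
  I ωₓ, which is exact for the frontal component whenever the segment's
  products of inertia with the X axis vanish in the lab frame.
* Velocities: used as supplied; when absent, central finite differences
  of position at the sample rate (120 Hz by default).

Segment masses, CoM ratios, and radii of gyration come from a packaged
anthropometric table scaled by body mass and stature. The default
coefficients follow the adult regressions of Dumas, Chèze & Verriest
(2007), rounded to 2–3 significant figures; the table is a CSV the user
can replace wholesale. The 12 retained segments carry ≈ 92% of body
mass; the missing head/hand mass only enters through the body-CoM
weighting, a deliberate simplification of the head-less 12-segment
model.

Pre-processing and per-cycle reduction:

* Zero-phase Butterworth smoothing: a 4th-order design applied forward
  and backward (`scipy.signal.sosfiltfilt`), cutoffs 6 Hz for marker
  kinematics and 80 Hz for the vertical ground reaction force (GRF).
  The bidirectional pass squares the magnitude response, so the
  amplitude gain at the cutoff is 0.5, not 1/√2. This is asserted
  against the analytic |H(f)|² = 1/(1 + (f/fc)⁸) per pass.
* Gait cycles run from one paretic foot contact to the next. Contacts
  are rising edges of the vertical GRF through 20 N (a common gait-lab
  threshold); without force data, local minima of the paretic foot's
  vertical CoM trajectory are used as a kinematic fallback.
* Each cycle is linearly resampled onto a 0–100% grid (101 points),
  then divided by body mass × height × walking speed to make it
  dimensionless. The outcome is the per-cycle range, max − min, which
  is non-negative and shift-invariant by construction.

Marker-level input is supported through an endpoint convention only:
`<Segment>_PROX`/`<Segment>_DIST` marker pairs in a TRC file define the
segment axis; the CoM sits at the tabulated proximal ratio and the
frontal-plane angular velocity is the finite-differenced axis angle in
the lateral–vertical plane. Full 41-marker pose reconstruction is out
of scope: the WBAM needs only segment CoM states and angular
velocities.

## Statistical models

For each patient j and trial i, the post-rehabilitation range is a
multiple of the pre value plus Gaussian trial noise:

    post_{i,j} ~ Normal( β_eff · pre_{i,j}, σ ),
    β_eff = β_CT (+ β_AF in the AF arm).

The four models differ in which effect carries patient-level
individuality:

| model | treadmill effect | feedback effect |
|-------|------------------|-----------------|
| 1 | common β_CT | common β_AF |
| 2 | β_CT,j ~ N(μ_CT, σ_CT) | common β_AF |
| 3 | common β_CT | β_AF,j ~ N(μ_AF, σ_AF) |
| 4 | β_CT,j ~ N(μ_CT, σ_CT) | β_AF,j ~ N(μ_AF, σ_AF) |

Because the patient-level effects enter linearly in a Gaussian
likelihood, they integrate out in closed form. The package fits the
models directly on this marginalized likelihood (e.g. model 4:
post ~ N((μ_CT + g μ_AF) pre, √((σ_CT² + g σ_AF²) pre² + σ²)), with
g = 1 in the AF arm): the hyperparameter posterior is identical to the
full hierarchical posterior with patient effects integrated out
analytically, the sampling space stays 3–5 dimensional, and the
pointwise log likelihood needed for model comparison is exactly this
new-patient density. The conditional (patient-level) likelihood is
retained and tested against the marginal by Monte Carlo averaging and
by numeric quadrature.

Pairing: the models index pre and post by the same trial number, so the
i-th pre trial is paired with the i-th post trial in ascending order,
truncating to the smaller count with a logged warning. An alternative
`pre-mean` mode pairs every post trial against the patient's mean pre
value; both are explicit because trial alignment is a protocol detail
the data format does not encode.

Priors are non-informative uniforms. Effect-type parameters get
Uniform(−5, 5) — the post/pre multiplier of a two-week intervention is
physiologically far inside this box. Scale-type parameters get
Uniform(0, 10·sd(post)), a scale-aware cap resolved from the data at
fit time and recorded with the fit.

### Sampling

The posteriors are low-dimensional and unimodal, so the default sampler
is the affine-invariant ensemble sampler (emcee). A "chain" is an
independently seeded, independently initialised ensemble; defaults are
4 chains × 2000 steps (1000 warm-up) × 16 walkers, i.e. 64 000 retained
draws. Walkers start in a small ball around the per-group
least-squares-through-origin multipliers, with ball size matched to the
asymptotic posterior scale σ̂/√(Σ pre²) so that near-degenerate
(noise-free) posteriors are still reached. All seeding flows through
`numpy.random.SeedSequence`, making every fit a pure function of
(data, config).

Convergence is monitored with the split-chain Gelman–Rubin statistic,
computed per parameter across the flattened per-ensemble draws: each
chain is halved, and R̂ = √(var̂⁺/W) over the 2m half-chains. R̂ < 1.10
is the acceptance threshold; zero total variance returns 1.0 by
convention. A non-converged fit is returned but flagged, and
effect summaries refuse it unless forced.

### Model comparison

WAIC is computed from the (draws × observations) marginal log-likelihood
matrix: lppd by a stable log-sum-exp, p_waic as the ddof-1 posterior
variance of each observation's log likelihood, reported on the deviance
scale, WAIC = −2(lppd − p_waic), so lower is better. Using the
marginalized density means the criterion targets prediction for a *new*
patient, which is the clinically relevant question; a conditional-WAIC
variant can be obtained by passing the conditional pointwise matrix,
but is not the default. Only WAIC differences (dWAIC) and ranks are
comparable across implementations — absolute values depend on constant
factors in the pointwise density — so the reporting table carries
dWAIC from the best model, with ties broken by ascending model id.

### Effect reporting

All intervals are equal-tailed empirical percentiles (2.5/97.5) of the
posterior draws. The AF arm's combined effect is computed drawwise as
the sum of the treadmill and feedback effects (population means for
hierarchical models). The feedback effect is also reported as a percent
reduction, −100·β_AF drawwise. Predictive bands for a new patient pool
one predictive draw per posterior draw of the marginal normal (common
random numbers across the pre grid keep the curves smooth) and report
central 50%/95% bands; the mean line passes through the origin.

Cohen's d standardizes the between-arm contrast drawwise:
d_s = |ct_s − af_s| / √((sd_ct² + sd_af²)/2), with sd_* the posterior
standard deviations of each arm's total effect. The pooled terms are
standard deviations, not variances: the posterior effect scales here
are ~0.16–0.19, and only the s.d. reading produces effect sizes of the
conventional magnitude (d ≈ 1.2) for a mean contrast of ~0.21.

## Synthetic data generators

Neither generator is a fixture: both are first-class, tested library
code, and all generators are pure functions of (config, seed).

### Cohort generator

Emulates the trial-level dataset of a two-arm pre/post study. Defaults
are the study conditions the package targets: 8 patients per arm, 5
paired trials each, a treadmill effect of 1.046 and feedback effect of
−0.209 (the package's canonical effect sizes), trial noise σ = 0.005,
and no patient-level effect dispersion (σ_CT = σ_AF = 0, the
non-hierarchical truth; set them positive to generate from models 2–4).
Per-patient pre-rehabilitation "bias" is log-normal with median ≈ 0.032
and log-s.d. 0.576, spanning ≈ 0.01–0.1 — the order of magnitude of
mass·height·speed-normalized WBAM ranges. This span is an assumption:
published figures show the spread graphically without printing values.
Trial-level pre values spread multiplicatively (5% default) around the
bias, a feature visible in real per-trial scatter but absent from the
model equations; set it to 0 to match the equations exactly. Trial
noise realisations that would produce a negative range (physically
inadmissible, probability < 1e-4 per trial at defaults for all but the
smallest biases) are redrawn. The drawn truths — biases and per-patient
effects — are returned as a ledger, and written as a JSON sidecar by
the CLI and pipeline so recovery studies never parse logs.

Block randomization balances AF/CT within strata (blocks of 2, random
order per block), differing by at most one patient per stratum.

### Gait generator

Builds segment-level sinusoidal kinematics with exact analytic
velocities and angular velocities, so the pipeline's output can be
compared pointwise with an independently evaluated closed form (the
defining sum evaluated symbolically from the sinusoid expressions in
continuous time — no sampling, no finite differences). The default
oscillation set is mirror-symmetric in the limbs: the paretic side
carries the sign-flipped lateral motion, so at `asymmetry_factor = 1`
all limb contributions to the frontal WBAM cancel exactly and only the
trunk/pelvis sway remains; scaling the paretic amplitudes breaks the
mirror and monotonically widens the range, emulating hemiplegic
asymmetry. A synthetic vertical GRF of square stance pulses (750 N,
60% duty cycle, 1200 Hz) marks paretic contacts for the event detector.
The generator does not model double support, ground contact dynamics,
soft-tissue artefact or marker noise: passing its tests shows the
pipeline arithmetic is exact, not that event detection or filtering is
robust to real-world artefacts.

## Numerical and testing choices

* Replicated test studies (20 cohorts of parameter recovery; 20
  replicates of 4-model selection) run 4 chains × 800 steps (400
  warm-up) × 10 walkers, sizes chosen so each fit stays ~1 s while
  every fit still passes R̂ < 1.10; convergence is asserted inside the
  loops.
* The quadrature oracle for the marginal likelihood uses adaptive
  Gauss–Kronrod integration (`scipy.integrate.quad`, dblquad for the
  doubly hierarchical model over a ±8 s.d. box), agreeing to 1e-6.
* The WAIC oracle is a naive two-pass implementation; arviz provides a
  second, external cross-check (its p_waic uses the ddof-0 variance, so
  agreement is to O(1/draws)).
* Filter tests measure steady-state amplitude by least-squares sinusoid
  fitting over the middle half of a long record, avoiding edge
  transients.
* Degenerate inputs fail loudly: empty/singleton series, non-positive
  normalisation constants, σ ≤ 0, single chains, single draws, missing
  segments, datasets without an AF arm (the feedback effect is then
  unidentifiable), patients without both phases.

## Known limitations

* The anthropometric defaults are rounded literature values; studies
  needing exact published coefficients should supply their own table.
* The endpoint marker convention recovers only the frontal-plane
  angular velocity; out-of-plane spin of a segment is not observable
  from two markers and is set to zero.
* The pairing rule is a convention, not ground truth; if trial indices
  do not reflect a meaningful order, use the `pre-mean` mode.
* Absolute WAIC values are implementation-specific; only dWAIC and
  ranks should be compared across software.
* The synthetic cohort's pre-range scale and noise levels are
  assumptions calibrated to order-of-magnitude realism, not
  reproductions of any particular dataset.
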