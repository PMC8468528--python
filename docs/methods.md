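# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate conventions and the metric

All analysis happens in a shank-based frame: **X anterior, Y proximal
(along the pylon), Z to the subject's right**. The sagittal plane is X–Y
and the sagittal moment is the Z component, with plantarflexion — ground
reaction force anterior to the ankle — positive. A positive DMAMA is
therefore a signed anterior distance.

The quasi-static joint moment transports the sensed wrench from the
load-cell origin to a joint centre,

    M_joint = (r_joint→LC × F_sag)_z + M_z ,

where `r_joint→LC` points from the joint to the load cell and
`F_sag = (Fx, Fy, 0)`. Inertial terms are neglected; stance-phase shank
accelerations are small, so this is a second-order correction relative to
the measured wrench. The knee moment is computed the same way with the
knee lever arm; it takes no part in DMAMA but feeds the classifier's
channel set.

DMAMA is the ratio of the sagittal ankle-moment impulse to the magnitude
of the *vector* impulse of the sagittal force, `‖∫(Fx,Fy)dt‖` — not the
integral of the force magnitude. The two printed forms of the metric
(impulse ratio, and mean moment over mean force with the same time
weights) agree identically; a test asserts this. The prosthetic ankle
centre is a fixed physical point supplied through the geometry input; any
error in that point shifts DMAMA by a constant offset, which is why the
sensitivity analyses (slopes) are the robust quantities.

## Numerical integration

Load-cell sampling is nonuniform (about 150 Hz with heavy jitter), so all
impulses use the trapezoid rule on the measured sample times — second-order
accurate on nonuniform grids without inventing smoothness assumptions.
Integration runs over exactly `[HS, TO]`: interior samples at their
measured times plus channel values linearly interpolated at the two event
times. Without the interpolated endpoints, dropping a single near-threshold
edge sample costs up to ~0.3% of the force impulse at 150 Hz; with them the
end-to-end recovery error on noise-free synthetic sessions stays below
0.1% (asserted in the suite, reported by the acceptance script).

Strides whose sagittal force impulse falls below 1 N·s are flagged invalid
and excluded from statistics rather than raising.

## Event detection and segmentation

Stance is defined by the sagittal force magnitude `hypot(Fx, Fy)` exceeding
8% of body weight; the same threshold is used for heel strike and toe-off
(a symmetric, hysteresis-free rule). Event times are refined to sub-sample
precision by linear interpolation of the threshold crossing, except across
recording gaps (neighbour farther than the minimum swing time), where the
sample time itself is kept. Debouncing: sub-threshold dips shorter than
0.1 s are merged into the surrounding stance, and stances shorter than
0.2 s are discarded. These two durations are conventions chosen to
suppress sensor-noise chatter near the threshold; results are insensitive
to them on clean data. Stride mode labels come from the majority
per-sample annotation over the stance; a stance spanning a mode boundary,
or containing flagged transition samples, is excluded from all analyses.

## Frame calibration

Each calibration sample (a 3×3 rotation) is converted to its rotation
vector, the vectors are averaged element-wise, and the mean maps back
through the exponential map; the result is re-orthonormalised by polar
(SVD) projection to absorb floating-point drift. The angle branch is fixed
to `[0, π)`; samples within 1e-6 of π are rejected rather than silently
sign-flipped, because element-wise averaging is only meaningful on a
consistent branch and a physically mounted sensor never approaches a
half-turn misalignment. Offset vectors are arithmetic means. At the study
geometry (300 samples, ~1° orientation noise) the averaged rotation lands
within 0.5° of truth in essentially every replicate; the suite also checks
agreement with an independent chordal-mean (projected matrix mean) oracle
and that error shrinks with sample count.

## Synthetic gait sessions

The generator is first-class, tested code: it defines the conditions every
statistical claim in this package is evaluated under.

**Stride-level model.** Each stride draws a target DMAMA (percent foot
length) from

    target = β0_subject + β_stiff·code + β_incl·incline + β_int·code·incline + ε ,

with stiffness coded 0/1/2 (low/medium/high), incline −5/0/+5° for ramps
and level ground, stairs entering with a zero incline term (they
participate in mode labels and stiffness analyses only), and
ε ~ N(0, stride_noise_sd²). Defaults: slopes (3.01, 0.413, −0.145) — the
stiffness, incline and interaction sensitivities reported for this
protocol — stride noise 3 %FL, subject intercepts (10, 14, 8, 12) %FL,
4 subjects with body weights around 90 kg, one 0.24 m prosthetic foot.
Per-trial stride counts default to 50 level and 11 of each other mode,
the circuit yield of the study protocol.

**Waveforms.** Only the impulse ratio is constrained by the metric; the
waveform family is a modelling choice. Axial load is a two-peak profile
(`sin(πφ) + notch·sin(3πφ)` on a pedestal, smoothstep edges over 1% of
stance), shear is an S-shape with a mode-specific propulsive skew, and the
ankle moment is a late-peaking `sin²(πφ)(0.25+0.75φ)` envelope scaled so
that the trapezoidal impulse ratio over the stride's own samples equals
the drawn target exactly. Stairs use single-peak (negative-notch)
profiles and distinct accessory Mx/My channels so the five modes are
separable; separability is tunable through `MODE_SHAPES`. The load-cell
stream is produced by inverting the moment transfer
(`Mz_sensor = M_ankle − (r×F)_z`), rotating by the inverse of the true
mounting rotation, and adding white sensor noise.

**Sampling.** Per-sample rates are drawn from a normal (mean 149.9 Hz, SD
38.5 Hz) truncated below at 50 Hz — the truncation avoids non-physical
rates — and intervals are their reciprocals. Two samples are emitted at
the exact stance boundaries, where the waveforms are exactly zero; this
keeps the sampled piecewise-linear signal consistent with the target
impulse ratio under the exact-window integration downstream. Transition
strides are generated at every mode boundary with the label switching
mid-stance and are flagged.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and socket dynamics, footwear,
turning, speed variation, within-mode waveform variability beyond white
noise and duration jitter, IMU-based labelling error, load-cell bias or
drift, and any nonlinearity in the DMAMA response. Parameter-recovery
results validate the estimators under the stated generative model, not the
biomechanics.

## Locomotion-mode classification

Streams are linearly resampled to 100 Hz (classifier path only; DMAMA
always integrates raw timestamps). Nine channels (Fx, Fy, Fz, Mx, My, Mz,
ankle moment, knee moment, sagittal force magnitude) over a fixed-length
window ending at the toe-off sample yield 6 statistics each — mean, sample
SD, min, max, starting value, ending value — 54 features in a documented
channel-major order. The window's starting value is the first sample of
the *window* (the stance start is not used); the feature-selection stage
window defaults to 300 ms and is exposed as a parameter.

LDA uses a pooled within-class covariance blended with its own diagonal,
`(1−λ)S + λ·diag(S)`, λ chosen from {0, 0.01, 0.1} by the same
cross-validation (smallest λ wins ties); λ=0 reproduces classical LDA and
is verified against scikit-learn. Models are fitted per
(subject, stiffness) group — stiffness is known to a semi-active
controller — and scored by stratified 10-fold cross-validation with the
fold count reduced (with a warning) when a class has fewer members than
folds. Class imbalance is retained; no resampling. Forward selection adds
the feature minimising aggregated CV misclassification error, ties broken
by lowest column index, stopping at the first non-improving step (λ=0.01
during selection for numerical safety); window optimisation scans 100–500
ms in 33 ms increments, ties to the smallest window. With identical seeds
the whole chain is bit-reproducible.

## Sensitivity statistics

The subject-independent sensitivity is computed as described for this
protocol: per-subject condition means, then least squares with a common
slope and one fixed intercept per subject. This is the fixed-intercept
realisation of a mixed model with participants as random effects; a
per-stride random-intercept variant (statsmodels MixedLM, REML) is
provided as an option, with the means-based fit as the default because it
is the computation the headline numbers describe. Slope inference is a
Wald t-test at α = 0.05 with classical 95% intervals.

Cross-fit R² scores how well the pooled trend explains one subject's
strides: strides are adjusted by subtracting the subject's fitted
intercept offset relative to the grand (mean) intercept, predictions use
the grand-intercept line, and `R² = 1 − RSS/TSS` with TSS about the
subject's mean adjusted value. It is negative whenever the pooled trend
fits worse than that mean, and never exceeds the subject's own-fit R²
(least-squares optimality; asserted as an invariant).

The interaction analysis regresses per-stride DMAMA on
`[1, stiffness, incline, stiffness·incline]` over the three incline
conditions, stairs excluded. The parameter-recovery study for this fit
uses equal subject intercepts and 1 %FL stride noise: the regression
carries no subject terms, so between-subject intercept spread would
inflate residual variance and make the confidence intervals conservative
rather than nominal — the correctly specified experiment is the one that
measures coverage. The permutation-null check for the classifier likewise
uses balanced classes, where chance is exactly 20%.

## Problem sizes and reproducibility

Monte-Carlo suites use 100 replicates (50 in the faster unit-test
variants); classifier checks run on two-to-four-subject sessions at the
default stride counts. These sizes give stable coverage estimates while
keeping the full suite and the acceptance script in the tens of seconds.
All randomness flows from explicit seeds (`numpy.random.default_rng`;
stage seeds spawned via `SeedSequence`), every output artifact records the
seed and a configuration hash, and rerunning any stage with the same seed
is byte-identical.

## Known limitations

- The generator's waveform family is stylised; classifier accuracy on it
  (typically near-perfect) is a qualitative analogue of field performance,
  not a prediction of it.
- DMAMA offset bias from the choice of prosthetic ankle point is not
  modelled; only sensitivities are offset-free.
- The heel-strike criterion and debounce durations are conventions; real
  devices may need tuning for compliant floors or very slow gait.
- Subject-independent classification and frontal/transverse-plane moments
  are out of scope.
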