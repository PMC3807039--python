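# Methods

This note documents the models implemented in `cortexlimb`, the numerical
and design choices made where the problem was genuinely open, what the
synthetic data do and do not emulate, and the known limitations.

## Arm model and kinematics

The arm is a two-segment chain (upper arm `l1`, forearm `l2`; defaults
0.30 m and 0.26 m, estimated from markers as median segment distances when
not supplied) with four degrees of freedom: shoulder
adduction/abduction (θ1, rotation about x), extension/flexion (θ2, about
y), medial/lateral rotation (θ3, about the upper-arm axis z) and elbow
extension/flexion (θ4). The shoulder sits at the origin and the arm hangs
along −z at zero shoulder angles. θ4 is the *interior* elbow angle: π is
the straight arm, which makes the law-of-cosines inversion
`cos θ4 = (l1² + l2² − R²)/(2 l1 l2)` (R the shoulder–wrist distance)
hold on the principal arccos branch. The full transform chain is
`Ax(θ1) Ay(θ2) Az(θ3) Lz(l1) Ax(π − θ4) Lz(l2)`; the closed forms for the
elbow and wrist positions and the scalar inverse relations were derived
from this chain symbolically and are locked in by two independent tests:
agreement with an explicitly coded homogeneous-matrix product, and the
forward/inverse round-trip identity (< 1e−8 rad over 1000 random
postures).

Branch selection: θ1 by the two-argument arctangent `atan2(yE, −zE)` (the
branch of `tan θ1 = −yE/zE` that makes the round trip an identity), θ2
and θ3 by principal arcsin, θ4 by principal arccos. These branches are
correct on the restricted workspace θ2, θ3 ∈ (−π/2, π/2),
θ4 ∈ (0.05, π − 0.05), which the trajectory generator respects.
Numerics: |sin θ2| and |cos θ4| are clamped to 1 within 1e−6 (marker
noise) and rejected beyond; |sin θ4| < 1e−8 raises a
singular-configuration error because θ3 is then undefined.

Resampling between the 120 Hz marker rate, 256 Hz source rate and 1 kHz
EMG rate uses cubic-spline interpolation (exact on straight lines;
round-trip error for slow kinematic signals through the 120 Hz grid stays
below 1e−3, which linear interpolation cannot achieve at that rate).

## EMG processing

Raw EMG is rectified, averaged over a symmetric 5-ms window (rounded to
an odd sample count), low-pass filtered at 3 Hz (2nd-order Butterworth,
causal — the intended use is online decoding), and convolved with the
causal FIR sampling of the muscle-tension impulse response

    h(t) = 6.44 · (exp(−10.80 t) − exp(−16.52 t)),

truncated at the first tap past the peak below 1e−3 of the peak (about
0.6 s of taps). The resulting "quasi-tension" is a standard linear
approximation of muscle tension; it ignores length/velocity
nonlinearities and degrades for very fast contractions. The FIR's DC gain
is the tap sum (≈ 0.206 × rate, e.g. ≈ 206 at 1 kHz); it is reported by
`quasi_tension_dc_gain` and deliberately *not* rescaled away, because all
downstream use normalizes each channel by its training-set maximum.

## EEG preprocessing

Epochs span −1 s (baseline) to the trial end. Per channel: mean over
[−1, 0] s subtracted, 5th-order Butterworth filter, polyphase resampling
to 256 Hz (trimmed to `floor(seconds × 256)` samples). Filtering is
zero-phase by default (no systematic lag against kinematics when training
and evaluating); a causal mode exists for simulated online use. The
documented default band is 8–30 Hz; the synthetic-session decoding runs
use a pure 30 Hz low-pass instead — see "Decoding band" below.

## Hierarchical Bayesian source inverse

Observation model per sample: `E = G J + ξ`, noise precision β, prior
`P(J | α, β) ∝ exp(−β/2 · J′ diag(α) J)` — source precisions are
*relative* to the noise precision. ARD hierarchy: `α_i ~ Gamma` with mean
`α0_i = 1/v0_i` and degree of freedom `r0`; Jeffreys prior on β. The fMRI
map enters as `v0_i = vbase (1 + (m0 − 1) t̂_i²)` with `m0 = 100`,
`r0 = 10`. `vbase` (and the baseline noise variance that anchors the
relative units) is estimated from the −1.0…−0.5 s pre-movement interval
by maximizing the Gaussian evidence of `C = v G G′ + s I` over (v, s);
when `G G′` is near a multiple of the identity this split is a flat ridge
and the tie-break prefers the noise explanation, so source variance is
only claimed on evidence.

Inference is coordinate-ascent variational Bayes under the factorization
q(J) q(α) q(β): Gaussian updates for J (via the Woodbury identity, so
only sensor-sized systems are solved), conjugate Gamma updates for α and
β. The exact free energy is evaluated every iteration and is
non-decreasing (asserted in tests to 1e−9 relative); convergence is a
relative free-energy change below 1e−6 or 500 iterations (with a warning
and the last iterate on non-convergence). Artifact dipole columns (heart,
right shoulder/wrist, two eyes, two carotids, one spare) receive the
magnified prior variance `m0 · vbase` and are never exported in cortical
ROIs. If the sensor-space system's condition number exceeds 1e12, a
trace-scaled jitter of 1e−10 is added.

α is estimated once per training fold on (subsampled) task segments and
the filter is then fixed — decoding a trial is a single matrix product,
as required for real-time use.

## Sparse cortex-to-EMG regression

The cortico-muscular model is instantaneous at a fixed 17-ms delay
(rounded to 4 samples at 256 Hz). Per muscle, weights over the 33 M1
vertexes carry individual Gaussian precision hyperpriors optimized by
evidence maximization. The optimizer is greedy sequential sparse Bayesian
learning: from the empty model, the single add / delete / re-estimate
action that most increases the *size-penalized* exact marginal likelihood
`L − 0.5 ln(n) · |model|` is applied, interleaved with noise-variance
updates. The BIC-style penalty is essential: the unpenalized type-II
criterion admits any feature whose quality² exceeds its sparsity, which
at finite samples retains a spurious small weight for roughly a third of
the irrelevant candidates regardless of sample size. With the penalty,
noiseless recovery is exact (weight error < 1e−6) and support recovery at
SNR 10 succeeds in 20/20 seeded runs. A weight whose precision exceeds
1e9 × the smallest retained precision is pruned to exactly zero; the bias
is always kept. Regression runs at the source rate (256 Hz, where the
currents live); predictions are clipped at zero (quasi-tension is
non-negative; a diagnostic flag disables clipping) and upsampled to 1 kHz
for evaluation.

## Mixture-of-experts angle decoder

Two experts (one hidden layer, 20 tanh units, linear output — the
smallest size that passes the recovery tests; configurable) map the nine
filtered-EMG channels to the four angles; a linear gate on the scalar
summed-squared joint velocity produces softmax weights. The likelihood
is the Gaussian mixture over experts; the public `mixture_loglik` exposes
the bare-kernel form (perfect fit at unit gate weight gives lnL = 0),
while training uses the *normalized* Gaussian kernels: with per-expert
scales σ_i an unnormalized kernel lets a large-σ expert approach kernel 1
everywhere and absorb all responsibilities (observed as single-expert
takeover). σ_i starts at 1 and is updated each epoch as the
responsibility-weighted RMS residual of expert i (floor 0.05 in
standardized units).

Training is plain full-batch gradient ascent with fixed learning rate
(default 0.05 on standardized inputs/outputs) and seeded Gaussian
initialization (scale 0.1). Two schedule elements matter:

* **Expert-step preconditioning.** The raw expert gradient carries a
  1/σ_i² factor that grows without bound as an expert tightens and
  destabilizes fixed-step ascent; expert steps are scaled by σ_i² (a
  positive multiple of the same ascent direction — the
  responsibility-weighted least-squares gradient), making the step size
  σ-independent.
* **Warmup.** For the first 200 epochs each sample is hard-assigned to
  the expert preferred by the (frozen) gate prior, whose initial slopes
  are spread deterministically so the first expert is favored at low
  velocity (posture) and the last at high velocity (movement). Without
  this symmetry breaking the experts start interchangeable and neither
  specializes.

A kick-out-style restart (seeded weight perturbation of 1% of each
tensor's norm after 50 plateau epochs, best checkpoint retained) is a
surrogate for the cited restart procedure whose published details are
unavailable; it preserves the stated purpose — escaping local optima —
and can be disabled. Training is bitwise deterministic for a fixed seed.

The gate input at test time is a linear least-squares proxy from filtered
EMG to the summed-squared velocity, clipped at zero; the true velocity is
used only during training.

The monolithic comparison network receives the same information as the
whole mixture system (nine EMG channels plus the gate feature) with its
hidden size chosen to match the mixture's total parameter count, so the
comparison isolates the modular architecture rather than input access.

## Forward simulator

The generator defines the study conditions; all randomness flows through
one seeded generator and a manifest records the configuration hash and
seed.

* **Task.** Four sequences (Hold→C→A→B, Hold→C→D→B, Hold→D→B→A,
  Hold→D→C→A); 7 sets × 40 trials (10 per sequence, shuffled) at full
  scale. The decoded window is 4.503 s = 3 × (0.501-s reach + 1-s hold),
  with movement onset at t = 0 so the initial hold supplies the [−1, 0] s
  baseline; reach onsets carry up to 40 ms of uniform jitter. One trial
  therefore contributes round(4.503 × 1000) = 4503 samples, and the
  standard 60/10-trials-per-task split yields 1,080,720 training and
  180,120 test samples. Whether the printed window includes the initial
  hold is ambiguous; it is treated as the decoded task window and is
  configurable. Inter-trial rests (3–4 s) are generated but excluded from
  decoding.
* **Postures and reaches.** The five buttons are realized as joint
  postures on a frontal shell at ~70% arm extension; reaches are
  minimum-jerk in joint space between postures (a wrist-only
  minimum-jerk path would underdetermine the redundant 4-DOF chain), so
  markers are exact forward kinematics of the ground-truth angles.
* **Muscles.** Each muscle sums rectified joint-velocity (gain 0.35
  s/rad) and joint-excursion (gain 1.0 rad⁻¹) drives over the
  DOF/direction roles it serves per the measurement table, over a tonic
  co-contraction floor of 0.05. Excursions are measured from the hold
  posture, so holding the hold button yields exactly the floor, while
  other static postures remain distinguishable — without the excursion
  term, posture decoding from EMG would be information-theoretically
  impossible.
* **Surface EMG.** 20–450 Hz band-limited unit-variance carrier
  modulated by the activation plus white noise of standard deviation
  0.2/√SNR (tied to a fixed reference scale so quiet muscles keep a noise
  floor). Default SNR 10.
* **Cortical currents.** Each muscle's quasi-tension drive (normalized
  by the FIR DC gain to order 1), advanced by the 17-ms delay, is mixed
  onto its own 3 dedicated M1 vertexes with seeded positive weights —
  the delayed linear cortex-to-muscle model holds *exactly* by
  construction (`W_true J(t) = fEMG(t+δt)`). Non-driven vertexes carry
  8–30 Hz background at 5% of the nominal drive amplitude (a strongly
  task-locked activation regime, ~10 dB task-to-background at the
  sensors). Artifact sources: 1.2-Hz cardiac pulses, shared eye-blink
  transients, movement-locked shoulder/wrist activity, attenuated delayed
  carotid pulses. Sensor noise is white at SNR 10 against the clean
  cortical EEG.
* **Lead fields.** Full scale: an analytic three-concentric-sphere head
  model (radii 8.7/9.2/10.0 cm, conductivities 1 : 0.0125 : 1) solved
  per spherical-harmonic order as a small boundary-value linear system
  driven by the validated multipole expansion of the dipole potential;
  sources sit on an upper-hemisphere cortical shell with random
  orientations folded into the gain columns. Desk scale: a seeded random
  matrix with controlled condition number (default 100). Labeled vertex
  groups (M1, premotor and parietal analogs, All) are disjoint contiguous
  blocks; artifact columns are random with twice the mean cortical column
  norm. The fMRI prior is high (0.7–1.0) on M1, |N(0, 0.03)| elsewhere,
  normalized to maximum 1.

**Decoding band.** The synthetic cortical drive is a slow
(quasi-tension-like) signal. A drive strictly confined to 8–30 Hz could
not support an *instantaneous* linear map to the slow filtered EMG in any
synthetic world, so the pipeline's default decoding band for synthetic
sessions is a pure 30-Hz low-pass (baseline correction removes the
offset); the 8–30 Hz band remains the preprocessing default for
conventional sensorimotor-rhythm analyses.

**What the simulator does not emulate** — and hence what passing tests do
not show about real recordings: genuine cortical dynamics (oscillations
whose *amplitude*, not signed value, carries motor information),
realistic head geometry and per-subject lead-field error, fMRI-to-EEG
mis-registration, electrode impedance drift and motion artifacts in EMG,
muscle-model nonlinearity (a config flag for mild nonlinearity exists),
and inter-subject variability. Recovery here certifies the estimators
against their own model classes at realistic noise levels, not clinical
performance.

## Evaluation protocol

Set-level leave-one-out: train every stage on all-but-one set, decode the
held-out set; per-task mean (SD) of CC and range-normalized RMSE across
held-out trials, averaged across folds (the aggregation level of the
"mean (SD)" notation is a choice; per-trial values are retained in the
report). An audit records the trial ids consumed by each fold's training
stages and asserts disjointness from the held-out trials. EMG and angle
stages are both evaluated at 1 kHz after upsampling predictions.

The angle network trains on *both* the measured and the cortically
decoded filtered EMG of the training trials: at test time it only ever
sees decoded signals, and matching that input distribution (while keeping
the clean pairs) raises held-out angle CC substantially. The training
pairs are downsampled to 50 Hz (the angle trajectories are band-limited
well below that); prediction runs at 1 kHz.

**Problem sizes used in tests and the acceptance script.** Desk scale is
224 vertexes / 16 sensors / 2 sets, with 8 trials per set for unit tests
and 16 per set for the end-to-end recovery runs; the region-comparison
experiment uses 64 sensors because with 16 sensors every 33-vertex ROI's
reconstruction spans the whole sensor space and all regions are
mathematically tied — region separation requires fewer ROI vertexes than
sensors, which is the full-scale geometry (33 vs 64). VB variance
estimation subsamples the training task segments to ≤ 4000 time points.

## Known limitations

* The gate is linear in a single scalar feature; more than two experts
  are configurable but untested beyond the contract level.
* The sparse regression's Occam factor (0.5 ln n per weight) is a
  declared constant, appropriate for the n ≫ p regimes used here; in
  p ≈ n regimes it would need re-examination.
* The sphere head model omits anisotropy and realistic skull geometry;
  it exists to give the inverse problem physically plausible structure,
  not to model a particular head.
* Baseline-variance estimation assumes spatially white sensor noise.
* The velocity proxy is linear; strongly nonlinear EMG-velocity
  relations would degrade the gate at test time.
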