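# Methods

This note documents the models, conventions, and numerical choices behind
`emgkin`, and what the synthetic evaluation does and does not establish.

## Signal conditioning

EMG (7 bipolar channels, 2048 Hz) is band-pass filtered with a 2nd-order
Butterworth, 10–450 Hz, then resampled to the 1024 Hz working rate by an
anti-alias low-pass (6th-order Butterworth at 0.9 × the target Nyquist)
and 2:1 decimation. Filtering is **causal by default** — the pipeline
models an online-capable prosthesis controller, where zero-phase filtering
is unavailable — with a `zero_phase` flag for offline use. Low-pass stages
initialize the filter state to the steady-state response of each row's
first sample, suppressing startup transients on signals with a baseline.
Only integer resampling ratios are supported; anything else raises rather
than silently interpolating.

A note on an invariant one might expect: band-pass-then-decimate and
decimate-then-band-pass agree to <1% RMS only for content well inside the
band. Near the 450 Hz edge the bilinear designs at 2048 vs 1024 Hz warp
differently (≈2% gain difference at 250 Hz, ≈10% at 350 Hz), so the
commutation property is only asserted for mid-band content.

Stream synchronization uses the shared 20 Hz ±5 V square wave recorded by
both acquisition systems. Rising edges are detected by hysteresis
thresholding at 30%/70% of the trace's amplitude range (scale- and
offset-invariant); the offset between the first rising edges, converted to
each stream's own sample units, is removed from the stream starts. Edge
quantization bounds the residual misalignment by about one kinematic
sample (≈4 ms), negligible against the 100 ms analysis window.

## TDAR features

Per channel and 100 ms window (60 ms overlap → 40 ms step): MAV, MAV
slope, zero crossings, slope sign changes, and 6 autoregressive
coefficients — 70 features per window. At 1024 Hz neither window nor step
is integral; the window is floored to 102 samples and the step rounded to
41, fixed constants for reproducibility.

- **MAVS** is the difference of MAV between consecutive analysis windows
  (the final window carries 0). The alternative intra-window-segment
  definition is not implemented; with one feature vector per window the
  across-window difference is the natural reading.
- **ZC/SSC dead zone**: counts require the relevant amplitude steps to
  exceed `eps_amp`, by default 1% of the channel RMS of the recording
  being processed. (A training-set-derived threshold would need split
  information that does not exist at extraction time; at 1% of RMS the
  difference is immaterial.)
- **LMS-AR**: predictor x̂[n] = Σ a_k x[n−k], order 6, adapted from zero
  over the unit-variance-normalized window. Defaults: step size 0.002,
  8 passes. The step size trades convergence speed against steady-state
  misadjustment; these defaults put long-window estimates (n ≈ 2048)
  within 0.1 of the true coefficients of a synthetic AR(2) process across
  RNG seeds, which a faster/noisier setting (e.g. 0.01 × 3 passes) does
  not reliably achieve. On 102-sample windows adaptation is partial; the
  coefficients then act as relative spectral-shape summaries, which is all
  the downstream regressor consumes. Divergence (coefficient norm above a
  bound) raises with a suggestion to reduce the step.

## Wrist angles from markers

Origin O = midpoint(STR, STU); E = midpoint(MEP, LEP); z = unit(E−O)
(proximal); x = unit Gram–Schmidt of (STR−STU) against z; y = z × x.
H = midpoint(RMC, UMC), with H_z taken along the *distal* direction −z so
it is positive for any physiological pose. α₁/α₂ use plain `atan` (the
stated ±90° ranges make a quadrant-aware variant unnecessary); at the
H_z ≈ 0 singularity the angle is clipped to ±90°. α₃ is the unsigned angle
between STR−STU and LEP−MEP, 0–180°, 90° neutral.

**Side convention.** Mirrored bilateral motion must read identical angles
on both arms, but a sagittal mirror flips frame handedness: no strictly
right-handed frame with x lateral on both sides can make α₁ *and* α₂
mirror-equal. The frame here stays right-handed (x is lateral on both
sides because the styloid pair itself mirrors; y = z × x is anterior on
the right, posterior on the left), and the flexion component H_y is read
along the side-aware palmar direction s·y with s = +1 (right) / −1 (left).
This keeps the orthonormal right-handed frame invariant, matches the
stated positive directions on the right arm, and makes bilateral mirrored
motion bilaterally equal — the property contralateral training requires.

Angles are computed per frame from raw markers and filtered afterwards
(6 Hz 2nd-order Butterworth on the angle traces, then linear upsampling
256 → 1024 Hz). Marker gaps up to 0.25 s are linearly interpolated per
coordinate; frames in longer gaps are invalid, and any analysis window
touching an invalid sample is dropped jointly from features and targets.
Regression targets are per-window arithmetic means of each angle.

## Regression

Three MLPs, one per DoF: 70 inputs → 3 tanh hidden units → linear output.
Inputs are z-scored with training-set statistics (zero-variance columns
fall back to unit scale); targets stay in degrees. Training uses
full-batch L-BFGS (scikit-learn `MLPRegressor`, `max_iter=400`,
`alpha=1e-4`), deterministic given the seed; for a 3-hidden-unit
regression this converges in seconds and removes the stochasticity and
tail-holdout bookkeeping a gradient/early-stopping scheme would add. The
trained weights are copied into a plain-array model used for prediction
and JSON serialization, so inference does not depend on the training
backend. Constant-target runs produce a degenerate constant predictor and
are flagged (R² is undefined there).

**Cross-validation.** Per run, windows are split into 5 contiguous blocks
(sizes within 1), and a seeded permutation assigns blocks to folds; fold i
tests one block of every run and trains on the rest. "Randomly selected
4/5 of the data" is thus implemented block-wise, not window-wise: with 60%
window overlap, window-wise sampling would put near-duplicates of test
windows into training. Training additionally drops a guard band of 2
windows at each test-block boundary (the windows whose 102-sample span
overlaps the test span), so train and test sample spans are disjoint.

**Scenarios.** DoF12 uses runs 1–2, DoF13 runs 3–4, DoF23 runs 5–6,
DoF123 all seven; each scenario evaluates only its articulated DoFs (the
held DoF of a run pair has essentially zero variance on its own). Training
uses one position's fold-training blocks, or — for positional pooling —
the concatenation over all three positions. Intra-position tests are the
fold's test blocks at the training position; inter-position tests are all
windows of the scenario's runs at each other position. Pooled models are
tested on each position's fold test blocks (the pooled training saw 4/5
of every position, so full-run testing would leak).

## Evaluation

The multivariate R² pools squared errors and target variances over the
scenario's DoFs before forming a single ratio — not a mean of per-DoF
R² — which keeps the index stable when one DoF's excursion is small.
Internally a fraction, reported as a percentage.

Inter-position entries are normalized by the fold-matched intra-position
baseline (same scenario, training position, fold) — the strictest
reproducible pairing; the summary tables aggregate normalized cells over
folds into per-scenario 3×3 training × testing matrices (diagonal 1 by
construction). Pooling is assessed with a one-tailed paired t test
(pooled > single) across matched (training position, testing position,
fold) triples per scenario; a zero-variance positive difference is
reported as p = 0. The two-way ANOVA over subject groups that a
multi-subject study would run downstream consumes these normalized tables
but is outside this pipeline's scope.

## Synthetic sessions

The generator emulates the recording protocol: 3 arm positions × 7 runs ×
2 sides; each run ~65 s by default (1–2 s neutral→extreme→neutral
half-cycles, drawn per cycle); runs 1–6 articulate one DoF sinusoidally
with the partner DoF held at 90% of its range, run 7 cycles all three.
Default amplitudes: ±60° for DoF1/DoF2 and 90° ± 60° for α₃ — inside the
stated physiological ranges.

Markers come from a rigid-segment forward model (upper arm 300 mm, forearm
260 mm, hand 80 mm; styloid/epicondyle/metacarpal pair widths 50/70/70 mm)
that embeds the scripted angles exactly, so angle reconstruction is an
identity to floating-point precision in the noiseless case; isotropic
Gaussian marker noise (default σ = 0.5 mm, the motion-capture calibration
error scale) propagates to <1° RMS angle error. Arm positions apply rigid
global poses only — the wrist angles are invariant to them by
construction, as Eqs above are to any rigid motion.

EMG is amplitude-modulated band-limited noise: per channel, envelope =
noise floor + gains · rectified normalized excursions in the six DoF
half-directions, times a unit-variance 20–350 Hz Gaussian carrier at
2048 Hz. The default 7×6 gain matrix gives each half-direction one
dominant channel plus cross-talk, with a seventh mixed channel. This
reproduces envelope and gross spectral statistics — sufficient for a
pipeline that consumes only windowed features — and deliberately omits
motor-unit physiology, fatigue, and soft-tissue artifacts, so passing
tests certify the pipeline's correctness and sensitivity, not clinical
performance on real EMG.

**Position effect.** Each position applies a multiplicative channel-gain
vector exp(σ_g · v_pos) and an additive baseline σ_b·|w_pos|. The three
patterns v_pos are mutually orthogonal directions of a seeded random
orthonormal basis (scaled so per-channel log-gain std ≈ σ_g): the
perturbation *magnitude* between any two positions is then set
deterministically by σ_g while its direction across channels stays random.
An i.i.d. draw per position would make the pairwise effect itself random —
occasionally near zero — defeating a controllable knob. With σ_g = 0 the
generator is position-invariant and intra ≈ inter (null control); with
σ_g = 0.3 the pipeline shows the expected orderings (intra > inter,
normalized inter < 1, pooling recovers most of the gap). Because the
effect direction is random relative to each scenario's informative
channels, an occasional scenario × position-pair cell at an arbitrary seed
may show little degradation; the fixed-seed test suite and the reported
aggregate orderings are the calibrated claims.

In amputee mode the control side's gain matrix is blended 50% toward its
channel mean (reduced channel specificity of a stump recording); targets
always come from the contralateral side, as in contralateral training.

## Problem sizes and determinism

End-to-end tests and the acceptance script use 16 s runs (≈ 397 analysis
windows per run) instead of the protocol's 65 s (1621 windows): the fold
structure, guard bands, and all tested orderings are unchanged, and the
full grid (4 scenarios × [3 single + pooled] × 5 folds, 240 entries)
computes in well under a minute per session. Every random choice — run
scripting, marker noise, carriers, position patterns, fold assignment, MLP
initialization — derives from one master seed through independent seed
sequences, so a (config, manifest) pair reproduces the grid bit for bit;
the CLI caches results keyed by a config digest.

## Known limitations

- Synthetic EMG realism is envelope/spectrum-level only; absolute R²
  values on synthetic sessions (≈0.91 intra at the defaults) say nothing
  about values attainable on human recordings.
- The per-recording ZC/SSC dead zone makes those two features mildly
  recording-dependent; pass an explicit `eps_amp` for strict comparability
  across recordings.
- Causal filtering introduces group delay common to both streams' feature
  path but not modeled out explicitly; at 6 Hz/2nd order on the angles and
  100 ms windows the induced target shift is well under one window step.
- `atan`-based α₁/α₂ fold poses beyond ±90° back into range; such poses
  are outside the wrist's physiological range and the generator's scripts.
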