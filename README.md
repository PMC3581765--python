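# emgkin

Simultaneous and proportional estimation of wrist kinematics from
multichannel surface EMG, with a systematic evaluation of how **arm
position** degrades the estimation and how much **positional pooling** of
training data recovers.

## The problem

Myoelectric prosthesis control needs continuous estimates of several wrist
degrees of freedom (DoFs) at once: flexion/extension (DoF1), radial/ulnar
deviation (DoF2), and pronation/supination (DoF3). A regression approach
learns the map from forearm surface EMG to joint angles — here with
*contralateral training*: the EMG of one arm (the amputated or dominant
side) is paired with the mirrored joint angles measured on the other arm,
so an amputee can train the model by moving the intact limb. A practical
obstacle is that the EMG pattern for the same wrist movement changes with
the global limb pose (muscles shift under the electrodes), so a model
trained with the arm in one position degrades when the arm moves.

`emgkin` implements that full analysis as a tested, reusable pipeline:

- **io** — plain-TSV formats for 7-channel EMG (2048 Hz), 7-marker motion
  capture (256 Hz), sync traces, and the session manifest
  (3 arm positions × 7 movement runs × 2 sides).
- **preprocess** — 10–450 Hz 2nd-order Butterworth band-pass, resampling to
  a 1024 Hz working rate, and stream alignment via a shared 20 Hz
  synchronization square wave.
- **features** — the TDAR set on 100 ms windows with 60 ms overlap:
  mean absolute value (MAV), MAV slope, zero crossings, slope sign changes,
  and order-6 autoregressive coefficients from an LMS linear prediction
  filter (7 channels × 10 features = 70 per window).
- **kinematics** — a wrist-centered anatomical frame from the marker set
  {SHO, MEP, LEP, STU, STR, RMC, UMC}; with H the metacarpal midpoint and
  (H_x, H_y, H_z) its mediolateral / dorsopalmar / distal components,

      α₁ = atan(H_y / H_z)        flexion(+) / extension(−)
      α₂ = atan(H_x / H_z)        radial(+) / ulnar(−)
      α₃ = ∠(STR−STU, LEP−MEP)    90° neutral, >90° pronation

  then 6 Hz low-pass, 1024 Hz resampling, and per-window mean-angle
  regression targets.
- **regression** — one MLP per DoF (70 inputs, 3 tanh hidden units, linear
  output) on z-scored features; 5-fold cross-validation with contiguous
  per-run blocks so the 60% window overlap cannot leak train into test.
- **evaluation** — the pooled multivariate R²

      R² = 1 − [Σᵢ Σₜ (α̂ᵢ(t) − αᵢ(t))²] / [Σᵢ Σₜ (αᵢ(t) − ᾱᵢ)²]

  over a grid of scenario (DoF12/DoF13/DoF23/DoF123) × training position(s)
  × testing position × fold, normalization of inter-position scores to
  their intra-position baselines, and a one-tailed paired t test of pooled
  vs single-position training.
- **synthdata** — a synthetic session generator (scripted mirrored wrist
  movements, a rigid-segment marker forward model, and angle-driven
  amplitude-modulated band-limited EMG with a controllable arm-position
  effect) so the whole pipeline is verifiable without human recordings.

## Worked example

Simulate a session with a moderate position effect (σ_g = 0.3), run the
full analysis, and print the report:

```sh
emgkin run --out demo --seed 7 --duration 16
```

which ends with (abridged):

```
scenario  intra_mean_pct  intra_sd_pct  inter_mean_pct  inter_sd_pct
   DoF12            91.4           1.6            66.3          17.9
   DoF13            90.5           2.3            15.3          48.4
   DoF23            90.8           1.4            66.2          17.2
  DoF123            91.2           1.8            45.5          21.9

scenario  n_pairs  single_mean_pct  pooled_mean_pct       t  p_one_tailed
   DoF12       30          66.2720          92.7058  8.0773           0.0
   DoF13       30          15.3328          90.2602  8.6838           0.0
   DoF23       30          66.2370          93.0724  8.5161           0.0
  DoF123       30          45.5474          93.6962 12.2831           0.0
```

Reading: within the training position the three angles are tracked at
R² ≈ 91% in every scenario; testing at a *different* arm position drops the
score (how much depends on which channels the position effect hits), and
pooling the training data over all three positions restores ≈ 90%+ — the
qualitative pattern a position-sensitive EMG-to-kinematics map must show.
The per-entry grid, the summary, the position-normalized 3×3 matrices, and
the pooling test land in `demo/results/` as TSVs plus `report.md`.

The same stages are available individually (`emgkin simulate / preprocess /
angles / features / train / predict / evaluate / report`) and as library
functions.

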