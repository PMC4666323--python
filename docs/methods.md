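# Methods

This note documents the models and numerical choices behind `graspmvpa`:
what the synthetic generator simulates, how the decoding pipeline is
defined, and which decisions were genuinely open.

## Experimental design model

The simulated experiment crosses three actions — precision grasp (PG),
whole-hand grasp (WHG), reaching-only (R) — with two object sizes (small
S, large L), giving six conditions (PGS, PGL, WHGS, WHGL, RS, RL). Each
condition contributes 45 trials grouped into mini-blocks of 5 consecutive
trials of the same condition (54 mini-blocks in total). Trials are spread
over 4 runs of 117 volumes at TR = 3 s (351 s per run); object size is
blocked by run parity (odd runs small, even runs large), so each run hosts
three conditions. Mini-block counts are balanced 13/14 across runs (a
condition's 9 blocks split 4/5 over its two eligible runs, with the
remainder rotated across conditions).

Stimulus-onset asynchronies are drawn from an exponential distribution
truncated to [3, 8] s ("long exponential"). The rate is solved numerically
(Brent's method on the closed-form truncated-exponential mean) so the mean
SOA equals a configurable target, 4.9 s by default — the value at which the
expected schedule of the longest run (70 trials plus an initial fixation
gap and trailing rest) fits the 351 s run. Negative rates (density rising
toward 8 s) are supported, so any target mean in the open interval (3, 8)
is attainable. Because the default mean sits close to the feasibility
boundary, a drawn schedule can exceed the run length; the generator then
redraws the run's SOA vector (up to 1000 attempts) and raises a
run-naming `ScheduleOverflowError` only if no draw fits. The realized SOA
distribution is therefore the truncated exponential *conditioned on the
schedule fitting the run* — a negligible distortion at the default mean,
and exactly what an experimenter generating schedules would have done.
Trial duration (the boxcar length, not stated by the acquisition
parameters) is a config knob, 2 s by default.

`ScheduleOverflowError` is raised rather than truncating because silently
dropping trials would break the per-condition counts every downstream
stage assumes.

## BOLD signal and noise model

Per voxel and run,

    y(t) = baseline + sum_c [boxcar_c * h](t) * (u_c + w_c[v]) + n(t) + d(t)

where `h` is a double-gamma HRF (peak mode 6 s, undershoot mode 16 s,
dispersions 1 s, peak:undershoot ratio 6:1, unit peak; all configurable),
`u_c` a spatially uniform condition amplitude, and `w_c` a zero-mean
(across voxels) multivoxel pattern. Convolution happens on a 0.1 s
microtime grid and is read out at the volume acquisition times, so the
result is resolution-independent. Noise `n` is AR(1)-filtered white noise
(innovation SD 1.0, coefficient 0.3); drift `d` is a sinusoid of period
128 s with random per-voxel phase, which the 0.01 Hz high-pass filter must
remove. Runs are independent noise realizations.

Pattern construction: each level of a factor (grasp type, action type,
object size, or fully condition-specific) receives a random unit-SD
zero-mean voxel vector; a condition's pattern is the sum of its levels'
vectors scaled by per-factor effect sizes β (per-voxel signal SD in the
same units as the noise innovation SD). Subject-specific patterns scatter
around a group template, `w_subj = (w_group + σ_s · fresh)/√(1+σ_s²)`
(σ_s = 0.3 by default), which keeps the per-voxel signal SD at β while
controlling between-subject accuracy variance — the quantity the group
t-test consumes.

What the generator does *not* emulate: spatial voxel correlations, motion,
physiological noise spectra, susceptibility artifacts, or any k-space
physics. Passing tests therefore certify the statistical machinery
(sampling, CV, inference) under idealized noise, not performance on real
scans.

Two emergent properties of the simulated design are worth knowing:

- **Run confound of object size.** Size is blocked by run parity, so the
  two object-size classifications compare samples from disjoint run sets;
  run-idiosyncratic noise can push their accuracy off 0.5 even with zero
  size signal. This mirrors the original design and is why those
  classifications are not used for calibration checks.
- **Inter-block bleed.** The HRF tail (undershoot out to ~30 s) of one
  mini-block leaks into the next block's retained volumes, which caps
  attainable accuracy below 1.0 even at very large β.

## Preprocessing

Per run and voxel, in this order: (1) standardize to mean 0, SD 1 (N−1
denominator; constant series map to zeros with a logged warning rather
than NaN); (2) remove the OLS fit on intercept + linear time; (3) project
out an orthonormal discrete-cosine basis of all components below the
cutoff (0.01 Hz default — k/(2·N·TR) < 0.01 keeps the DC term plus
cosines k = 1…7 for N = 117, TR = 3). The DCT projection was chosen over
an IIR filter for zero phase distortion and exact nulling of modeled
drifts. The chain never mixes information across runs.

## Sampling and decoding

Volumes are partitioned among mini-blocks by onset intervals (a volume
belongs to the block whose first-trial onset most recently precedes its
acquisition time; the run's last block extends to the run end). Within a
block the first 4 volumes (12 s) are discarded as the hemodynamic
stabilization window and the remainder averaged into one sample; an
optional `lag_volumes` shift exists for sensitivity analyses and defaults
to 0 because the discard already plays that role. A 5-trial block spans at
least 15 s (5 volumes), so at least one volume always survives the
discard; typical blocks span ~8.

Each binary classification labels its conditions ±1 (e.g. grasp type:
PGS+PGL vs WHGS+WHGL, N = 36 balanced samples under the default design)
and is decoded with a linear soft-margin SVM, C = 1, no internal feature
scaling and no hyperparameter search. Cross-validation holds out one
sample per class per fold ("leave-pair-out"): the k-th positive sample is
paired with the k-th negative sample in chronological (run, mini-block)
order — the pairing rule is not dictated by the scheme itself, so a seeded
random pairing is available as an option. Accuracy is correct test
predictions over 2 × folds; a decision value of exactly 0 predicts the
positive class (measure-zero tie-break).

## Group statistics

- One-sample one-tailed t against chance (0.5) per ROI × hemisphere cell;
  zero-variance inputs yield a flagged degenerate result instead of NaN.
- Benjamini–Hochberg step-up FDR across the family of all cells of one
  classification (the control ROI is inside the family by default;
  configurable). The reported "corrected α" is the largest raw p rejected.
- Two-way fully within-subject ANOVA (ROI × hemisphere) from the direct
  sums-of-squares decomposition, each effect tested against its
  subject-by-effect interaction; partial η² = SS_eff/(SS_eff+SS_err).
  Sphericity is assumed by default (matching the uncorrected df
  convention); Greenhouse–Geisser adjustment is available behind a flag.
- Post-hoc all-pairs paired t-tests on ROI means collapsed over
  hemisphere, BH-corrected.
- Classification comparison: one-way RM-ANOVA over three classifications
  per ROI (hemispheres averaged) plus a linear trend contrast with weights
  (−1, 0, +1), tested as the one-sample F (= t²) of the per-subject
  contrast scores.

These are implemented from closed forms (and unit-tested against
`pingouin` and textbook hand computations) so that fixture agreement to
1e−10 is meaningful.

## ROI geometry

Masks live in the mm space of the supplied voxel grid (default 64×64×47
at 3.3×3.3×3 mm). Sphere: voxel centers within `radius` of the requested
center snapped to the nearest voxel center (so a vanishing radius selects
exactly one voxel). Cube: |Δ| ≤ edge/2 per world axis. Membership is by
voxel center, not partial overlap. No Talairach↔MNI conversion is
performed — sphere centers are interpreted in the grid's own space and a
`space_label` is carried as documentation; atlas-defined ROIs must be
supplied as mask files.

## Problem sizes and defaults used in shipped checks

The shipped calibration and recovery checks run the full pipeline at
24–100 voxels per ROI — pattern decoding at these dimensions is already
representative, and null calibration is voxel-count-invariant — with 16
subjects for group-level checks, 20–50 replicate experiments for recovery
and detection-rate properties, and 500 reduced (pattern-level) null
experiments for the type-I-error check. The planted-signal preset uses
grasp-type β = 0.11/0.09 (L/R) and action-type β = 0.27/0.22, chosen once
to place per-subject accuracies in the 0.6 (grasp) and 0.7 (action)
regimes with a small left>right asymmetry, qualitatively mirroring the
findings the pipeline is designed to produce tables for; the preset is
synthetic and labeled as such.

## Known limitations

- The simulator's idealized noise makes absolute accuracies
  configuration-dependent; only calibration (chance-level behavior, type-I
  error) and ordering properties (monotonicity in β, planted asymmetries)
  transfer to real data.
- Leave-pair-out accuracy estimates are correlated across folds; the group
  t-test treats per-subject accuracies as exchangeable, which the type-I
  check verifies empirically rather than analytically.
- The cross-validation pairing rule and the FDR family are conventions
  exposed as options, since neither is forced by the scheme itself.
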