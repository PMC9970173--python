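# Methods

This note documents the models, numerical choices and limitations of the
package in its own terms: what each stage computes, which defaults matter,
what the simulator does and does not emulate, and therefore what a green
test establishes.

## Canonical preprocessing order

The pipeline order is fixed and not commutative:

0.1–80 Hz zero-phase band-pass → cue-locked epoching (−1…90 s) with
−1…0 s baseline subtraction → selection of 1…89 s (88 s per trial) →
optional EOG regression → 1 s segmentation → amplitude rejection →
down-sampling to 250 Hz → 2–20 Hz band-pass → average reference.

- All band-pass filters are 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`): zero phase preserves microstate
  timing; the filter family is a free choice and is documented, not
  load-bearing.
- The rejection threshold defaults to ±100 µV. Two readings of
  "amplitude change" are implemented — absolute value exceeding the
  threshold, and peak-to-peak range exceeding twice it — with `"both"`
  as default; rejection is monotone in the threshold by construction.
  An all-rejected subject/condition is a hard error, not silence.
- Alpha power is measured on the clean broadband 1 s epochs (before the
  2–20 Hz filter): Hann-windowed per-epoch periodograms (Welch with 1 s
  segments, density normalisation), integrated over 8–12 Hz and averaged
  over a nine-electrode parieto-occipital set
  (O1, O2, Oz, PO3, PO4, POz, P3, P4, Pz), configurable. With density
  normalisation a sinusoid of amplitude A integrates to ≈ A²/2, which the
  tests check against a Parseval oracle.

## Microstate chain

- **GFP and peaks.** GFP is the per-sample population standard deviation
  across electrodes. Peaks are strict local maxima detected *within each
  1 s epoch*; epoch-edge samples are never peaks, so no segment crosses
  an epoch boundary.
- **Clustering** operates on unit-normalised GFP-peak maps only.
  Polarity is ignored end to end (squared/absolute spatial correlation):
  the template update is the first right singular vector of the member
  stack, which is sign-blind. Defaults: 20 restarts, max 100 iterations,
  tolerance 1e-7 on explained variance, all seeded — identical seeds give
  identical results. Empty clusters are re-seeded from the worst-fitted
  map.
- **Choice of k.** W(k) is computed for k from 1 to 9 so the KL curve
  covers k = 2…8. `KL(k) = |DIFF(k)|/|DIFF(k+1)|` with
  `DIFF(k) = (k−1)^{2/p}W(k−1) − k^{2/p}W(k)`, p = electrode count.
  The chosen k is the **second local maximum in ascending k**, counting
  endpoints with one-sided comparisons; the first local maximum is
  typically the trivial low-k one. If fewer than two local maxima exist
  the global maximum is used, and the "second-largest value" reading is
  reported alongside for audit. On noise-free peak maps the trivial
  low-k bump can vanish, in which case the rule can overshoot — this is a
  property of the rule, deliberately not special-cased; at realistic
  peak-map noise the Monte-Carlo acceptance check recovers k = 4 in well
  over 80% of seeds.
- **Permutation averaging** aligns template sets by solving a linear
  assignment on squared correlations (with per-map polarity signs),
  eigenvector-averages each aligned slot, and iterates to a 1e-6
  tolerance on the total squared correlation. Class names A–D are
  assigned to the overall maps by best bijective match to canonical
  topographies (left-right diagonal, right-left diagonal,
  anterior–posterior, fronto-central); the naming is cosmetic and can be
  disabled.
- **Back-fitting** labels each GFP-peak map by maximal polarity-invariant
  correlation; non-peak samples inherit the temporally nearest peak's
  label with ties going to the earlier peak (midpoint rule). Epochs
  without any peak are labelled unassigned and excluded from parameters.
  No minimum-duration smoothing is applied.
- **Parameters.** Runs are maximal same-label stretches split at epoch
  boundaries. Duration = mean run length (ms); occurrence = runs per
  labelled second; contribution = fraction of labelled samples. With
  boundary-truncated runs included (default) the identity
  contribution ≡ occurrence × duration / 1000 holds exactly and
  contributions sum to 1; an exclusion mode for truncated runs exists
  because the literature is ambiguous on this point, and breaks the
  identity by design. GEV is computed over labelled GFP peaks (the
  domain the templates were fitted on); a sample-based variant is a
  documented alternative, not the default.

## Statistics

- The 2×4 repeated-measures ANOVA is an exact cell-mean sum-of-squares
  decomposition (each within-effect tested against its subject ×
  effect interaction); SS additivity is asserted in tests and the F
  values are checked against an independent oracle to 1e-9.
  Greenhouse–Geisser epsilons are computed from the effect's orthonormal
  contrast covariance and reported alongside the uncorrected p, which
  stays the headline.
- Post-hoc per-class paired t-tests run only when the interaction is
  significant (gate overridable, logged), with Benjamini–Hochberg
  correction *within* each parameter family (across its 4 classes); the
  across-all-12 family is available through the raw p-values.
- Condition-difference variables (smoking − neutral) are created **only**
  for measures whose contrast was significant; correlation families
  (craving, addiction covariates) report raw p as primary plus
  BH-adjusted alongside.
- Mediation (simple three-variable model): variables standardised, OLS
  paths m = a·x, y = c′·x + b·m, y = c·x; the indirect effect a·b gets a
  percentile bootstrap CI (default B = 5000, seeded, subject resampling;
  BCa was deliberately not used — percentile matches the common macro
  default). Verdict: *full* if the CI excludes 0 and c′ is
  non-significant (p ≥ 0.05), *partial* if both significant, *none*
  otherwise.

## The synthetic cohort

The generator states a world and keeps it fixed:

- 40 subjects × 2 conditions × 4 trials of 88 s usable EEG at 250 Hz
  (64-channel approximate 10–20 montage). Simulation runs directly at
  250 Hz — the post-down-sampling rate — to save compute; the
  down-sampling operator is exercised separately with 1000 Hz inputs.
- Latent classes default to the four canonical A–D topographies so that
  recovered class names line up with the generating linkage; random
  well-separated dipolar maps are available instead.
- Dwell times are gamma-distributed (shape 4, i.e. CV = 0.5) — not
  exponential — so mean duration is tunable independently of occurrence
  and implausibly short segments are rare. Baseline means
  (A–D: 88, 86, 92, 84 ms) sit in the field-typical 80–120 ms band.
- Condition effects: smoking multiplies B/C/D dwell means by
  1.15/1.18/1.20 and re-weights transitions mildly toward class D
  (weights 0.92/0.96/0.96/1.12). Consequences: longer B/C/D durations,
  lower A/B/C occurrence with class-D occurrence roughly flat, lower
  class-A and higher class-D contribution — the qualitative
  cue-reactivity pattern. No published effect sizes exist for these
  dwell differences; the defaults were chosen once to make the sign
  pattern recoverable and are not tuned further.
- Signal composition: `data = template[label_t]·g_t + noise + alpha`,
  with g_t a rectified 2–20 Hz-band noise envelope (so GFP peaks fall
  inside stable segments, as the microstate model assumes), pink (1/f)
  noise mixed across the cap by a squared-exponential spatial kernel
  (length scale 0.5 on the unit sphere; white noise would make
  clustering unrealistically easy), scaled to SNR 3 (signal RMS / noise
  RMS), and a 10 Hz sinusoid (2.0 µV neutral, +0.5 µV smoking, subject-
  and electrode-jittered) on the posterior set.
- Behavioural linkage (full-mediation chain): each subject's alpha
  increase is 0.08 µV per ms of their realised class-C dwell increase
  plus N(0, 0.4 µV) noise; their craving increase is 3.5 + 1.2 per µV of
  alpha increase plus N(0, 0.5) on the 0–10 scale; there is no direct
  dwell → craving path. Years of smoking is generated correlated with
  the class-D dwell increase (slope 0.9 yr/ms, noise SD 5 yr).
- Reproducibility: all randomness flows from the cohort seed through
  per-subject seeds; identical seed + config gives bit-identical
  cohorts, recordings and reports.

**What the simulator does not emulate:** ocular/muscle/movement
artifacts (the rejection stage is exercised on constructed spike
fixtures), volume-conduction physics (no forward head model), non-10 Hz
or non-sinusoidal alpha, drifts in vigilance, or microstate syntax beyond
first-order semi-Markov switching. A green recovery test therefore
establishes that the chain is internally correct and recovers this
stated world — not that real-data effect sizes will match.

## Scaling choices in the tests

The acceptance checks run the full EEG chain on a 20-subject cohort at
the default recording length (4 × 88 s) once, shared between the
template-recovery and parameter-recovery checks. Calibration checks
(type-I error, 200 null cohorts) and the effect-pattern check (20
cohorts) run at the label-sequence/parameter-table level: state
sequences are generated and summarised by the same run-length machinery
and the same ANOVA/post-hoc pipeline, without synthesising 64-channel
EEG each time — regenerating full EEG for hundreds of cohorts does not
fit a single-CPU budget, and the EEG-level recovery path is covered by
the shared cohort.

## Known limitations

- The EOG-regression blink option is a linear stand-in for adaptive
  filters used in practice; it is off by default and unvalidated against
  real ocular artifacts.
- `run_full` requires all individual template sets to share one k; with
  per-subject KL selection in mixed cohorts it refuses rather than
  silently harmonising.
- The montage is an idealised spherical layout, adequate for simulation
  and distance-based kernels, not for source analysis.
- Paired designs only (exactly two conditions); no between-group
  factor, no covariate-adjusted mediation, no microstate
  syntax/transition statistics.
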