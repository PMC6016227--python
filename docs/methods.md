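# Methods

This note documents the models and procedures implemented in `emobh`,
the parameter choices, and what the synthetic benchmark does and does
not demonstrate.

## Signal model and preprocessing

Sessions are real-valued matrices of samples × channels at a fixed
sampling rate (default 128 Hz).  Analysis is restricted to the EEG beta
band, taken here as **12.5–30 Hz**: a 3rd-order Butterworth bandpass is
applied to each whole channel before framing, so filter edge transients
fall outside every frame.  The filter is applied forward–backward
(zero phase), which keeps features time-aligned across channels at the
cost of doubling the effective magnitude order; the passband/stopband
tests check the *designed* response (|H|² for the two passes), not a
nominal textbook curve.

Frames are consecutive, non-overlapping windows of 9 s (1152 samples
at 128 Hz); a trailing partial window is discarded.  Each frame
inherits its session's quadrant label.

When more than two channels are present, the two with the highest mean
beta-band power spectral density are selected (Welch estimate, 1-s Hann
segments, 50% overlap, band-restricted mean; ties broken by lower
channel index).  This mimics choosing the most beta-reactive electrodes
from a montage; with the default two-channel data it is the identity.

## Empirical Mode Decomposition

Each frame channel is decomposed by classical sifting:

1. locate strict interior extrema (a plateau counts once, at its middle
   sample — a deterministic tie-break);
2. interpolate maxima and minima separately with **natural cubic
   splines**, extending each spline by mirroring the first/last two
   extrema across the signal boundaries (standard practice to limit end
   swings; the literature leaves the boundary rule open);
3. subtract the envelope mean, repeat until the candidate satisfies the
   two IMF conditions — |#extrema − #zero-crossings| ≤ 1 and a maximum
   absolute envelope mean below `tol_mean` × amplitude range — or until
   `max_sifts` is reached.  Defaults: `tol_mean = 0.05`,
   `max_sifts = 50`; no numeric convergence tolerance is canonical, so
   both are configurable.
4. subtract the accepted IMF from the running residue and repeat, up to
   4 IMFs.  Extraction stops early when the residue has ≤ 1 interior
   extremum, or when a sift aborts because its candidate lost its
   extrema (the remainder then belongs to the residue).

Because each IMF is literally subtracted from the running residue,
`sum(imfs) + residue` reproduces the input to floating-point round-off;
the suite asserts relative error < 1e−8.  Zero-crossings ignore
exactly-zero samples.  A soft spectral-ordering property (IMF_k has a
spectral centroid ≥ IMF_{k+1} for ≥ 90% of random frames) documents
the expected fast-to-slow ordering without demanding it pointwise.

## Sample entropy

SampEn(m, r, N) = −ln(A/B), where B and A count template pairs (i < j,
self-pairs excluded) within tolerance at lengths m and m + 1.  Both
template populations use start indices 0..N−m−1 (the Richman–Moorman
matched-population convention), so the constant pair-count denominators
cancel in the ratio.  Distance is Chebyshev; the tolerance is r × SD of
the analyzed window (per-window, not per-recording), which makes SampEn
scale-invariant.  Defaults: m = 2, r = 0.15, N = 128.

A 1152-sample frame-IMF is longer than the canonical N = 128 window, so
SampEn is computed on the 9 non-overlapping 128-sample windows and
averaged, skipping undefined windows; a `whole_frame_sampen` flag
switches to a single whole-frame computation.  Which of the two a
practitioner intends is genuinely ambiguous; the windowed mode is the
default because it honors N = 128 literally.

When B = 0 or A = 0 the conditional probability is undefined and a NaN
sentinel is returned.  At the feature-table level such entries are
imputed with the maximum *defined* value of the same component — zero
matches means maximal irregularity — and the imputation count is
recorded.  If a decomposition yields fewer than 4 IMFs, the residue's
entropy fills the missing slots so the vector stays 8-dimensional.

## Classifier

A soft-margin SVM with Gaussian kernel, decomposed one-vs-one: k
observed classes yield k(k−1)/2 binary separators; prediction is by
majority vote with ties going to the lowest class index.  Features are
standardized (zero mean, unit variance, statistics fitted on the
training rows only) before the kernel, because SampEn components of
different IMF orders live on unequal scales.  Defaults when not
optimized: C = 1, gamma = 1/(8 × variance of the standardized training
matrix).  The quadratic program is solved by scikit-learn's SVC with a
fixed tolerance; the pairwise decomposition and voting are implemented
explicitly so the tie-break is exact and training is deterministic for
identical inputs.

## Black-hole optimization

A star's position encodes a candidate configuration.  The default
search space (`mode="both"`, 10 dimensions) concatenates:

* 8 additive offsets on the training-feature columns, bounded by
  ±1 column SD — "modified characteristics" derived from the originals;
* log10 C ∈ [−2, 2] and log10 gamma within ±2 of the default kernel
  width.

Pure `feature_perturbation` and `hyperparameters` modes are selectable.
Fitness decodes a position, trains the classifier on the (possibly
offset) training matrix, and measures accuracy on an **untouched**
stratified 30% evaluation split — evaluation rows are never perturbed.
The 70/30 split is fixed per run by the run seed; no canonical
validation protocol exists for this construction, so the split ratio is
a documented package choice.

Initialization: star 0 is the unperturbed baseline configuration;
stars 1..n−1 add Gaussian noise with per-component SD equal to the
baseline *error rate* times the component's bound half-width, so a weak
baseline explores more aggressively.  Per iteration: evaluate all
stars, swap the black hole with any better star, move every other star
by x ← x + α(x_bh − x) with a single α ~ U(0,1) per star (per-component
α behind a flag; positions clipped to bounds), then apply the event
horizon R = f_bh / Σ f_i.  Two absorption variants exist because the
verbal and formulaic accounts of the rule differ in the literature:

* **distance rule (default)**: absorb when the bound-normalized
  Euclidean distance to the black hole is below R — the standard,
  stable reading;
* **probability rule** (`horizon_rule="probability"`): absorb when
  u ~ U(0,1) < R.

Likewise the denominator of R can exclude the black hole's own fitness
(`horizon_excludes_bh`); the default includes all stars, following the
formula rather than the prose.  Absorbed stars are replaced by fresh
uniform in-bounds stars.  The historically best star is returned with
the per-iteration best-so-far trace, which is monotone nondecreasing by
construction and at least the baseline accuracy because star 0 starts
at the baseline.

Canonical experiment parameters: 30 stars, 100 iterations, 30
independent runs with consecutive seeds, aggregated per iteration into
min/avg/sd/max columns (accuracy in percent, two decimals).  The `sd`
column is the standard deviation of best-so-far accuracies across runs,
in percentage points.  Desk-scale defaults used by the acceptance
script are smaller (20 sessions/class, 5 runs × 20 iterations, 30
stars) purely so the whole experiment re-runs in about a minute; the
protocol is otherwise identical.

## Synthetic data

The generator emulates exactly the contrasts the features detect:

* beta oscillation with a per-session centre frequency drawn uniformly
  in 13–29 Hz; amplitude 2.0 for high arousal vs 1.0 for low (2:1);
* additive white Gaussian noise, SD 1.0 for low valence vs 0.5 for
  high (2:1) — noisier signals are more irregular, raising the SampEn
  of the fast IMFs;
* a shared slow drift (0.3 Hz, amplitude 0.5) standing in for baseline
  wander;
* two channels with independent noise and phases but shared class
  structure; 36-s sessions (4 frames) by default.

Effect sizes were chosen once so that desk-scale datasets separate the
four classes clearly above chance without being trivially separable;
they are exposed in `EffectSizes`.  The generator deliberately does
**not** model 1/f background spectra, alpha rhythms, eye-blink or
muscle artifacts, inter-subject variability, or volume conduction.
Consequently, passing tests demonstrate that the pipeline's machinery
is correct and that the optimizer improves a real classifier on data
with the assumed structure — they do not certify accuracy levels on
real EEG, whose headline numbers depend on a restricted corpus.

## Numerical and degenerate-input choices

* Zero-variance series and templates with no matches yield the
  undefined-SampEn sentinel rather than infinities.
* Constant signals have no extrema and decompose to a bare residue.
* PSD requires ≥ 2 s of signal; sessions must contain ≥ 1 full frame.
* Channel-PSD ties and voting ties break toward the lower index.
* All randomness flows through seeded `numpy` generators; identical
  config + seeds give bit-identical CSV outputs.

## Known limitations

* The event-horizon absorption rate is high when fitnesses are nearly
  equal (R ≈ 1/n but contracted populations sit close together), so the
  search behaves like an elitist random restart in late iterations;
  this matches the algorithm as described, and elitism protects the
  reported optimum.
* Sifting tolerances trade IMF purity against leakage between
  neighbouring IMFs; the defaults favour speed and reconstruction
  exactness, which the feature layer tolerates because it consumes
  entropies, not waveforms.
* A "resonant frequency 0.1 Hz" sometimes quoted alongside this beta
  bandpass recipe has no standard interpretation for a 12.5–30 Hz
  Butterworth design and is not implemented.
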