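# Methods

This note documents the model, its parameters and the design choices behind
`ndoa`, in the order the data flows through the package.

## Signal model and windowing

The input is single-channel EEG sampled at 128 Hz in microvolts, with a
per-second annotation stream (reference index in [0, 100], signal-quality
indicator SQI in [0, 100], EMG index ≥ 0). Awake cortex produces low-voltage
(~±15 µV) broadband activity with dominant 8–30 Hz power; deepening
anaesthesia produces increasingly high-voltage (~±60 µV) 0.5–4 Hz slow
waves. All processing operates on 10 s windows (1280 samples) advanced by
1 s, so consecutive windows overlap by 9 s. A reference value of −3276.8 is
the monitor's invalid marker (recorded when SQI < 15, at which point the
monitor blanks its display); `valid_bis_mask` treats a second as invalid
when the sentinel is present (|bis + 3276.8| ≤ 1e-6) or SQI < 15. The
sentinel tolerance absorbs decimal-text round-trips.

## Preprocessing

1. **Outlier clipping.** Samples beyond mean ± k·std (k = 5) are clipped to
   the boundary, not deleted, so sample/annotation alignment is preserved.
   A constant window passes through (std = 0 would otherwise clip
   everything to the mean).
2. **Wavelet thresholding.** Daubechies-16 at 6 levels (the same transform
   the PSD feature uses; at 1280 samples level 6 slightly exceeds
   PyWavelets' conservative depth recommendation, which is harmless under
   symmetric extension — perfect reconstruction is tested to 1e-8).
   Two threshold rules:
   * *universal*: per detail level, Th = σ√(2 ln N), σ = median(|d|)/0.6745;
   * *adaptive* (default): Th_new = |ln(r_pe)/[ln(n·ln n)]² − a|·b with
     a = 9, b = 6, natural logs, computed once per window from the time
     series and applied to all detail levels. The entropy is a time-domain
     property, so a per-level version would conflate scale content with
     irregularity. r_pe is the whole-window permutation entropy (m = 3,
     delay 1, ties broken by order of occurrence) divided by the summed
     permutation entropy of K = 10 equal segments — one per second of the
     window. If every segment is perfectly ordered (total energy 0) the
     window is degenerate and the denoiser falls back to the universal rule.
   The absolute value makes the rule sign-stable: ln(r_pe) ≤ 0, so without
   it the bracket's sign would depend on a. The constants a and b are
   empirical offsets fitted upstream against clinical recordings; they give
   Th_new ≈ 54 on typical windows, only weakly dependent on r_pe.
3. **Shrinkage mode.** Hard thresholding is the default. With a threshold
   of ~54 µV, soft shrinkage subtracts the full threshold from every
   surviving coefficient, which systematically attenuates genuine signal;
   on clean-signal-plus-spike fixtures this attenuation costs about as much
   RMSE as the spike itself, and the "denoising never hurts" property then
   fails (17/20 seeds vs 20/20 for hard). Hard keeps above-threshold
   coefficients exact and removes everything below. Soft remains available
   (`DenoiseConfig.mode = "soft"`).

A consequence worth knowing: the threshold's absolute scale sits *above*
the awake-state amplitude, so the denoiser suppresses most low-voltage
awake activity. Post-threshold entropies therefore no longer rank awake
above deep — that contrast is a property of the raw signals (and is tested
there) — but the post-threshold features remain a strong, monotone-enough
encoding of state for the regression stage, which is what the end-to-end
benchmark verifies.

## Features

Per denoised window (defaults in parentheses):

* **Sample entropy** (m = 2, r = 0.2·std): −ln(A/B) over Chebyshev
  template pairs with strict `< r` matching, self-matches excluded, both
  counts over the same N−m templates. A = 0 is reported as infinity, B = 0
  as a degenerate window. The tolerance scales with std, so SE is invariant
  under positive affine maps.
* **Fuzzy entropy** (m = 2, n = 2, r = 0.15·std): templates are de-meaned
  and matches weighted by exp(−(d/r)^n), giving a statistic continuous in
  the data.
* **Permutation entropy** (m = 4, τ = 1): Shannon entropy of ordinal
  patterns normalised by ln(m!) into [0, 1]; only observed patterns
  contribute; ties break by order of occurrence (stable argsort). The
  conventional minus sign is applied so the value is non-negative.
* **Hurst range response**: for each dyadic scale {N, N/2, …, ≥ 8} the
  window is cut into segments; per segment the range R of the cumulative
  de-meaned sums and the population std S are computed; the feature is the
  minimum over scales of the mean R, taken literally as a range-response
  statistic (homogeneous of degree 1 in amplitude — it tracks the voltage
  swing). S = 0 segments are excluded. The classical R/S curve and its
  log–log slope (the Hurst exponent) are exposed via
  `rescaled_range_curve`/`classic=True` for users who want the standard
  estimator.
* **PSD eigenvector feature**: at each of 6 db16 levels, both the
  approximation and detail series feed an eigenvector (EV) pseudospectrum —
  Toeplitz autocorrelation matrix of order 12, the 6 smallest-eigenvalue
  eigenvectors as the noise subspace, inverse-eigenvalue weighting,
  evaluated on 128 frequencies over [0, π) rad/sample. The grid, order and
  subspace size are configurable; order 12 comfortably exceeds the few
  dominant rhythms per band while staying well below the shortest
  coefficient series (~40 samples at level 6). Per level the
  pseudospectrum's mean and std are taken over the grid; across levels
  M = ½[ln(mean of detail means) + ln(mean of approximation means)] and S
  analogously for stds, and the feature is (k₁·M + k₂·S)/k₃ with
  k = (28, 90, 3). Logs are natural. Because pseudospectra scale with the
  square of amplitude, amplitude changes shift the feature additively — a
  tested identity.

Degenerate windows (constant signal, no template matches, non-finite
sub-results) never crash or emit NaN into feature tables: the window is
flagged and its placeholder values excluded downstream.

## Index model

A squared-exponential Gaussian-process regressor: kernel
C·RBF(ℓ) + WhiteKernel, hyperparameters by marginal-likelihood optimisation
from a seeded start, features z-scored with training statistics stored in
the model, predictions clamped to [0, 100]. Exact GP cost is O(n³); above a
cap (default 3000 rows) a seeded uniform subsample is used for
hyperparameter fitting and doubles as the inducing set for prediction —
at desk scale (hundreds to a few thousand rows) this is exact. The
comparison menu — robust linear (Huber), decision tree (min leaf 4), RBF
SVM — uses standard library parameterisations; fivefold cross-validation
(row-wise by default, subject-grouped behind a flag) pools held-out
predictions before computing R², MSE, RMSE and MAE. Model archives are
self-describing JSON (kind, seed, standardisation, training subset, GP
kernel parameters, frozen preprocessing config); loading refits
deterministically from the stored subset, so save→load→predict reproduces
predictions to float precision.

## Real-time engine

Per second: append 128 samples; before the 5th second emit an invalid
entry (startup delay); afterwards process the trailing window —
min(buffered, 10 s), i.e. the window grows from 5 s to its full 10 s length
during seconds 5–10, reconciling the 4 s delay with the 10 s window —
through clip → denoise → features → predict, then smooth:
tuned = 0.8·mean(history) + 0.2·raw, where history holds the raw
predictions of up to the last 4 s (fewer during warm-up; the recursive
variant that stores tuned values instead is available via
`history_mode="tuned"`). The smoother bounds each step by 0.2·range(raw)
and keeps the output inside the raw range. The index is emitted at every
second regardless of reference validity; degenerate windows yield invalid
entries without advancing the history. Batch (`run_record`) and
incremental (`step`) execution share the per-window path and are tested to
produce identical traces. Single-window feature extraction runs in
~0.1 s on one CPU, well inside the 1 s real-time budget.

## Agreement analysis

Differences d = index − reference on seconds valid on both sides.
Bias = mean(d), sd = std(d) with the sample convention (n−1; the
population convention is a flag, and the two differ by √(n/(n−1)) — tested
explicitly). Limits of agreement are bias ± 2·sd (the multiplier is
configurable; 2.0, not 1.96, is the package default) and the agreement rate
is the percentage of d inside the limits (≈95.45% for normal d). Per-subject
reports list one Pearson correlation per subject plus an average row
(arithmetic mean of the per-subject r).

## Synthetic generator

Each state contributes two band-limited components (4th-order Butterworth,
zero-phase) with per-state amplitudes, µV std (slow 0.5–4 Hz / mid
8–30 Hz): awake 1.5/4.5, light 4.0/3.5, moderate 8.0/3.0, deep 18.0/1.5,
plus a 0.8 µV broadband floor — chosen so awake peaks sit near ±15 µV with
mid-band dominance and deep peaks near ±60 µV with slow-wave dominance.
State changes crossfade over ~5 s (Gaussian-smoothed envelopes). Nuisance
injections: single-sample spikes at 8× the local rms (Poisson, 2/min),
3 s low-amplitude collapses to 15% amplitude (0.5/min), 30–60 Hz EMG
bursts on scheduled spans, and SQI dropouts (SQI = 10, reference set to the
−3276.8 sentinel). The reference trace follows conventional clinical index
bands per state (awake 90, light 65, moderate 50, deep 30 — general
anaesthesia is conventionally 40–60), Gaussian-smoothed (σ = 3 s) with
jitter (sd 3), clipped to [0, 100]. Everything is deterministic per seed.

What the generator does *not* emulate: burst suppression, real artefact
morphology (eye blinks, electrocautery), pharmacokinetics, inter-subject
variability of spectra, or any validated mapping from EEG to a clinical
index — its reference trace is constructed, not measured. Passing tests on
this data demonstrate that the pipeline's machinery is correct and that it
recovers ordinal state structure from signals with the assumed spectral
contrast; they say nothing about clinical accuracy.

## Benchmark and problem sizes

The end-to-end benchmark generates 10 records (~150–200 s each: awake →
light → moderate → deep → moderate → awake, varied durations; half with an
EMG burst, a third with an SQI dropout) and a 60/73-proportioned train
split in its manifest. Held-out traces use record-wise 2-fold
cross-fitting — each half of the records is streamed through a model
trained on the other half — so every record's correlation is computed on a
model that never saw it. Benchmark training uses a GP subset cap of 1000
rows. These sizes keep a full run in a few minutes on one CPU while leaving
every stage exercised at its real window length.

## Numerical conventions and edge cases

* Natural logarithms everywhere an entropy or log appears.
* std is the population convention (divisor n) in features and generator;
  the Bland–Altman sd defaults to the sample convention (n−1).
* Sample-entropy matching is strict (`d < r`).
* Ordinal-pattern ties break by order of occurrence.
* Thresholds are non-negative by construction; shrinkage at threshold 0 is
  the identity.
* Eigen-problems use symmetric (`eigh`) solvers; pseudospectrum
  denominators and eigenvalues are floored at tiny positive values to
  avoid division by zero on degenerate inputs.
* Constant windows, zero-entropy windows and zero-variance targets raise
  (or flag) explicitly rather than propagating NaN.

## Known limitations

* The adaptive-threshold constants (a = 9, b = 6) are absolute-scale
  offsets inherited from clinical calibration data that are not public;
  on data in other units they should be re-fitted.
* The literal range-response feature is not the classical Hurst exponent;
  both are exposed, but only the literal form feeds the default model.
* The EV pseudospectrum's model order and grid are package conventions;
  the feature's absolute value is convention-dependent (its use is
  relative, through the trained model).
* Row-wise cross-validation shares subjects across folds; use the
  subject-grouped flag for leakage-safe model assessment.
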