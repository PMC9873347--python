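# Methods

Design notes for `ehgkit`: the signal model, every fixed parameter with
its rationale, and the numerical choices that matter for correctness.

## Signal model and synthetic cohorts

Real labeled EHG cohorts are small and access-controlled, so the package
ships a generative model rich enough to exercise every pipeline stage
and to pose a falsifiable end-to-end question (can the pipeline recover
a known class contrast, and does it stay at chance when there is none?).

Each record is three channels at 20 Hz:

- **Baseline**: 1/f^α noise (α = 1), shaped in the frequency domain and
  scaled to a configurable RMS (default 1.0). Physiological abdominal
  recordings are dominated by low-frequency drift; 1/f is the simplest
  spectral shape with that property.
- **Contraction bursts**: Poisson-counted events (default 10 per
  30 min) with Gaussian-jittered durations (45 ± 10 s) and Hann
  envelopes. Burst timing is shared across channels (one uterus),
  channel gains jitter lognormally (σ = 0.1) to mimic electrode
  placement.
- **Burst carrier**: a convex mix of a coherent tone (frequency drawn
  from the carrier band, default 0.3–1.0 Hz) and band-limited noise,
  weighted by a `regularity` parameter. This provides a complexity
  contrast that the entropy features can detect independently of
  amplitude.
- **Cardiac interference**: a truncated-Fourier pulse train at 1.4 Hz
  with three harmonics, scaled per class. Maternal ECG contamination is
  a documented EHG nuisance and gives the F2 subband (1–2 Hz) a
  class-dependent spectral signature.

The default class profiles are the study conditions, fixed a priori:
preterm records get stronger bursts (gain 3.0 vs 1.5, ratio 2), more
regular carriers (0.8 vs 0.3), and less ECG interference (0.05 vs 0.3).
Reproducibility: the generator seeds `numpy.random.default_rng` with
`[seed mod 2^31, record_index]`, so records are independent streams and
cohorts are bit-reproducible.

## Preprocessing

- Z-scoring uses the population standard deviation and raises on
  constant signals rather than dividing by zero.
- Subband filters are order-4 Butterworth band-passes applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase with squared
  magnitude response. Verified properties: ≥ 0.99 power gain at
  mid-band, ≤ 0.1 one octave outside each edge.
- Windows are 120 s (2400 samples) with 50% overlap; a 30-min record
  yields exactly 29 windows sharing 1200 samples with each neighbor.

## Features (33 per window)

**Linear (5).** Welch PSD (512-sample Hann segments, 50% overlap).
Peak frequency takes the lowest bin on ties; median frequency linearly
interpolates the half-power crossing of the cumulative in-band power,
so it is not quantized to the bin grid.

**Entropy (18).** Parameters follow common practice for short
physiological windows:

- Sample entropy: m = 2, r = 0.15·SD. Returns 0 for a fully regular
  series and +inf (sentinel) when no template matches survive.
- Fuzzy entropy, local and global: m = 2, absolute tolerance
  r = 0.0077, exponential membership exp(−(d/r)³). "Local" removes the
  template mean, "global" the series mean. The absolute tolerance makes
  this the one deliberately scale-sensitive entropy.
- Permutation entropy: order 3, delay 2, normalized by ln 3!.
- Dispersion entropy: m = 2, c = 3 linear (min-max) mapping.
- Bubble entropy: m = 10, Rényi-2 entropy of bubble-sort swap counts,
  normalized by ln((m+1)/(m−1)).
- Phase entropy: Shannon entropy of the angular histogram of the
  second-order difference plot, at 12 sector counts k = 2, 4, …, 24.

The sample- and fuzzy-entropy kernels are `numba`-compiled with an
early-abort bound (memberships below exp(−745) underflow to zero), which
keeps the worst-case 33-feature window under ~150 ms.

**Time-frequency (10).** The continuous transform uses an analytic
Morse wavelet (γ = 3, time-bandwidth P² = 60) implemented directly in
the frequency domain, L1-normalized so equal-amplitude tones attain
equal ridge magnitude (verified to 5%). The dyadic grid has 10 voices
per octave from the Nyquist frequency down to where two wavelet
half-widths fit inside the window. Energy is the summed squared
magnitude; the three flux features are mean absolute scalogram
differences at offsets (0,1), (1,1), (1,0) along (time, frequency).
The discrete transform is a 7-level db12 decomposition with
periodization; windows are zero-padded to a multiple of 2⁷ so the
orthogonal transform satisfies Parseval exactly (verified to 1e-8
relative), and the six features are the adjacent log-energy differences
of the detail levels (finest first).

## Selection and classification

Selection runs on training windows only: F-test top-10, χ² on 10
equal-width bins top-10, multivariate OLS of the numeric label keeping
coefficients with p < 0.05 (univariate fallback when n ≤ p+1, collinear
columns dropped), and sequential forward selection maximizing
stratified 5-fold CV accuracy of a linear SVM. The final set is
(SFS ∩ union-of-others) ∪ (regression ∩ (F-test ∪ χ²)), padded by F-rank
to at least 7 and truncated to at most 13.

The seven classifier families are fixed presets (no hyperparameter
search): polynomial SVMs of degree 2 and 3 (C = 1, coef0 = 1), RBF SVM
with kernel scale √p/4, k-NN with k = 10 and squared-inverse weights,
30-tree bagging, and linear/quadratic discriminants (QDA with
regularization 1e-3 for stability on near-singular class covariances).
All run behind a standardization step fit on the training folds.

Records are split per class into train/validation/test by rounded 70/15/15
fractions (20 per class → 14/3/3). The family is chosen by validation
accuracy with AUC as tie-break; the chosen family is then assessed by
k-fold CV (default k = 23) over the pooled train+validation *windows*,
with the fixed test set scored by every fold model. Window-level pooling
inside train+validation is deliberate and documented; record-level
independence of the test set is enforced structurally — overlapping
record ids raise `LeakageError`. The positive class is `P`, so
sensitivity reads as preterm detection.

Mann–Whitney screening is exact (full enumeration null) when the pooled
sample is ≤ 20 without ties, otherwise normal-approximated with tie
correction; stars at p < 0.05/0.01/0.001/0.0001.

## Problem sizes

The study conditions used by the gating end-to-end experiment are this
package's own choice, sized for a single CPU: 10 contrast and 10
matched-null cohorts of 20 P + 20 T records, 240-s records (3 windows
each, pool of 102 windows ≥ k = 23), channel S1, subband F2. At these
sizes the full 20-cohort experiment completes in ≈ 8 min; observed mean
held-out-test accuracy is 0.97 on contrast cohorts and 0.50 on null
cohorts. Full-length (1800-s) records and all nine channel-band
datasets are supported and simply cost proportionally more.

## Limitations

- The generator is a phenomenological surrogate, not a biophysical
  uterus model; absolute feature values should not be compared with
  clinical recordings.
- Window-level CV inside the pooled train+validation set can place
  windows of one record in both a training and a validation fold; only
  the test set guarantees record independence.
- The fuzzy-entropy tolerance is absolute, so that feature responds to
  signal scale by design; all other entropies are affine-invariant.
- Classifier presets are fixed; no hyperparameter search is performed.
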