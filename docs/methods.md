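# Methods

## Pipeline overview

The package classifies the valence (positive vs negative) of fixed-length
EEG trials in five stages: (1) per-channel 4-level discrete wavelet
decomposition with the Daubechies-2 filter pair; (2) reduction of the
level-4 detail band (4–8 Hz theta at a 128 Hz sampling rate) to five
statistics; (3) wrapper channel selection — rank channels by the accuracy
a classifier reaches on each channel's features alone, keep the top five;
(4) classification of the concatenated 25-dimensional vectors with a
single-hidden-layer perceptron and with k-nearest neighbours; (5) repeated
random 30/10 train/test splitting with accuracy/specificity/sensitivity
reporting.

The method assumes trials are stationary enough that band statistics are
meaningful, that the discriminative signal is concentrated in the theta
band, and that per-channel separability is a good proxy for a channel's
value in the joint feature vector (the selection is strictly univariate).

## Wavelet transform

The analysis pair is the db2 low-pass
`h = [(1+√3), (3+√3), (3−√3), (1−√3)] / (4√2)` with the quadrature-mirror
high-pass `g[n] = (−1)ⁿ h[3−n]`. Each level extends the signal at the
boundaries, correlates with `h` and `g`, and keeps every second sample.

* **Extension modes.** `symmetric` (default) uses half-sample reflection
  and maps length `L` to `⌊(L+3)/2⌋` per level, which is the convention
  under which an 8064-sample trial yields 4033 → 2018 → 1010 → 506 cD4
  coefficients. `periodic` (periodization) halves the length exactly and
  makes the filter bank orthonormal; it exists for the energy-conservation
  guarantee (relative error < 1e-15 in practice) and pads odd lengths by
  repeating the final sample. Nothing pins the boundary *values* beyond
  the length convention; the symmetric default matches the common choice
  in wavelet toolboxes, and the test suite locks both modes
  coefficient-for-coefficient against PyWavelets.
* **Inversion** upsamples, convolves with the same pair and trims; perfect
  reconstruction holds to < 1e-8 max error for lengths 64–10000 in both
  modes (measured ~4e-15).
* **Band localization.** db2 has only four taps, so its half-band filters
  are far from brick-wall: a 6 Hz tone at 128 Hz places ~74.5% of its
  total detail energy in cD4 (the remainder mostly in cD3), and a 24 Hz
  tone ~72.7% in cD2. The localization tests therefore require the correct
  band to dominate and to hold ≥ 70% of detail energy — the attainable
  figure for this wavelet, measured with an independent reference
  implementation before the constant was fixed. Longer wavelets would
  concentrate more but would change every coefficient count.

## Features

Per channel the cD4 vector is reduced to, in fixed order: max |c|,
mean |c|, sample standard deviation (n−1 denominator; the convention is a
package choice), average power = mean c², and average energy = Σ c². With
a fixed-length cD4, energy = 506 × power exactly, so the fifth feature is
redundant given the fourth; both are kept for fidelity to the established
five-statistic set, and the redundancy is asserted in tests. "Average
energy" is taken as *total* energy (Σ c²); reading it as normalized energy
would duplicate average power exactly.

Because the five statistics span orders of magnitude (max |c| ~ units,
energy ~ 10³–10⁵), features are z-scored with training-fold statistics
before either classifier; without this the sigmoid units saturate and kNN
distances are dominated by the energy column. This scaling is a necessary
addition to the core recipe, applied identically to both classifiers and
fitted on training folds only.

## Classifiers

**MLP.** Architecture `n_in × n_hidden × 2`, sigmoid at hidden *and*
output layer (the output activation is a package choice; two output units
with targets `[1 0]`/`[0 1]` and argmax readout). Training is online
gradient descent on `E = 0.5 Σ (t − o)²` with momentum:
`Δw(t) = −η ∂E/∂w + μ Δw(t−1)`, η = 0.7, μ = 0.9. Weights start uniform
in (−0.5, 0.5), the pattern order is reshuffled every epoch, and training
stops when the epoch mean squared error (per pattern and output) falls
below `tol = 1e-3` or at `max_epochs = 1000`. All draws come from one
seeded generator, so training is bit-reproducible. The per-pattern inner
loop is JIT-compiled (numba); the analytic gradients are verified against
central finite differences to < 1e-5 relative error.

Hidden size for the final 25-input network is chosen per participant over
the grid {5, 10, 15, 20} by stratified inner-validation splits (~20% of
each training fold), averaging validation accuracy over repeats; ties go
to the smallest network. The selection-stage network uses a fixed
`5 × 10 × 2` architecture.

**kNN.** Euclidean distance, majority vote among the k nearest, k odd so
two-class votes cannot tie; exact distance ties are broken toward the
lower exemplar index (stable sort), making predictions permutation-
invariant away from ties. k ∈ {1, 3} is chosen per participant by
leave-one-out accuracy on the training folds (ties → k = 1); choosing on
test data would leak.

## Evaluation

Each repeat draws 30 training and 10 test trials; four repeats by default.
Splits are stratified by default (class proportions within ±1 trial per
fold) — with 20/20 labels this keeps test folds at 5±1 per class; a
training fold with a single class is redrawn from the next seed substream.
Metrics follow the printed formulas: accuracy = 100(TP+TN)/total,
specificity = 100·TP/(TP+FP), sensitivity = 100·TN/(TN+FN), with positive
emotion as the positive class. Under standard nomenclature these
"specificity"/"sensitivity" formulas are the positive-class precision and
the negative predictive value; the textbook definitions are available via
`metrics(..., standard=True)`. A zero-denominator ratio is reported as
undefined (`None`) and excluded from averages with a logged count, never
silently set to 0. Counts are tallied per repeat and the metric
percentages averaged across repeats — pooling counts first would weight
repeats by their test sizes and is deliberately not done; the choice is
pinned by a test. Report tables round to one decimal.

Channel selection and final evaluation draw their split plans from
disjoint seed substreams: reusing the selection folds for final testing
would bias accuracy upward. Both classifiers are evaluated on identical
final folds (hash-checked).

## Synthetic data

The generator emulates the *structure* of a preprocessed affective-EEG
study: 40 trials × 32 channels × 8064 samples at 128 Hz per participant,
valence ratings on the 1–9 scale, labels negative iff rating < 5. Classes
are balanced 20/20 and ratings are drawn uniformly from [1, 4.5] or
[5.5, 9], avoiding the boundary rating 5 (which the strict rule maps to
positive). Trials are 63 s; that length, not 60 s, is what makes a 4-level
decomposition produce 506 cD4 coefficients, and the generator defaults to
it.

Each channel carries broadband 1/f-shaped noise: white noise integrated by
cumulative sum (gives an f⁻² spectrum), band-passed 4–45 Hz with a
4th-order zero-phase Butterworth (mirroring the emulated preprocessing),
rescaled per channel to `background_sd` (default 2 µV). Informative
channels (default P3, FC2, AF3, O1, Fp1) additionally carry
`A sin(2πft + φ)` with `f ~ U(4, 8)` Hz and `φ ~ U(0, 2π)` redrawn per
channel and trial — so no single spectral line identifies the class — and
`A = theta_amp_pos` (4 µV) on positive trials vs `theta_amp_neg` (1 µV) on
negative ones. That amplitude difference is the only class signal.

What the generator does **not** emulate: event-related potentials,
artifacts (ocular, muscular), volume conduction and inter-channel
correlation, non-stationarity within trials, inter-participant
variability beyond the seed, or realistic rating distributions. Passing
tests therefore show that the chain recovers a planted band-specific
effect and stays at chance without one — not that it reaches any
particular accuracy on real recordings. With the default strong effect
the synthetic problem is easy (cohort accuracies saturate near 100%);
the end-to-end assertions are deliberately qualitative (above the 95%
binomial chance bound; MLP ≥ 70%; classifiers within 10 points of each
other).

## Reproducibility and problem sizes

Every random site — data generation, split plans, weight initialisation,
epoch shuffles, inner validation — derives from named substreams
(`numpy` `SeedSequence` spawn keys) of one master seed; reruns are
byte-identical. The acceptance script exercises the study-scale sizes:
8064-sample trials, 100 random kNN problems, 20 seeds for selection
recovery and its null control, and a 20-participant cohort end to end.
Unit tests use shorter segments (2–4 s) where only contracts, not
accuracies, are at stake.

## Known limitations

* The univariate wrapper ignores channel interactions; a channel useless
  alone but useful jointly would never be selected.
* The printed specificity/sensitivity formulas differ from standard
  usage; cross-study comparisons should use `standard=True`.
* Selection consolidates nothing across participants: each participant
  gets their own ranking (a fixed channel set can be forced via
  `RunConfig.fixed_channels`).
* db2's coarse band edges mean cD4 contains non-trivial energy from
  outside 4–8 Hz and vice versa; "theta features" are theta-dominated,
  not theta-exclusive.
* Native import of the original database's files is out of scope; data
  enter through the portable manifest + CSV format or the generator.
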