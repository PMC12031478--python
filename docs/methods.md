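# Methods

`silentspeech` implements a letter-classification stack for two-channel
chin-sensor recordings of silent articulation: a surface-EMG channel
(muscle activity of the tongue/jaw complex) and a piezoelectric (PZT)
channel (low-frequency skin vibration), sampled at 4096 Hz per channel.
The classification target is the eight most frequent English letters
(E, T, A, O, I, N, R, S), 100 trials per letter.

This note documents the models, the synthetic data the package is tested
on, the numerical choices, and the limits of what the tests demonstrate.

## Pipeline and protocol

Every experiment follows one protocol, fixed across all nine
input/model scenarios:

1. per-class stratified split into 60% train / 20% validation / 20% test
   (largest-remainder rounding within each class; the split depends only
   on the trial-id set and the seed);
2. augmentation of the **training partition only** — SMOTE in feature
   space for the classic models, the eight signal operators for the
   networks; the driver hashes test trials before and after training and
   refuses to return results if they changed;
3. model fitting with all model selection driven by **validation**
   accuracy (grid search for SVM/decision-tree/random-forest; early
   stopping for the networks);
4. evaluation on the untouched test partition: accuracy, macro-averaged
   F1 (classes are balanced), and the 8x8 confusion matrix.

## Features

Nine descriptors per channel, computed over the whole trial as a single
window (no sub-windowing): mean absolute value, RMS, population variance
(1/N), waveform length, zero-crossing count, and — from the one-sided,
unwindowed DFT — dominant frequency, power-weighted mean frequency,
median frequency (smallest frequency where cumulative power reaches half
the total) and magnitude-weighted frequency centroid.

Decisions where the definitions were open:

* zero crossings use the strict product rule `y[i]*y[i+1] < 0`; an exact
  zero sample breaks a crossing;
* "mean frequency" weights by the power spectrum and "frequency
  centroid" by the magnitude spectrum, keeping the two features distinct;
* the DC bin participates in every spectral weight; dominant-frequency
  ties resolve to the lowest frequency;
* no window/detrend is applied by default (a Hann window would bias the
  low-frequency PZT features far more than it helps the EMG ones).

Every feature is checked against an independent naive-loop or
direct-summation-DFT oracle to 1e-9 relative error.

## Feature selection

Backward recursive feature elimination: fit an importance estimator,
drop the least important feature, repeat to a single survivor, recording
the full elimination order.  The importance source is a random forest's
impurity importance (scale-free; a linear-SVM squared-weight option
exists).  The retained subset is the smallest prefix of the ranking
whose validation accuracy is within a tolerance (default 0.5 percentage
points) of the best prefix — the procedure exists to reduce
dimensionality, so ties go to the smaller subset.

The tolerance interacts with validation-set granularity: with V
validation trials one misclassification moves accuracy by 100/V pp, so
the default tolerance is only meaningful for V >= ~200.  The selection
benchmark (`make_feature_benchmark`) therefore uses 8 classes x 100
samples and places class centroids on binary codewords at 6-sigma
separation, constructed so that dropping any informative dimension makes
two classes coincide: the informative set is the unique optimal subset,
and recovery is a well-posed ground-truth question.

## Augmentation

* **SMOTE** (feature space): synthetic rows `x + U(0,1)*(x_nn - x)` with
  `x_nn` among the 5 nearest same-class neighbours; applied to all
  classes equally (the protocol is balanced), default target twice the
  original count.
* **Signal operators** (raw space): hang, windowed Gaussian smoothing
  (odd kernel in [3, 31] samples, truncated at 3 sigma), windowed additive
  noise scaled by the signal's std (per-sample draws U(0,1) as
  documented; a zero-centred U(-1,1) variant is available because the
  one-sided draw adds a positive bias), windowed down/up-sampling to
  1-25% by linear interpolation, additive slope with total rise below
  10x std, circular x-shift of at most 5% (circular keeps length and
  avoids an undefined tail), y-shift of at most 5% of the range, and
  scaling in [0.95, 1.05].  A composition applies operators in a
  seed-shuffled order, each included independently with probability 0.5;
  each training trial contributes one augmented copy by default.  All
  operators preserve length, and a 1000-draw audit per operator checks
  every drawn parameter against its bound.

## Networks

All networks are built on a small reverse-mode automatic-differentiation
engine written for this package (numpy, float64, single-threaded), with
1D convolution (im2col), batch normalisation, adaptive average pooling
and fused softmax cross-entropy as primitives; all primitive gradients
are verified against central differences in the test suite.

* **FEN** (Feature Extraction Network): stacked blocks of
  Conv1d -> tanh -> BatchNorm -> adaptive average pooling.  The full
  architecture has seven blocks; pooled lengths are fixed by the spec
  (not the input), so output shapes are input-length invariant — this is
  what lets streams with different sampling rates share downstream
  layers.  Defaults: kernel 7, channels doubling from 16 capped at 64,
  pooled lengths halving to a floor of 16.
* **CN** (Classification Network): two fully connected layers reducing
  the flattened FEN output to a 256-dimensional feature vector, with an
  optional 8-way softmax layer.
* **Siamese classifier**: a single shared-weight embedder (FEN+CN) —
  weight sharing is exact, both "branches" are the same module.  Five
  reference trials per class are drawn from the training partition; a
  class's reference vector is the mean embedding of its references,
  recomputed as the embedder trains (gradients flow through references
  and samples).  The loss is contrastive cosine:
  `(1 - cos(f, r_y)) + 1/(C-1) * sum_{c!=y} max(0, cos(f, r_c) - m)`,
  margin `m = 0` by default.  Prediction is argmax cosine similarity to
  the reference vectors, ties to the lexicographically first label.
* **PMLDF** (parallel multi-layer data fusion): one FEN per sensor
  stream plus a central fusion stack of the same block type.  Fusion
  block l consumes the channel concatenation of the previous fusion
  output and every stream's block-l output, each adaptively pooled to the
  fusion block's length (concatenation rather than summation so streams
  with different channel counts compose, and a third stream is one more
  FEN).  The fused map feeds the CN with either the softmax or the
  Siamese head.

Training: Adam (lr 1e-3, batch 32), learning rate multiplied by 0.992
every 10 epochs (`lr(e) = lr0 * 0.992**(e//10)`, exact), early stopping
on validation accuracy with the best checkpoint restored.  The reference
patience is 150 epochs at up to 500 epochs; the desk-scale benchmark
configuration uses four FEN blocks, at most 100 epochs and patience 15,
which the synthetic benchmarks converge well inside.  Raw signals are
standardised per trial and Fourier-resampled before entering the
network: EMG to 1024 samples (content up to ~500 Hz must survive the
implied low-pass), PZT to 256 (content below ~100 Hz).  Runs are
deterministic given the seed: all randomness (init, batching, reference
choice) flows from `numpy.random.SeedSequence` substreams.

## Synthetic data

The generator emulates the qualitative structure of the recordings, not
their physiology.  EMG = enveloped band-limited Gaussian-noise bursts
(bands within ~40-500 Hz, Hann envelopes); PZT = exponentially decaying
sinusoids below 100 Hz; additive white noise floor at 20 dB SNR; default
trial length 1.0 s at 4096 Hz (the recording protocol does not state a
duration).  Per-trial jitter (default 10%) perturbs amplitudes and
onsets.  Each class has a template; `separability` in [0, 1] blends all
templates between a shared base and class-specific motifs, and the mean
inter-class feature distance is non-decreasing in it.

`channel_coupling_mode="cross_channel_only"` builds the fusion
benchmark: 8 classes from 4 EMG motifs x 4 PZT motifs with every motif
shared by exactly two classes, so either channel alone caps at 50%
accuracy while the motif *pair* determines the class.  Measured
single-channel accuracies sit at ~48-52% and the fused PMLDF model
recovers the class nearly perfectly, a gain of roughly 45-50 pp.

What passing these benchmarks does **not** show: performance on real
chin-sensor data.  The synthetic classes are cleanly separated by
construction (near-ceiling accuracies are expected and observed);
real recordings add electrode-contact drift, motion artefacts,
inter-session and inter-subject variability, and class overlap that no
parameter here models.  The benchmarks validate the machinery —
formulas, protocol integrity, optimisation, fusion wiring — not field
accuracy.

## Numerical and degenerate-input choices

* population variance can cancel catastrophically in the identity
  `var = rms^2 - mean^2` at large offsets; the package computes it
  directly from deviations;
* all-zero spectra raise instead of returning NaN frequency features;
  zero-norm embeddings raise instead of silently normalising;
* cosine normalisation adds 1e-12 inside the square root, bounding the
  loss identity error at ~1e-12;
* batch normalisation skips batches of size 1 (undefined batch variance);
* degenerate augmentation windows (< 2 samples) are redrawn, never an
  error; a constant signal makes noise/slope draws collapse to zero.

## Known limitations

* The autograd engine is single-threaded numpy; it is sized for the
  desk-scale benchmarks (minutes on one CPU), not for large inputs or
  deep stacks.
* FFT resampling is an ideal low-pass: spectral content above the target
  Nyquist is discarded, so `input_length` must be chosen per channel.
* The Google-Drive importer for the originally deposited recordings is
  out of scope; `read_dataset` accepts any manifest following the
  documented layout.
* SMOTE assumes each class has at least `k_neighbors + 1` samples and
  interpolates linearly; it cannot extrapolate beyond the class's convex
  hull.
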