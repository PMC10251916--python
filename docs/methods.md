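# Methods

## Problem setting

A tri-axial accelerometer fixed to a cow's left paralumbar fossa and
sampled at 5 Hz measures the gravity vector projected onto the sensor
axes plus body dynamics. With the cow standing, X is vertical, Y
parallel to the ground and Z orthogonal to the flank; lying rotates the
gravity projection from X towards Z. Five behaviours are classified:
feeding, moving, resting, ruminating and standing still. Spans where a
human observer could not assign a behaviour are labelled `unclear` and
excluded before modelling; `unclear` is never a model class.

## Feature representation

Each sample is expanded to 15 variables: raw X/Y/Z plus, per axis, the
rolling average and rolling sample standard deviation over the trailing
15 observations (3 s), the percentage change from the previous sample
and its binary sign indicator. Conventions:

- **Alignment.** Rolling metrics are trailing (causal), which keeps the
  representation streamable; the first `max(window−1, 1)` samples of a
  run are warm-up and emit no feature row (the percentage change is
  also undefined at a run's first sample, so warm-up is at least 1).
- **Standard deviation** uses the sample (n−1) denominator; the choice
  is configurable (`ddof`) and recorded in the frame metadata sidecar.
- **Percentage change** is made total: when the previous value's
  magnitude is below ε = 1e−12 the change is defined as 0 (binary 1).
  This avoids infinities on a still axis; the convention is recorded in
  the metadata.
- Features are computed per label-contiguous run, where a run boundary
  is a label change or an inter-sample gap exceeding 1.5× the nominal
  0.2 s period (configurable). Windows therefore never straddle a
  behaviour change or a recording gap.

## Observation units and split

Feature rows are cut into windows of 40 time-steps (8 s) advanced by a
stride of 13 (~33% of the window); each window inherits its run's
single behaviour. Units are split uniformly at random 80/20 into
training and testing sets, and all 15 columns are z-scored with the
training partition's mean and standard deviation only. Note that
overlapping windows share raw samples, so a window-level split leaks
information between partitions; held-out scores under this design are
optimistic relative to deployment on unseen animals. A stricter
`group_by_cow` split mode is provided as a clearly labelled deviation
for leakage-free estimates.

## Classifier

The reference network is an 8-layer sequential 1D CNN on (40, 15)
input: Conv1D(128, k=3) → Conv1D(64, k=3) → Conv1D(32, k=3), all valid
padding, stride 1, ReLU; Dropout(rate 0.3); MaxPool(pool 2,
non-overlapping); Flatten; Dense(100, ReLU); Dense(5, softmax). Valid
convolutions shorten the sequence 40 → 38 → 36 → 34; pooling halves it
to 17; flattening gives 544 = 17 × 32; the totals are 91,709 trainable
parameters. Two reference-summary inconsistencies are resolved by the
arithmetic itself: the first convolution must have 128 filters (its
output shape and parameter count 5888 = (3·15+1)·128 both require it),
and the output layer must be softmax to emit class probabilities.

Training uses categorical cross-entropy and Adam at the standard
framework defaults (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−7), batch size 32,
with the training set reshuffled every epoch. The reference schedule is
600 epochs; the package's desk-testing default is 30 epochs, which is
sufficient for convergence at the simulated data sizes used here
(~4,000 training units; at that size one epoch is 102 weight updates).
No early stopping and no validation split beyond the 80/20 partition
are used. Dropout is active only during training.

The network runs on the package's own NumPy backend: convolutions are
evaluated as one GEMM per layer over an im2col view, gradients are
derived analytically (the transposed convolution for the input gradient
is itself expressed as a strided GEMM), and everything is computed in
float32. Weight initialisation is Glorot uniform with zero biases. A
single training-run seed fans out (via independent spawned generators)
to weight initialisation, dropout masks and epoch shuffling, making
runs bit-reproducible; the data split carries its own seed.

**Architecture audit.** `model.audit()` computes every layer's output
shape and parameter count purely from the layer hyperparameters
(L′ = L − k + 1 for valid convolution, ⌊L/p⌋ for pooling,
(k·C_in+1)·C_out and (n_in+1)·n_out for the weighted layers).
`fit()` refuses to train unless this analytic count equals the
parameter count of the instantiated weight arrays — two independent
computations that catch silent drift between declaration and network.

## Evaluation

Confusion-matrix rows are actual classes and columns predicted, in the
fixed order (feeding, moving, resting, ruminating, standing_still), so
row sums equal per-class supports. Per class: precision TP/(TP+FP),
recall TP/(TP+FN), F1 = 2pr/(p+r); overall accuracy is the matrix trace
over the total; macro averages are unweighted means and weighted
averages use class supports as weights (the informative summary under
class imbalance). A class absent from both streams has undefined (0/0)
metrics; these are reported as 0 with an explicit `undefined` flag.
Printed tables round half-up to two decimals; JSON output keeps full
precision. The micro-averaged precision/recall/accuracy identity is
used as an internal consistency check in the test suite, alongside an
independent scikit-learn cross-check.

## Synthetic trace generator

The simulator is parametric and transparent rather than learned: its
purpose is pipeline verification and controlled benchmarking, not
biomechanical fidelity. Per behaviour it draws

- a mean orientation vector (g-equivalents on X/Y/Z) plus a per-bout
  Gaussian orientation offset (`orient_jitter`) modelling posture
  variability between bouts,
- i.i.d. Gaussian sensor noise per axis,
- optionally a sinusoidal oscillation (chewing/rumination cycle,
  1.1–1.2 Hz, below the 2.5 Hz Nyquist limit; phase resampled per bout
  so overlapping windows differ and no global phase can be memorised),
- optionally a Poisson burst process (half-sine transients, random
  sign and scale) for steps and body movements.

Schedules alternate behaviours with no immediate repeats; class
imbalance is carried entirely by gamma-distributed bout durations whose
means are proportional to the observed time shares (resting 31%,
standing still 20%, moving 18%, feeding 18%, ruminating 12% of clear
time), never by discarding windows. About 7% of time is emitted as
`unclear` bouts to exercise the exclusion stage, mirroring the gap
between raw and usable recording time in the study design the defaults
mirror (12 cows, ~136 min each; the desk benchmark uses 4 cows × 55 min
≈ 4,000 units so a full run stays in the minutes range on a laptop
core).

Two fixed difficulty profiles:

- **separable** — every class has a distinct orientation and distinct
  dynamics and no orientation jitter; near-perfect classifiability by
  construction. Used to verify that the pipeline and optimizer can
  drive held-out macro F1 ≥ 0.90 under the desk profile.
- **realistic** — the three standing-family classes share the standing
  orientation within jitter and differ only in dynamics (feeding's
  oscillation, moving's bursts) partly masked by noise, and ruminating
  is modelled lying with resting's orientation, distinguishable only
  through its weak ~1.1 Hz oscillation. This reproduces the structure
  of real confusions: resting scores best, the standing family and
  ruminating absorb the errors.

What passing benchmarks on these profiles shows: that features,
windowing, training and evaluation are wired correctly and that the
network can exploit orientation, spectral and burst cues at realistic
noise levels. What it does not show: performance on real cows — real
signals contain drift, within-bout posture changes, individual
variation and observer labelling error that the generator deliberately
omits, and the window-level split leaks as described above.

## Numerical and degenerate-input conventions

- Runs shorter than the rolling window emit an empty feature frame
  with a warning; runs shorter than 40 feature rows yield no units.
- Feature tensors and normalization statistics are float64 (training
  casts to float32 once); z-scoring the training set is idempotent to
  machine precision. A feature column constant across the training set
  would have its sd clamped to 1 with a warning.
- Unparseable numeric rows in a CSV are logged, counted and skipped;
  non-monotone timestamps abort with the first offending row named;
  a missing configured column is a configuration error.
- Max pooling discards a trailing remainder that does not fill a
  window (valid padding); ties in pooling take the first maximum.
- `epochs=0` is valid and yields predictions from the initialised
  weights with an empty learning curve.

## Known limitations

- The simulator's realism is limited by design (see above); absolute
  benchmark scores should not be read as field performance.
- The backend is single-threaded NumPy; it is sized for the desk
  profile, not for multi-million-unit datasets.
- The 600-epoch reference schedule is supported but not exercised by
  the default test suite.
- No resampling: input must be 5 Hz; non-5 Hz data should be resampled
  upstream.
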