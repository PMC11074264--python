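# Methods

## Problem and pipeline

The package decodes two binary emotion labels — valence (pleasant vs
unpleasant) and arousal (calm vs excited) — from short segments of
multichannel EEG. The input convention follows the public DEAP
preprocessed distribution: one block per subject of shape
`(n_trials, n_channels, n_samples)` sampled at 128 Hz, with a 1–9
self-assessment rating per trial and dimension. Ratings are binarized at a
configurable threshold (default 5.0, `rating >= threshold` → "high"); the
threshold is exposed because the 1–9 scale has no canonical cut.

The pipeline is:

1. **Channel selection.** A 1-based index list; the default analysis set is
   the 14-channel subset (1, 2, 3, 4, 6, 11, 13, 17, 19, 20, 21, 25, 29, 31)
   conventionally used for band-power emotion decoding.
2. **Windowed band power.** Each trial is cut into windows of
   `window_size` samples with hop `step` (default 50% overlap); windows
   start at 0, step, 2·step, … while the full window fits, giving
   `floor((n_samples − window_size)/step) + 1` windows per trial. Each
   window/channel is DFT-transformed and summarised as the mean of
   |X_k|² over the bins of five bands: theta 4–8, alpha 8–12, low-beta
   12–16, high-beta 16–25, gamma 25–45 Hz. Bands are half-open `[lo, hi)`
   so shared edges are not double-counted. Windows shorter than
   `min_fft_len` (default 256 samples) are zero-padded to that FFT length
   before binning, so every band keeps a non-empty bin set even for
   windows of 4 samples; this is what makes the published window-size
   sweep {4, 8, …, 128} executable at 128 Hz. A single-window periodogram
   without taper is used; the windows are short and the features are
   band averages, so leakage control is left to the band widths. An
   optional zero-phase 4–45 Hz Butterworth pre-filter is off by default
   (distributed DEAP data is already band-limited).
3. **Classification** by the convolutional fuzzy network below, one model
   per emotion dimension.

## The network

Input is one feature row treated as a length-`input_len` sequence with one
channel. The default `input_len` is 73 for fidelity to the reference
parameter ledger; 14 channels × 5 bands give 70 features, and the adapter
right-pads rows with zeros up to `input_len` (configurable off). The layer
stack is

| layer | output | parameters |
|---|---|---|
| Conv1D, 64 filters, kernel 5, same, ReLU | (73, 64) | 384 |
| Conv1D, 32 filters, kernel 3, same, ReLU | (73, 32) | 6 176 |
| MaxPool, size 2 | (36, 32) | 0 |
| Flatten | 1152 | 0 |
| Fuzzify, 2 rules | 2 | 4 608 |
| BatchNorm | 2 | 8 (4 non-trainable) |
| Dense, 2 units, softplus | 2 | 6 |
| Defuzzify | 2 | 4 |
| Softmax | 2 | 0 |

totalling 11 186 parameters (11 182 trainable). The kernels are 1-D
(length 5 and 3): the printed conv parameter counts (384 = 64·5·1 + 64,
6176 = 32·3·64 + 32) admit no other reading, and the flatten width 1152 =
floor(73/2)·32 forces 'same' padding with pool 2.

**Fuzzification.** Each of the 1152 flattened features `x_i` has a Gaussian
membership per rule, `exp(−(x_i − m_ij)²/(2σ_ij²))` (singleton
fuzzification: the membership evaluated at the observed crisp value). The
per-rule firing strength aggregates all input memberships. A raw product of
1152 factors in (0, 1] underflows, so the default aggregation is the
geometric mean computed in the exponent domain,
`strength_j = exp(−e_j/n)` with `e_j = Σ_i (x_i − m_ij)²/(2σ_ij²)`; a
log-domain max-shifted product (`exp(−(e_j − min_k e_k))`) is available as
an alternative. Both keep strengths in (0, 1], preserve rule ordering, and
are differentiable; the batch-norm that follows absorbs the overall scale.
Widths are reparameterized as `σ = softplus(ρ) + 10⁻³` so gradient descent
cannot drive them to zero. The fuzzy parameter count, 1152 × 2 rules × 2
(mean, width) = 4608, matches the ledger.

**Defuzzification.** Centre-of-gravity with learned centres:
`ν_k = Σ_j C_kj x_j / (Σ_j x_j + ε)`, ε = 10⁻⁹. For nonnegative inputs the
output lies in the hull of the centres and is invariant to positive
rescaling of the activations; an all-zero activation maps to zero rather
than dividing by zero. The C matrix (2×2 here) contributes the final 4
parameters. Softmax over ν with categorical cross-entropy closes the model.

### Numerical choices that mattered

Three choices are deliberate departures from the "obvious" defaults, each
forced by observed optimisation failures on the synthetic task:

- **Activations.** The layer recipe names no intermediate activations. With
  purely linear conv/dense layers the dense output is signed and the
  defuzzification denominator `Σx + ε` crosses zero, which makes the logit
  map discontinuous across samples; the head then cannot fit even trivially
  separable 2-D data and training settles at the uniform-output plateau
  (loss = log 2). ReLU on the conv layers and **softplus on the dense
  layer** fix this: softplus keeps both rule activations strictly positive,
  so the denominator never vanishes and no unit can die. (ReLU on the dense
  layer works when both units stay alive, but with only two units a dead
  unit freezes the logits to a constant — observed as one-sided prediction
  collapse in some folds.) Activations add no parameters, so the ledger is
  unaffected.
- **Initialisation.** Conv and dense weights use fan-in-scaled (LeCun)
  uniform initialisation rather than fan-average (Glorot). The
  fuzzification layer is initialised with means ~ N(0, 1) and σ = 1, which
  presumes unit-scale inputs; fan-average initialisation let flatten
  activations reach ±40, driving every rule strength to ~e⁻⁵⁰ and all
  gradients through the exponent to numerical zero. Fan-in scaling keeps
  the flatten activations near unit variance at initialisation.
  Defuzzification centres start at N(0, 0.1).
- **Feature scaling.** Band powers span orders of magnitude, so the input
  adapter standardises features with mean/SD fitted on the training split
  (stored with the model for inference).

Batch-norm uses momentum 0.99 and ε = 10⁻³ (common deep-learning framework
defaults); its four per-feature quantities (scale, shift, moving mean,
moving variance) account for the 4 non-trainable parameters.

## Training and evaluation

Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) with learning rate 0.01, batch size
256, 100 epochs, no early stopping or schedule. All randomness —
initialisation and epoch shuffling — derives from the config seed, so a
fixed seed reproduces weights, history, feature tables and evaluation
reports byte for byte. Labels are one-hot with a 2-way softmax; one model
is trained per emotion dimension.

Evaluation offers stratified hold-out (default 75:25) and stratified
k-fold (default k = 5), both seeded, with sklearn's splitters behind the
package API. Metrics are accuracy, precision, recall and F1 from the
binary confusion counts (positive class = "high"); zero-denominator ratios
are reported as 0 and flagged rather than raised. The confidence interval
on a proportion is the normal-approximation binomial interval
p̂ ± z·√(p̂(1−p̂)/n) clipped to [0, 1] — the published intervals' widths are
consistent with a per-test-set binomial interval, and no resampling
protocol is invented. K-fold aggregates metrics as the unweighted mean
over folds (with pooled confusion counts reported); splits are pooled
across windows, not grouped by subject — a `group-by-subject` protocol is
a possible extension, and window-level splitting means windows of one
trial can appear on both sides of a split, which inflates absolute
accuracies on real data.

## Synthetic data: what it does and does not emulate

`SyntheticSpec`/`generate_dataset` produce DEAP-shaped recordings in which
each trial carries a binary class per dimension; each class has a
band-power profile (default: class 0 alpha-dominant, class 1
gamma-dominant — disjoint bands, so the classes are separable in feature
space). Signals are sums of band-limited sinusoids (3 tones per active
band, random frequencies and phases per channel) over 1/f-shaped noise
obtained by spectral shaping of white noise (noise SD 0.1 by default, a
low-noise regime relative to unit tone amplitudes). Ratings are drawn
uniformly from the side of the threshold matching the class, so
binarization recovers the ground truth exactly. The default scale —
8 trials × 16 channels × 8 s at 128 Hz — runs the full pipeline in seconds.

This emulates the *structure* of the real data and a clean spectral
separation between classes. It does not emulate volume conduction,
channel-specific topographies, artifacts (EOG/EMG), non-stationarity, or
the weak and distributed class differences of real EEG. Passing the
synthetic-recovery tests therefore shows the pipeline is implemented
correctly and can learn a genuine band-power contrast; it does not certify
any accuracy level on real recordings.

## Degenerate inputs and tie-breaks

- Windows never span trial boundaries; a window equal to the trial length
  yields exactly one window per trial.
- A band containing no FFT bin contributes 0 power (only possible when
  min-FFT-length padding is disabled).
- Rating exactly at the threshold binarizes to "high" (≥ rule).
- Max-pool drops a trailing odd element (floor division), matching the
  73 → 36 shape arithmetic.
- `metrics` flags rather than raises on empty positive predictions;
  `defuzzify` of an all-zero vector returns zeros.
- Stratified splits require at least 2 members per class; k > n is
  rejected; fold sizes differ by at most one.

## Problem sizes used in the shipped experiments

The test-suite and acceptance experiments use the default synthetic scale
(8 trials × 16 channels × 8 s; window 32, step 16 → 504 windows of 70
features) and the full 100-epoch schedule; a hold-out evaluation trains in
well under a minute on one CPU core. These sizes were chosen as the
smallest at which every stage (overlapping windows, batching at 256,
stratified folds) is exercised non-trivially.

## Known limitations

- The 73-feature default input is ledger-faithful but 3 columns wider than
  the 70 extracted features; the zero-pad adapter is a documented stand-in
  for an unexplained discrepancy.
- Only Gaussian memberships and two aggregation rules are implemented; no
  triangular/trapezoidal families, no rule extraction.
- Binary heads only; no multiclass emotion labels.
- No subject-grouped splitting (see above); reported synthetic accuracies
  are window-level.
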