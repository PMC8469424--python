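# Methods and numerical conventions

This document records exactly what the code computes: model definitions,
how the reference configurations were determined, estimator conventions,
the synthetic generator's scope, and known limitations. All quantitative
statements here are produced by code in this repository (tests or the
acceptance script); nothing below is an empirical claim about real clinical
data.

## 1. Data pipeline

**Input convention.** A dataset directory contains `ptbxl_database.csv`
(one row per record, indexed by `ecg_id`, with a serialized `scp_codes`
mapping from SCP statement code to likelihood percentage and a `filename_lr`
path), `scp_statements.csv` (per-code `diagnostic` flag,
`diagnostic_subclass`, `diagnostic_class`), and WFDB format-16 records of
12 channels × 1000 samples at 100 Hz in millivolts.

**Filtering** applies three rules in order:
1. keep records with at least one *diagnostic* statement;
2. keep records whose diagnostic statements all have likelihood exactly 100;
3. census the diagnostic subclasses over the survivors and keep records whose
   subclasses all have at least 20 records.

**Labeling.** `binary` maps superclasses to NORM/ABNORM; `super5` uses the
five superclasses; `sub20` uses subclasses. Records whose diagnostic codes
map to more than one distinct label under the active scheme are excluded —
every retained record has exactly one label.

**Splitting** is stratified 70/15/15 by class: train receives
`floor(0.70·n)` records, the remainder is split evenly between validation
and test with validation taking the floor. Each split therefore deviates
from its exact proportion by at most one record per class. The shuffle is
driven by `numpy.random.default_rng(seed)`; identical seeds give identical
splits.

**Normalization.** Signals are z-scored per channel; constant channels map
to zeros.

## 2. Entropy features

Nine estimators per channel, 12 channels → a 12×9 matrix, flattened
channel-major into 108 features. Logarithms are base 2 (bits) except where
noted. Defaults: 16 equal-width histogram bins; embedding dimension m = 2
with tolerance r = 0.2·SD for ApEn/SampEn; permutation order 3, delay 1;
SVD embedding order 3, delay 1; Rényi α = 2; Tsallis q = 2.

* **Shannon / Rényi / Tsallis / extropy** operate on the equal-width
  histogram of channel amplitudes over [min, max]. Tsallis entropy
  `(1 − Σpᵠ)/(q − 1)` is in natural units. Extropy is
  `−Σ(1−p)·log₂(1−p)`.
* **Approximate entropy** follows the Pincus convention: Chebyshev distance,
  self-matches included, Φ_m over n−m+1 templates minus Φ_{m+1} over n−m
  templates.
* **Sample entropy** excludes self-matches (`−log(A/B)` over the first n−m
  templates). When A or B is zero, the documented finite stand-in for +∞ is
  `log((n−m)(n−m−1))`, the log of the number of comparable pairs.
* **Permutation entropy** uses stable argsort so ties break by index order.
* **Spectral entropy** is the Shannon entropy of the normalized periodogram
  divided by `log₂(#bins)` (range [0, 1]).
* **SVD entropy** is the normalized entropy of the singular-value spectrum
  of the delay-embedding matrix.

Constant channels short-circuit ApEn/SampEn to 0 (their match radius is 0).
ApEn/SampEn pair counting has two implementations that are tested to agree
exactly: a vectorized NumPy reference and a numba-compiled loop used for
n ≥ 256 (~10× faster; ~70 ms per 12×1000 record).

In the two-branch model the 108 features are z-scored with
**training-split statistics**; the scaler is persisted in the checkpoint
sidecar and re-applied at evaluation. Without this the heterogeneous feature
scales (SampEn's cap ≈ 13.8 vs. Tsallis ≤ 1) stall optimization.

**Stationarity screen.** `adf_stationary_fraction` runs an augmented
Dickey–Fuller test per channel (statsmodels; constant regression, no trend,
lag order by AIC up to 10) and counts a record as stationary only if every
channel rejects the unit-root null at the 5% level.

## 3. Architectures and the parameter-budget solver

The target totals for the two small families are affine in the class
count K, which pins their head structure:

* convnet: `total = 6,832 + 1,025·K` → the softmax head sees 1,024
  features, i.e. 64 channels × 16 pooled time bins;
* entropy convnet: `total = 58,124 + 27·K` → the last hidden layer has 26
  units.

`solve_budget` verifies the affine law across all given class counts, then
enumerates non-decreasing conv-width tuples and a small kernel menu in a
fixed deterministic order until the backbone budget is met exactly. The
first solutions are the committed reference configurations:

* **ConvNet** — widths (12, 12, 12, 12, 64), kernel 5, stride 2, 'same'
  padding, LeakyReLU(0.01), adaptive average pool to 16 bins, one dense
  softmax head. Totals 8,882 / 11,957 / 27,332 for K = 2/5/20.
* **EntropyConvNet** — widths (12, 12, 12, 12, 20), kernel 5, stride 2. Each
  stage adds a residual taken from the raw input average-pooled (window 2,
  ceil mode) to the stage's temporal length; where widths differ from the
  12 input channels a 1×1 projection (Dense 12→w) is used, identity
  otherwise. Output pooled to 16 bins, flattened (320) and concatenated with
  the 108 entropy features → Dense 428→118 → 118→26 → 26→K, dropout 0.2
  before each dense layer (inverted dropout; identity at evaluation).
  Totals 58,178 / 58,259 / 58,664.
* **SincNetClassifier** — the target totals for this family are mutually
  inconsistent (the same number appears for two different class counts,
  impossible with any K-dependent output layer), so they are treated as a
  magnitude target (~6.1 M) rather than an exact constraint. Reference:
  per channel, SincLayer (16 filters, L = 129, stride 4) → two conv stages
  (width 16, kernel 9, stride 2) each followed by layer normalization and
  LeakyReLU → adaptive average pool to 16 bins → dense 256→960→256→32 with
  batch normalization → shared head Dense(12·32→64→K). Total 6,123,074 + 65·(K−2).
  Pooling before the dense stack is a deliberate design choice: without it
  the 6.1 M-parameter network memorizes small training sets at sample-level
  resolution and does not generalize.

### Sinc layer conventions

Kernel `g[n] = 2f₂·sinc(2πf₂n) − 2f₁·sinc(2πf₁n)` on the symmetric integer
tap grid of odd length L, with `sinc(0) = 1`; frequencies are in cycles per
sample (Nyquist 0.5). The kernel is exactly even-symmetric, so convolution
equals correlation (zero phase). No tapering window is applied by default
(a Hamming option exists). The trainable tensor is the raw cutoff pair,
mapped through `f₁ = |r₁|`, `f₂ = f₁ + |r₂ − r₁|`, both clipped at 0.5;
cutoff gradients use the analytic derivative `∂g[n]/∂f = ±2·cos(2πfn)` with
sign/clip masks for the reparameterization. Banks are initialized as
contiguous mel-scale bands (`mel(f) = 2595·log₁₀(1 + f/700)`) covering
(0, Nyquist].

## 4. Training and evaluation

Adam (β₁ = 0.9, β₂ = 0.999, bias-corrected), batch size 128, cross-entropy
on softmax probabilities (clipped at 1e−12). The learning rate starts at
1e−3 and drops once to 1e−4 after 5 epochs without validation-loss
improvement; training stops after 10 non-improving epochs, and the weights
of the best-validation-loss epoch are restored. All randomness (shuffling,
initialization, dropout) flows from `numpy.random.default_rng(seed)`, so a
config + seed reproduces a run exactly.

Metrics: accuracy; macro one-vs-rest precision, recall, F1 (zero-division
counts as 0); macro one-vs-rest ROC AUC computed by a threshold sweep with
trapezoidal area, which equals the Mann–Whitney statistic with ties counted
as ½ (cross-checked against scikit-learn in the tests).

## 5. Synthetic ECG generator — scope

The generator exists to exercise the pipeline and to provide a learnable
testbed, **not** to simulate clinical ECGs. One scalar base waveform per
record (Gaussian P and T waves, piecewise Gaussian Q-R-S, sigmoid-edged ST
plateau, heart rate drawn per record) is projected onto 12 leads by fixed
scale factors (aVR negated), then corrupted by sinusoidal baseline wander
and white Gaussian noise (0.04 mV). Class identity enters through morphology
deltas chosen to be physiologically *directionally* plausible (MI: deep Q,
ST depression; STTC: inverted T, ST shift; CD: widened QRS; HYP: tall R)
and large relative to the noise floor, so the classes are separable by
design. The generator also plants records violating each filter rule
(sub-100 likelihoods, rhythm-statement-only records, a rare WPW subclass)
so the filter logic is testable end to end. Per-record seeds derive from a
single root generator; a fixture is a pure function of its spec.

## 6. Numerical choices

* Everything is float64 NumPy; convolutions use im2col with einsum
  contractions; conv input gradients use the dilated-output transposed
  convolution.
* Average pooling uses ceil mode (the last partial window repeats the final
  sample boundary); adaptive average pooling uses the standard
  `floor(i·n/t)..ceil((i+1)·n/t)` bin edges.
* `np.trapezoid` integrates the ROC curve.
* WFDB writing uses gain 1000 (quantization error ≤ 0.0005 mV); checksums
  are the int16-wrapped sample sums and are verified on read.

## 7. Limitations

* The synthetic classes are far easier than real diagnostic classes; the
  ≥ 0.90 validation-accuracy acceptance checks demonstrate that the training
  machinery works, not clinical performance.
* The SincNet family's exact target totals cannot be reproduced because
  they are internally inconsistent; only the magnitude is matched.
* The NumPy implementation is CPU-bound; full-corpus training (~17k records)
  is possible but slow, and no GPU path is provided.
* The budget solver searches a restricted, documented menu of widths and
  kernels; it re-derives the committed configurations deterministically but
  is not a general architecture-search tool.
* The trainable sinc layer passes no gradient to its input, so it is only
  usable as a first layer.
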