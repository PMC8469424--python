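# ecgnets

Classification of 12-lead electrocardiograms with three small neural-network
families — a parameter-budgeted plain 1-D convolutional network, a trainable
sinc band-pass filter bank (SincNet-style) front end, and a two-branch network
that fuses convolutional features with nine per-channel entropy measures —
plus a complete, deterministic data pipeline for PTB-XL-style datasets and a
synthetic ECG generator for offline development and testing.

Everything is implemented in NumPy, including forward and backward passes,
so the package runs on a single CPU with no deep-learning framework.

## Science

Resting 12-lead ECGs are short (here 10 s at 100 Hz) multichannel time
series whose diagnostic content lies in waveform morphology: the P wave, the
QRS complex, the ST segment and the T wave. The package targets three label
granularities derived from SCP diagnostic statements:

* **binary** — normal (NORM) vs. abnormal,
* **super5** — five diagnostic superclasses: NORM, myocardial infarction
  (MI), ST/T change (STTC), conduction disturbance (CD), hypertrophy (HYP),
* **sub20** — the diagnostic subclasses that survive a census threshold.

Three model families probe different inductive biases at matched problem
sizes:

1. **`convnet`** — five 1-D convolutions (kernel 5, stride 2) feeding a
   single softmax head through an adaptive average pool. Its configuration is
   pinned so the trainable-parameter totals are exactly **8,882 / 11,957 /
   27,332** for 2/5/20 classes (an affine law `6,832 + 1,025·K`).
2. **`entropy`** — a two-branch network: the same signal is encoded by five
   stride-2 convolutions with pooled-raw residual connections, flattened and
   concatenated with **108 entropy features** (9 estimators × 12 leads:
   Shannon, approximate, sample, permutation, spectral, SVD, Rényi, Tsallis
   entropy and extropy), then passed through three fully connected layers.
   Totals are exactly **58,178 / 58,259 / 58,664** (`58,124 + 27·K`).
3. **`sincnet`** — twelve weight-independent per-channel blocks whose first
   layer is a bank of 16 trainable sinc band-pass filters
   `g[n] = 2f₂ sinc(2πf₂n) − 2f₁ sinc(2πf₁n)` with mel-scale initialization;
   each block pools to 16 time bins and feeds fully connected layers with
   batch normalization; a shared head combines the twelve block outputs
   (≈ 6.1 M parameters).

The exact small-network configurations are *re-derived*, not hard-coded: the
budget solver (`ecgnets solve-budget`, `architectures.solve_budget`) pins the
head width from the per-class parameter increment and enumerates conv stacks
until the target totals are matched exactly. Entropy features are
justified by a stationarity screen: `entropy.adf_stationary_fraction` runs an
augmented Dickey–Fuller test per channel (constant regression, AIC lag
selection) and counts records whose channels all reject the unit-root null.

## Worked example

Generate a synthetic dataset in the PTB-XL on-disk layout (metadata CSV, SCP
statement table, WFDB format-16 records) and train the plain convnet on the
binary task. The generator plants rule-breaking records (sub-100% likelihood
statements, rhythm-only records, a rare subclass) that the filter stage must
remove:

```
$ ecgnets make-fixtures --out fixture --counts "NORM=256,MI=128,CD=128" --seed 7
wrote fixture metadata to fixture/ptbxl_database.csv

$ cat config.yaml
scheme: binary
family: convnet
seed: 1
train:
  max_epochs: 30

$ ecgnets run --data-root fixture --config config.yaml --out run_out
epoch   0  train_loss 0.6971  val_loss 0.6957  val_acc 0.474  lr 0.001
epoch   1  train_loss 0.6892  val_loss 0.6935  val_acc 0.487  lr 0.001
...
epoch  28  train_loss 0.0004  val_loss 0.0007  val_acc 1.000  lr 0.001
epoch  29  train_loss 0.0004  val_loss 0.0006  val_acc 1.000  lr 0.001
{
  "accuracy": 1.0,
  "precision": 1.0,
  "recall": 1.0,
  "f1": 1.0,
  "auc": 1.0,
  "total_params": 8882
}
```

(Output from this exact command sequence; the run takes ~17 s on one CPU.)
`run_out/` now holds `metrics.json` (with the config hash), `confusion.csv`,
`history.csv`, `manifest.csv` and a reloadable `checkpoint.npz/.json` pair.
The same config and seed reproduce the run bit-for-bit. Swap
`family: entropy` or `family: sincnet` to train the other models, and use
`ecgnets evaluate --checkpoint run_out/checkpoint --data-root fixture` to
re-score a saved model on its test split.

The reference architectures and their exact totals:

```
$ ecgnets solve-budget
convnet: ConvNetConfig(widths=(12, 12, 12, 12, 64), kernel=5, stride=2, pool_to=16)
   2 classes -> 8,882 parameters
   5 classes -> 11,957 parameters
  20 classes -> 27,332 parameters
entropy: EntropyConvNetConfig(widths=(12, 12, 12, 12, 20), kernel=5, pool_to=16, hidden1=118, hidden2=26, dropout_p=0.2)
   2 classes -> 58,178 parameters
   5 classes -> 58,259 parameters
  20 classes -> 58,664 parameters
sincnet: SincNetConfig(n_filters=16, kernel_length=129, sinc_stride=4, conv_width=16, conv_kernel=9, conv_stride=2, pool_to=16, fc_sizes=(960, 256, 32), shared_hidden=64)
   2 classes -> 6,123,074 parameters
   5 classes -> 6,123,269 parameters
  20 classes -> 6,124,244 parameters
```

## Using a real PTB-XL download

Point `--data-root` at a directory containing `ptbxl_database.csv`,
`scp_statements.csv` and the 100 Hz `records100/` tree. The pipeline applies
the three filter rules in order (diagnostic statement present → all
diagnostic likelihoods exactly 100 → all subclasses with ≥ 20 records),
assigns one label per record (multi-label records are dropped per scheme),
and makes a stratified 70/15/15 split.

## Reproduction

* `python -m pytest -q tests/` — full suite: estimator oracles (brute-force
  ApEn/SampEn, FFT band-energy checks, sklearn metric cross-checks),
  finite-difference gradient checks for every layer and the full two-branch
  model, pipeline determinism, CLI integration, and the acceptance criteria
  (exact parameter counts; ≥ 0.90 validation accuracy for all three families
  on a synthetic binary task within 30 epochs; filter/split behavior).
  Runs in under 5 minutes on one CPU.
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json` —
  re-derives the six reference parameter totals from scratch via the budget
  solver and writes them as JSON. Deterministic; seconds.

## Package layout

| module | contents |
| --- | --- |
| `ecgnets.dataset` | metadata loading, filter rules, labeling, stratified split, normalization |
| `ecgnets.io_wfdb` | WFDB format-16 reader/writer (checksum-verified) |
| `ecgnets.entropy` | nine entropy estimators, 12×9 feature matrix, ADF screen |
| `ecgnets.sincnet` | sinc kernels, mel initialization, trainable `SincLayer` |
| `ecgnets.nn` | NumPy layers (conv, dense, norms, pooling, dropout, softmax) and Adam |
| `ecgnets.architectures` | the three model families and the budget solver |
| `ecgnets.train` | training loop (lr schedule, early stopping) and metrics |
| `ecgnets.synthetic` | deterministic 12-lead ECG fixture generator |
| `ecgnets.pipeline` / `ecgnets.cli` | end-to-end experiments, checkpoints, CLI |

See `docs/methods.md` for the numerical conventions, estimator definitions
and design limitations.
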