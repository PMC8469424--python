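"""Training loop and evaluation metrics.

Training uses Adam on mini-batches of 128 examples with cross-entropy loss.
The learning rate starts at 0.001 and drops to 0.0001 once the validation
loss stops improving for ``lr_patience`` epochs; training stops after
``early_stop_patience`` further non-improving epochs and the weights of the
best-validation-loss epoch are restored.

Evaluation reports accuracy plus macro-averaged one-vs-rest precision,
recall, F1 and ROC AUC, alongside the trainable-parameter total.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, cross_entropy
from .architectures import count_parameters, predict_classes

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "MetricsReport",
    "train",
    "evaluate",
    "confusion",
    "metrics",
    "auc_macro",
]


@dataclass
class TrainConfig:
    batch_size: int = 128
    lr_initial: float = 1e-3
    lr_final: float = 1e-4
    lr_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.lr_final >= self.lr_initial:
            raise ValueError("lr_final must be below lr_initial")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    total_params: int

    def to_dict(self) -> dict:
        return asdict(self)


def _forward(model, inputs, training):
    return model.forward(inputs, training=training)


def _slice_inputs(inputs, idx):
    if isinstance(inputs, tuple):
        return tuple(np.asarray(part)[idx] for part in inputs)
    return np.asarray(inputs)[idx]


def _n_examples(inputs) -> int:
    return len(inputs[0]) if isinstance(inputs, tuple) else len(inputs)


def _snapshot(model):
    return [p.value.copy() for p in model.params()]


def _restore(model, snap):
    for p, v in zip(model.params(), snap):
        p.value[...] = v


def train(model, train_inputs, y_train, val_inputs, y_val,
          config: TrainConfig | None = None,
          log=None) -> TrainHistory:
    """Train ``model`` in place; returns the per-epoch history.

    ``*_inputs`` is either an (N, 12, 1000) signal array or a tuple
    (signals, entropy_features) for the two-branch family.
    """
    config = config or TrainConfig()
    n = _n_examples(train_inputs)
    if n == 0 or _n_examples(val_inputs) == 0:
        raise ValueError("empty training or validation split")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr_initial)
    history = TrainHistory()
    best_val = np.inf
    best_snap = _snapshot(model)
    since_improve = 0
    lr_dropped = False

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _slice_inputs(train_inputs, idx)
            probs = _forward(model, xb, training=True)
            loss, gprobs = cross_entropy(probs, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            opt.zero_grad()
            model.backward(gprobs)
            opt.step()
            losses.append(loss)
        val_probs = _forward(model, val_inputs, training=False)
        val_loss, _ = cross_entropy(val_probs, y_val)
        val_acc = float((predict_classes(val_probs) == y_val).mean())
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val_loss))
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(opt.lr)
        if log:
            log(f"epoch {epoch:3d}  train_loss {history.train_loss[-1]:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.3f}  lr {opt.lr:g}")
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_snap = _snapshot(model)
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if not lr_dropped and since_improve >= config.lr_patience:
                opt.lr = config.lr_final
                lr_dropped = True
            if since_improve >= config.early_stop_patience:
                break
    _restore(model, best_snap)
    return history


def evaluate(model, inputs, y_true, n_classes: int) -> tuple[MetricsReport, np.ndarray]:
    """Returns (metrics report, confusion matrix) for a fitted model."""
    probs = _forward(model, inputs, training=False)
    y_pred = predict_classes(probs)
    cm = confusion(y_true, y_pred, n_classes)
    report = metrics(cm)
    try:
        report.auc = auc_macro(y_true, probs, n_classes)
    except ValueError:
        report.auc = float("nan")
    report.total_params = count_parameters(model)
    return report, cm


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K counts; rows are true classes, columns predicted classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy and macro one-vs-rest precision/recall/F1 from a confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1).astype(np.float64)
    predicted = cm.sum(axis=0).astype(np.float64)
    if (support == 0).any():
        warnings.warn("zero-support class contributes 0 to macro averages",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=float(precision.mean()),
        recall=float(recall.mean()),
        f1=float(f1.mean()),
        auc=float("nan"),
        total_params=0,
    )


def _binary_auc(y: np.ndarray, score: np.ndarray) -> float:
    """ROC AUC by threshold sweep over the scores (trapezoidal area).

    Equals the Mann-Whitney pairwise statistic with ties counted as 1/2.
    """
    order = np.argsort(-score, kind="stable")
    y = y[order]
    s = score[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct].astype(np.float64)
    fps = (distinct + 1) - tps
    n_pos = tps[-1]
    n_neg = fps[-1]
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def auc_macro(y_true, probs, n_classes: int) -> float:
    """Macro-averaged one-vs-rest ROC AUC from class-probability rows."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probs)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for a single-class truth vector")
    aucs = []
    for k in range(n_classes):
        yk = (y_true == k).astype(np.int64)
        if yk.sum() == 0 or yk.sum() == len(yk):
            continue
        aucs.append(_binary_auc(yk, probs[:, k]))
    return float(np.mean(aucs))
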