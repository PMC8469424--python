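"""End-to-end experiment pipeline: load -> filter -> label -> split ->
normalize -> (entropy features) -> train -> evaluate, with artifacts.

The pipeline is fully reproducible from one :class:`ExperimentConfig`: the
same config and seed yield identical splits, initial weights, batch order and
therefore identical metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import architectures, dataset, train as train_mod
from .entropy import EntropyConfig, entropy_matrix
from .train import TrainConfig

__all__ = ["ExperimentConfig", "run_experiment", "prepare_manifest",
           "compute_feature_table", "save_checkpoint", "load_checkpoint"]

FAMILIES = ("convnet", "sincnet", "entropy")


@dataclass
class ExperimentConfig:
    data_root: str = "."
    scheme: str = "binary"          # binary | super5 | sub20
    family: str = "convnet"         # convnet | sincnet | entropy
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)

    def __post_init__(self) -> None:
        if self.scheme not in dataset.SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "entropy" in d and isinstance(d["entropy"], dict):
            d["entropy"] = EntropyConfig(**d["entropy"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def prepare_manifest(config: ExperimentConfig) -> tuple[pd.DataFrame, dict, list[str]]:
    """Load, filter, label and split; returns (manifest, label_map, class names)."""
    root = config.data_root
    meta, label_map = dataset.load_metadata(
        os.path.join(root, "ptbxl_database.csv"),
        os.path.join(root, "scp_statements.csv"),
    )
    filtered = dataset.filter_records(meta, label_map)
    labeled = dataset.assign_labels(filtered, label_map, config.scheme)
    manifest = dataset.split_dataset(labeled, seed=config.seed)
    classes = sorted(manifest["label"].unique())
    return manifest, label_map, classes


def _load_signals(manifest: pd.DataFrame, data_root) -> np.ndarray:
    out = np.empty((len(manifest), 12, 1000))
    for i, (_, row) in enumerate(manifest.iterrows()):
        out[i] = dataset.normalize_signal(dataset.load_signal(row, data_root))
    return out


def compute_feature_table(signals: np.ndarray, config: EntropyConfig,
                          index=None) -> pd.DataFrame:
    """Per-record 108-column entropy table, columns ``ch{00..11}_{entropy}``."""
    from .entropy import ENTROPY_NAMES

    cols = [f"ch{c:02d}_{name}" for c in range(12) for name in ENTROPY_NAMES]
    rows = [entropy_matrix(sig, config).ravel() for sig in signals]
    return pd.DataFrame(rows, columns=cols, index=index)


def fit_feature_scaler(train_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means/SDs of the training-set entropy features (z-score scaler)."""
    mu = train_features.mean(axis=0)
    sd = train_features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def apply_feature_scaler(features: np.ndarray, scaler) -> np.ndarray:
    mu, sd = scaler
    return (features - mu) / sd


def save_checkpoint(model, config: ExperimentConfig, classes: list[str], path_base,
                    scaler=None) -> None:
    """Flat map of named parameter tensors (.npz) + a JSON config sidecar."""
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[p.name or f"param{i}"] = p.value
    np.savez(str(path_base) + ".npz", **arrays)
    sidecar = {"experiment": config.to_dict(), "classes": classes,
               "n_classes": len(classes)}
    if scaler is not None:
        sidecar["feature_scaler"] = {"mean": scaler[0].tolist(),
                                     "sd": scaler[1].tolist()}
    with open(str(path_base) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path_base):
    """Rebuild a model from a checkpoint pair.

    Returns (model, config, classes, scaler); the scaler is None unless the
    checkpoint belongs to the entropy family.
    """
    with open(str(path_base) + ".json") as fh:
        sidecar = json.load(fh)
    config = ExperimentConfig.from_dict(sidecar["experiment"])
    rng = np.random.default_rng(config.seed)
    model = architectures.build_model(config.family, sidecar["n_classes"], rng=rng)
    data = np.load(str(path_base) + ".npz")
    for p in model.params():
        p.value[...] = data[p.name]
    scaler = None
    if "feature_scaler" in sidecar:
        scaler = (np.asarray(sidecar["feature_scaler"]["mean"]),
                  np.asarray(sidecar["feature_scaler"]["sd"]))
    return model, config, sidecar["classes"], scaler


def run_experiment(config: ExperimentConfig, out_dir=None, log=None):
    """Run the full pipeline; returns (MetricsReport, TrainHistory, manifest).

    When ``out_dir`` is given, writes metrics.json, confusion.csv,
    history.csv, manifest.csv and a model checkpoint there.
    """
    manifest, _, classes = prepare_manifest(config)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = manifest["label"].map(class_to_idx).to_numpy()
    signals = _load_signals(manifest, config.data_root)

    parts = {}
    for name in ("train", "val", "test"):
        mask = (manifest["split"] == name).to_numpy()
        parts[name] = (signals[mask], y[mask])

    scaler = None
    if config.family == "entropy":
        features = compute_feature_table(signals, config.entropy).to_numpy()
        train_mask = (manifest["split"] == "train").to_numpy()
        scaler = fit_feature_scaler(features[train_mask])
        features = apply_feature_scaler(features, scaler)
        inputs = {}
        for name in ("train", "val", "test"):
            mask = (manifest["split"] == name).to_numpy()
            inputs[name] = (parts[name][0], features[mask])
    else:
        inputs = {name: parts[name][0] for name in parts}

    rng = np.random.default_rng(config.seed)
    model = architectures.build_model(config.family, len(classes), rng=rng)
    history = train_mod.train(
        model, inputs["train"], parts["train"][1],
        inputs["val"], parts["val"][1], config.train, log=log,
    )
    report, cm = train_mod.evaluate(model, inputs["test"], parts["test"][1],
                                    len(classes))

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        payload = report.to_dict()
        payload["config_hash"] = config.config_hash()
        payload["classes"] = classes
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(payload, fh, indent=2)
        pd.DataFrame(cm, index=classes, columns=classes).to_csv(
            os.path.join(out_dir, "confusion.csv"))
        hist_df = pd.DataFrame({
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "val_accuracy": history.val_accuracy,
            "learning_rate": history.learning_rate,
        })
        hist_df.to_csv(os.path.join(out_dir, "history.csv"), index_label="epoch")
        manifest[["label", "split"]].to_csv(os.path.join(out_dir, "manifest.csv"))
        save_checkpoint(model, config, classes, os.path.join(out_dir, "checkpoint"),
                        scaler=scaler)
    return report, history, manifest
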