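"""PTB-XL-style dataset handling: loading, filtering, labeling, splitting.

The on-disk layout mirrors PTB-XL: a metadata CSV with one row per ECG record
(including a serialized ``scp_codes`` map from SCP statement code to
likelihood percentage), an SCP statement table mapping codes to diagnostic
subclasses and the five superclasses (NORM, MI, STTC, CD, HYP), and WFDB
signal files of 12 channels x 1000 samples at 100 Hz.

Filtering keeps records that (a) carry at least one diagnostic statement,
(b) have every diagnostic statement at likelihood exactly 100, and
(c) belong only to diagnostic subclasses with at least ``min_subclass_count``
records after (a) and (b); the rules are applied in that order.
"""

from __future__ import annotations

import ast
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_wfdb

__all__ = [
    "SUPERCLASSES",
    "LabelEntry",
    "load_metadata",
    "filter_records",
    "assign_labels",
    "split_dataset",
    "load_signal",
    "normalize_signal",
    "record_classes",
]

logger = logging.getLogger(__name__)

SUPERCLASSES = ("NORM", "MI", "STTC", "CD", "HYP")

SCHEMES = ("binary", "super5", "sub20")


@dataclass(frozen=True)
class LabelEntry:
    """Statement-table entry for one SCP code."""

    subclass: str
    superclass: str
    is_diagnostic: bool


def _parse_scp(cell: str, row_id) -> dict[str, float]:
    try:
        parsed = ast.literal_eval(cell)
        if not isinstance(parsed, dict):
            raise ValueError("not a mapping")
        return {str(k): float(v) for k, v in parsed.items()}
    except (ValueError, SyntaxError) as exc:
        raise ValueError(f"unparseable scp_codes cell in row {row_id!r}: {cell!r}") from exc


def load_metadata(metadata_path, statements_path) -> tuple[pd.DataFrame, dict[str, LabelEntry]]:
    """Load the record table and the code -> (subclass, superclass) label map.

    Returns a DataFrame indexed by ``ecg_id`` with a parsed ``scp_codes``
    column (dict code -> likelihood percent) and a label map covering every
    code in the statements table.  Codes used in the metadata but absent from
    the statements table trigger a warning and are treated as non-diagnostic.
    """
    meta = pd.read_csv(metadata_path, index_col="ecg_id")
    meta["scp_codes"] = [
        _parse_scp(cell, idx) for idx, cell in meta["scp_codes"].items()
    ]
    stm = pd.read_csv(statements_path, index_col=0)
    label_map: dict[str, LabelEntry] = {}
    for code, row in stm.iterrows():
        diag = bool(row.get("diagnostic", 0) == 1)
        label_map[str(code)] = LabelEntry(
            subclass=str(row.get("diagnostic_subclass", "")) if diag else "",
            superclass=str(row.get("diagnostic_class", "")) if diag else "",
            is_diagnostic=diag,
        )
    used = {c for codes in meta["scp_codes"] for c in codes}
    missing = sorted(used - set(label_map))
    if missing:
        warnings.warn(
            f"{len(missing)} SCP code(s) missing from the statement table, "
            f"treated as non-diagnostic: {missing[:10]}",
            stacklevel=2,
        )
        for code in missing:
            label_map[code] = LabelEntry("", "", False)
    return meta, label_map


def _diag_codes(codes: dict[str, float], label_map: dict[str, LabelEntry]) -> list[str]:
    return [c for c in codes if label_map.get(c) and label_map[c].is_diagnostic]


def record_classes(codes: dict[str, float], label_map: dict[str, LabelEntry],
                   level: str) -> set[str]:
    """Distinct superclasses or subclasses of a record's diagnostic codes."""
    attr = "superclass" if level == "super" else "subclass"
    return {getattr(label_map[c], attr) for c in _diag_codes(codes, label_map)}


def filter_records(meta: pd.DataFrame, label_map: dict[str, LabelEntry],
                   min_subclass_count: int = 20) -> pd.DataFrame:
    """Apply the three filter rules (diagnostic, full likelihood, rare subclass)."""
    has_diag = meta["scp_codes"].map(
        lambda c: len(_diag_codes(c, label_map)) > 0).astype(bool)
    kept = meta[has_diag]
    if kept.empty:
        raise ValueError("empty dataset: all records removed by filtering")
    full = kept["scp_codes"].map(
        lambda c: all(c[code] == 100.0 for code in _diag_codes(c, label_map))
    ).astype(bool)
    kept = kept[full]
    if kept.empty:
        raise ValueError("empty dataset: all records removed by filtering")
    # subclass census over the surviving records
    counts: dict[str, int] = {}
    subclasses = kept["scp_codes"].map(lambda c: record_classes(c, label_map, "sub"))
    for subs in subclasses:
        for s in subs:
            counts[s] = counts.get(s, 0) + 1
    common = subclasses.map(
        lambda subs: all(counts[s] >= min_subclass_count for s in subs)
    ).astype(bool)
    kept = kept[common]
    if kept.empty:
        raise ValueError("empty dataset: all records removed by filtering")
    return kept


def assign_labels(meta: pd.DataFrame, label_map: dict[str, LabelEntry],
                  scheme: str) -> pd.DataFrame:
    """Attach a single class label per record under the given scheme.

    binary: NORM vs ABNORM; super5: the five superclasses; sub20: diagnostic
    subclasses.  Records whose diagnostic codes map to more than one distinct
    label under the active scheme are excluded.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    labels = []
    keep_idx = []
    for idx, codes in meta["scp_codes"].items():
        if scheme == "sub20":
            classes = record_classes(codes, label_map, "sub")
        else:
            classes = record_classes(codes, label_map, "super")
            if scheme == "binary":
                classes = {"NORM" if c == "NORM" else "ABNORM" for c in classes}
        if len(classes) == 1:
            keep_idx.append(idx)
            labels.append(classes.pop())
    out = meta.loc[keep_idx].copy()
    out["label"] = labels
    return out


def split_dataset(labeled: pd.DataFrame, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> pd.DataFrame:
    """Stratified random 70/15/15 split; adds a ``split`` column.

    Per class: train gets floor(train_ratio * n); validation gets half of the
    remainder (floor), test the rest, so each set deviates from its exact
    proportion by at most one record per class.  Classes with fewer than three
    records go entirely to train with a warning.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if labeled.empty:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    split = pd.Series("train", index=labeled.index, name="split")
    for cls, group in labeled.groupby("label"):
        ids = group.index.to_numpy()
        if len(ids) < 3:
            warnings.warn(f"class {cls!r} has {len(ids)} record(s); all placed in train",
                          stacklevel=2)
            continue
        rng.shuffle(ids)
        n = len(ids)
        n_train = int(np.floor(ratios[0] * n))
        rem = n - n_train
        n_val = int(np.floor(rem * ratios[1] / (ratios[1] + ratios[2])))
        split.loc[ids[n_train:n_train + n_val]] = "val"
        split.loc[ids[n_train + n_val:]] = "test"
    out = labeled.copy()
    out["split"] = split
    return out


def load_signal(meta_row, data_root) -> np.ndarray:
    """Load one 12x1000 mV signal matrix at 100 Hz through the WFDB reader."""
    import os

    path = os.path.join(str(data_root), str(meta_row["filename_lr"]))
    signal, fs, _ = io_wfdb.read_record(path)
    if signal.shape != (12, 1000):
        raise io_wfdb.WfdbFormatError(
            f"{path}: expected a 12x1000 record, found {signal.shape}"
        )
    if fs != 100:
        raise io_wfdb.WfdbFormatError(f"{path}: expected 100 Hz, found {fs}")
    return signal


def normalize_signal(signal: np.ndarray) -> np.ndarray:
    """Per-channel z-score; constant channels map to all-zeros."""
    signal = np.asarray(signal, dtype=np.float64)
    if not np.isfinite(signal).all():
        raise ValueError("signal contains non-finite values")
    mu = signal.mean(axis=-1, keepdims=True)
    sd = signal.std(axis=-1, keepdims=True)
    out = np.zeros_like(signal)
    np.divide(signal - mu, sd, out=out, where=sd > 0)
    return out
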