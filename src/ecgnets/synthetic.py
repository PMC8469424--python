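"""Deterministic synthetic 12-lead ECG fixtures in the PTB-XL on-disk layout.

Each record is a 10 s, 100 Hz, 12-channel waveform built from per-beat
P/QRS/T composites: a Gaussian P wave, a piecewise Q-R-S deflection, a
Gaussian T wave, plus an ST-segment plateau.  The twelve leads are fixed
scaled/negated projections of one base waveform (lead aVR is inverted, chest
leads are amplified), with additive Gaussian noise and sinusoidal baseline
wander.  Class identity is encoded through morphology deltas that dominate
the noise floor:

  NORM  reference morphology
  MI    deep pathological Q waves and depressed ST segment
  STTC  inverted, widened T waves and shifted ST segment
  CD    widened QRS complexes (bundle-branch-block-like)
  HYP   tall R waves with secondary ST depression

The generator also plants records that each dataset filter rule must remove:
sub-100% likelihood statements, non-diagnostic-only records, and a rare
subclass below the census threshold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_wfdb

__all__ = ["ClassRecipe", "FixtureSpec", "CLASS_RECIPES", "LEAD_NAMES",
           "generate_record", "generate_dataset"]

LEAD_NAMES = ["I", "II", "III", "AVR", "AVL", "AVF",
              "V1", "V2", "V3", "V4", "V5", "V6"]

# Fixed projection of the base waveform onto the 12 leads (aVR negated).
_LEAD_SCALE = np.array([0.6, 1.0, 0.5, -0.7, 0.4, 0.8,
                        0.5, 0.9, 1.2, 1.1, 1.0, 0.9])


@dataclass(frozen=True)
class ClassRecipe:
    """Morphology deltas relative to the NORM beat."""

    class_label: str
    subclass: str
    scp_code: str
    qrs_width_factor: float = 1.0
    st_offset_mv: float = 0.0
    q_depth_mv: float = 0.0
    r_amp_factor: float = 1.0
    t_amp_factor: float = 1.0
    heart_rate_range: tuple[float, float] = (60.0, 90.0)

    def __post_init__(self) -> None:
        if self.qrs_width_factor <= 0 or self.r_amp_factor <= 0:
            raise ValueError("morphology factors must be positive")
        lo, hi = self.heart_rate_range
        if not (40.0 <= lo <= hi <= 180.0):
            raise ValueError("heart rate range must lie within [40, 180] bpm")


CLASS_RECIPES: dict[str, tuple[ClassRecipe, ...]] = {
    "NORM": (ClassRecipe("NORM", "NORM", "NORM"),),
    "MI": (
        ClassRecipe("MI", "IMI", "IMI", q_depth_mv=0.5, st_offset_mv=-0.15),
        ClassRecipe("MI", "AMI", "AMI", q_depth_mv=0.4, st_offset_mv=-0.25,
                    t_amp_factor=0.6),
    ),
    "STTC": (
        ClassRecipe("STTC", "NST_", "NST_", st_offset_mv=0.3, t_amp_factor=-1.2),
        ClassRecipe("STTC", "ISC_", "ISC_", st_offset_mv=0.2, t_amp_factor=-0.8),
    ),
    "CD": (
        ClassRecipe("CD", "CLBBB", "CLBBB", qrs_width_factor=2.6, r_amp_factor=0.8),
        ClassRecipe("CD", "IRBBB", "IRBBB", qrs_width_factor=2.0),
    ),
    "HYP": (
        ClassRecipe("HYP", "LVH", "LVH", r_amp_factor=2.0, st_offset_mv=-0.1),
        ClassRecipe("HYP", "RAO/RAE", "RAO/RAE", r_amp_factor=1.7, t_amp_factor=1.4),
    ),
}

#: Planted rare subclass: fewer records than the census threshold of 20.
_RARE_RECIPE = ClassRecipe("CD", "WPW", "WPW", qrs_width_factor=1.5)


@dataclass
class FixtureSpec:
    """What to generate: per-class counts, noise levels and planted rule-breakers."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in CLASS_RECIPES}
    )
    noise_sd: float = 0.04            # mV additive Gaussian noise
    wander_amp: float = 0.05          # mV baseline wander amplitude
    wander_freq: float = 0.33         # Hz
    seed: int = 0
    n_subthreshold: int = 10          # likelihood < 100 -> removed by rule (b)
    n_nondiagnostic: int = 5          # rhythm-statement-only -> removed by rule (a)
    n_rare: int = 3                   # rare subclass -> removed by rule (c)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be non-negative")


def _base_beat(recipe: ClassRecipe, fs: float, rr_samples: int) -> np.ndarray:
    """One beat of the base (scalar) waveform, length rr_samples."""
    t = np.arange(rr_samples) / fs
    beat = np.zeros(rr_samples)
    rr = rr_samples / fs
    # P wave: Gaussian bump early in the cycle
    beat += 0.15 * np.exp(-0.5 * ((t - 0.16 * rr) / 0.025) ** 2)
    # QRS complex centred at ~30% of the cycle
    qrs_c = 0.30 * rr
    w = 0.022 * recipe.qrs_width_factor
    beat -= (0.2 + recipe.q_depth_mv) * np.exp(-0.5 * ((t - (qrs_c - 1.8 * w)) / (0.6 * w)) ** 2)
    beat += 1.0 * recipe.r_amp_factor * np.exp(-0.5 * ((t - qrs_c) / w) ** 2)
    beat -= 0.25 * np.exp(-0.5 * ((t - (qrs_c + 1.8 * w)) / (0.6 * w)) ** 2)
    # ST segment plateau between QRS and T
    st_start, st_end = qrs_c + 3 * w, qrs_c + 3 * w + 0.10
    beat += recipe.st_offset_mv / (1 + np.exp(-(t - st_start) / 0.01)) \
        / (1 + np.exp((t - st_end) / 0.01))
    # T wave
    beat += 0.3 * recipe.t_amp_factor * np.exp(-0.5 * ((t - (st_end + 0.08)) / 0.05) ** 2)
    return beat


def generate_record(recipe: ClassRecipe, seed: int, n_samples: int = 1000,
                    fs: float = 100.0, noise_sd: float = 0.04,
                    wander_amp: float = 0.05, wander_freq: float = 0.33) -> np.ndarray:
    """One deterministic 12 x n_samples signal matrix in millivolts."""
    rng = np.random.default_rng(seed)
    hr = rng.uniform(*recipe.heart_rate_range)
    rr_samples = max(int(round(60.0 / hr * fs)), 30)
    base = np.zeros(n_samples + 2 * rr_samples)
    pos = 0
    while pos < len(base):
        beat = _base_beat(recipe, fs, rr_samples)
        end = min(pos + rr_samples, len(base))
        base[pos:end] += beat[: end - pos]
        pos += rr_samples
    offset = rng.integers(0, rr_samples)
    base = base[offset : offset + n_samples]
    signal = _LEAD_SCALE[:, None] * base[None, :]
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0, 2 * np.pi, size=12)
    signal = signal + wander_amp * np.sin(2 * np.pi * wander_freq * t[None, :] + phase[:, None])
    signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal


def _statements_table() -> pd.DataFrame:
    rows = []
    for recipes in CLASS_RECIPES.values():
        for r in recipes:
            rows.append((r.scp_code, r.subclass, r.class_label, 1))
    rows.append((_RARE_RECIPE.scp_code, _RARE_RECIPE.subclass, _RARE_RECIPE.class_label, 1))
    rows.append(("SR", "", "", 0))     # sinus rhythm: non-diagnostic
    rows.append(("PACE", "", "", 0))   # paced rhythm: non-diagnostic
    df = pd.DataFrame(rows, columns=["code", "diagnostic_subclass",
                                     "diagnostic_class", "diagnostic"])
    return df.set_index("code")


def generate_dataset(spec: FixtureSpec, out_dir) -> str:
    """Write a complete PTB-XL-layout fixture; returns the metadata CSV path.

    Output: ``ptbxl_database.csv``, ``scp_statements.csv`` and WFDB record
    pairs under ``records100/``.  Deterministic for a fixed spec (including
    its seed): per-record seeds are drawn from one seed sequence.
    """
    out_dir = str(out_dir)
    rec_dir = os.path.join(out_dir, "records100")
    os.makedirs(rec_dir, exist_ok=True)
    root = np.random.default_rng(spec.seed)
    rows = []
    ecg_id = 1

    def emit(recipe: ClassRecipe, scp_codes: dict[str, float]) -> None:
        nonlocal ecg_id
        rec_seed = int(root.integers(0, 2**31 - 1))
        sig = generate_record(recipe, rec_seed, noise_sd=spec.noise_sd,
                              wander_amp=spec.wander_amp, wander_freq=spec.wander_freq)
        fname = f"records100/{ecg_id:05d}_lr"
        io_wfdb.write_record(os.path.join(out_dir, fname), sig, fs=100.0,
                             lead_names=LEAD_NAMES)
        rows.append({
            "ecg_id": ecg_id,
            "patient_id": ecg_id,
            "age": int(root.integers(20, 90)),
            "sex": int(root.integers(0, 2)),
            "scp_codes": repr({k: float(v) for k, v in scp_codes.items()}),
            "filename_lr": fname,
        })
        ecg_id += 1

    for cls in sorted(spec.counts):
        recipes = CLASS_RECIPES[cls]
        count = spec.counts[cls]
        # spread across the class's subclasses only when every share stays at
        # or above the census threshold of 20, so intended records survive
        # the rare-subclass filter
        n_sub = max(1, min(len(recipes), count // 20))
        for i in range(count):
            recipe = recipes[i % n_sub]
            emit(recipe, {recipe.scp_code: 100.0, "SR": 0.0})
    norm = CLASS_RECIPES["NORM"][0]
    mi = CLASS_RECIPES["MI"][0]
    for i in range(spec.n_subthreshold):  # removed by the likelihood rule
        recipe = (norm, mi)[i % 2]
        emit(recipe, {recipe.scp_code: 50.0, "SR": 0.0})
    for _ in range(spec.n_nondiagnostic):  # removed by the diagnostic rule
        emit(norm, {"SR": 100.0})
    for _ in range(spec.n_rare):  # removed by the rare-subclass rule
        emit(_RARE_RECIPE, {_RARE_RECIPE.scp_code: 100.0})

    meta = pd.DataFrame(rows).set_index("ecg_id")
    meta_path = os.path.join(out_dir, "ptbxl_database.csv")
    meta.to_csv(meta_path)
    _statements_table().to_csv(os.path.join(out_dir, "scp_statements.csv"))
    return meta_path
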