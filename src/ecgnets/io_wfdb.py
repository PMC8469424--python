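"""Reader/writer for the WFDB format-16 subset used by 100 Hz PTB-XL records.

A record is a text header ``<name>.hea`` plus one little-endian int16 ``.dat``
file holding all channels multiplexed sample by sample.  Only the fields this
package needs are handled: sampling frequency, number of signals and samples,
per-signal gain/baseline/units and checksum.  Physical units are millivolts;
``physical = (digital - baseline) / gain``.
"""

from __future__ import annotations

import os
import re

import numpy as np

__all__ = ["read_record", "write_record", "WfdbFormatError"]

_GAIN_RE = re.compile(r"^([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/(\S+))?$")


class WfdbFormatError(ValueError):
    """Raised when a record's header or data file is malformed or inconsistent."""


def write_record(path_base: str, signal: np.ndarray, fs: float = 100.0,
                 lead_names: list[str] | None = None, gain: float = 1000.0) -> None:
    """Write ``signal`` (channels x samples, mV) as <path_base>.hea/.dat."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise ValueError("signal must be (channels, samples)")
    n_sig, n_samp = signal.shape
    lead_names = lead_names or [f"ch{i}" for i in range(n_sig)]
    digital = np.clip(np.rint(signal * gain), -32768, 32767).astype(np.int16)
    name = os.path.basename(path_base)
    dat_name = name + ".dat"
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        checksum = int(np.int16(digital[i].astype(np.int64).sum() & 0xFFFF))
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {int(digital[i, 0])} "
            f"{checksum} 0 {lead_names[i]}"
        )
    with open(path_base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # WFDB multiplexes channels: sample 0 of every signal, then sample 1, ...
    digital.T.astype("<i2").tofile(path_base + ".dat")


def read_record(path_base: str, verify_checksum: bool = True) -> tuple[np.ndarray, float, list[str]]:
    """Read <path_base>.hea/.dat; returns (signal mV (channels, samples), fs, leads)."""
    hea_path = path_base + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise WfdbFormatError(f"malformed header line in {hea_path}")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    if len(lines) < 1 + n_sig:
        raise WfdbFormatError(f"{hea_path}: expected {n_sig} signal lines")
    gains = np.empty(n_sig)
    baselines = np.zeros(n_sig)
    leads = []
    checksums: list[int | None] = []
    dat_name = None
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        parts = ln.split()
        if len(parts) < 3:
            raise WfdbFormatError(f"{hea_path}: malformed signal line {i}")
        dat_name = parts[0]
        if parts[1].split("x")[0] != "16":
            raise WfdbFormatError(f"{hea_path}: unsupported format {parts[1]} (only 16)")
        m = _GAIN_RE.match(parts[2])
        if not m:
            raise WfdbFormatError(f"{hea_path}: cannot parse gain spec {parts[2]!r}")
        gains[i] = float(m.group(1)) or 200.0  # WFDB default gain when 0
        baselines[i] = float(m.group(2) or (parts[4] if len(parts) > 4 else 0))
        checksums.append(int(parts[6]) if len(parts) > 6 else None)
        leads.append(parts[8] if len(parts) > 8 else f"ch{i}")
    dat_path = os.path.join(os.path.dirname(path_base), dat_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise WfdbFormatError(
            f"{dat_path}: expected {n_sig * n_samp} samples, found {raw.size}"
        )
    digital = raw.reshape(n_samp, n_sig).T
    if verify_checksum:
        for i, expect in enumerate(checksums):
            if expect is None:
                continue
            got = int(np.int16(digital[i].astype(np.int64).sum() & 0xFFFF))
            if got != expect:
                raise WfdbFormatError(f"{dat_path}: checksum mismatch on signal {i}")
    physical = (digital.astype(np.float64) - baselines[:, None]) / gains[:, None]
    return physical, fs, leads
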