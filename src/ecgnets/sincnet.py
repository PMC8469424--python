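"""Trainable sinc band-pass filter bank (SincNet-style layer).

A band-pass kernel is parameterized by a pair of cutoff frequencies
``(f1, f2)`` in normalized units (cycles/sample, Nyquist = 0.5):

    g[n] = 2 f2 sinc(2 pi f2 n) - 2 f1 sinc(2 pi f1 n),   sinc(x) = sin(x)/x

evaluated on the symmetric tap grid n in {-(L-1)/2, ..., (L-1)/2} for an odd
kernel length L.  Cutoffs are initialized on the mel scale and kept ordered
and inside [0, 0.5] through :func:`constrain_bands`.  No tapering window is
applied by default; a Hamming taper is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import Layer, Param, im2col

__all__ = [
    "BandPair",
    "FilterBank",
    "sinc",
    "band_pass_kernel",
    "constrain_bands",
    "mel_initialize",
    "sinc_convolve",
    "SincLayer",
    "hz_to_mel",
    "mel_to_hz",
]


@dataclass(frozen=True)
class BandPair:
    """Low/high cutoff in cycles/sample; 0 <= f1 <= f2 <= 0.5."""

    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f1 <= self.f2 <= 0.5 + 1e-12):
            raise ValueError(f"invalid band pair ({self.f1}, {self.f2})")


@dataclass
class FilterBank:
    """A bank of ``l`` trainable band pairs sharing one odd kernel length."""

    theta: list[BandPair]
    kernel_length: int = 129

    def __post_init__(self) -> None:
        if self.kernel_length % 2 == 0:
            raise ValueError("kernel_length must be odd")
        if len(self.theta) < 1:
            raise ValueError("filter bank needs at least one band")

    @property
    def l(self) -> int:
        return len(self.theta)


def sinc(x):
    """sin(x)/x with the removable singularity sinc(0) = 1."""
    x = np.asarray(x, dtype=np.float64)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = np.sin(x[nz]) / x[nz]
    if out.ndim == 0:
        return float(out)
    return out


def _tap_grid(kernel_length: int) -> np.ndarray:
    if kernel_length % 2 == 0:
        raise ValueError("kernel_length must be odd")
    half = (kernel_length - 1) // 2
    return np.arange(-half, half + 1, dtype=np.float64)


def band_pass_kernel(band: BandPair, kernel_length: int,
                     window: str | None = None) -> np.ndarray:
    """Band-pass kernel on the symmetric tap grid; even-symmetric by construction."""
    n = _tap_grid(kernel_length)
    g = 2 * band.f2 * sinc(2 * np.pi * band.f2 * n) - 2 * band.f1 * sinc(2 * np.pi * band.f1 * n)
    if window == "hamming":
        g = g * np.hamming(kernel_length)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    return g


def constrain_bands(raw: np.ndarray) -> BandPair:
    """Map an unconstrained (raw1, raw2) pair onto a valid band pair.

    f1 = |raw1|, f2 = f1 + |raw2 - raw1|, both clipped to the Nyquist 0.5.
    """
    r1, r2 = float(raw[0]), float(raw[1])
    f1 = min(abs(r1), 0.5)
    f2 = min(f1 + abs(r2 - r1), 0.5)
    return BandPair(f1, f2)


def hz_to_mel(f_hz):
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_initialize(l: int, sample_rate: float, kernel_length: int = 129) -> FilterBank:
    """Bank of ``l`` contiguous bands with mel-equal widths covering (0, Nyquist]."""
    if l < 1:
        raise ValueError("need at least one filter")
    nyquist = sample_rate / 2.0
    edges_hz = mel_to_hz(np.linspace(0.0, float(hz_to_mel(nyquist)), l + 1))
    edges = edges_hz / sample_rate  # normalized cycles/sample
    if len(np.unique(np.round(edges, 12))) != l + 1:
        raise ValueError(f"cannot place {l} distinct mel bands below {nyquist} Hz")
    theta = [BandPair(float(edges[i]), float(min(edges[i + 1], 0.5))) for i in range(l)]
    return FilterBank(theta, kernel_length)


def sinc_convolve(channel: np.ndarray, bank: FilterBank,
                  window: str | None = None) -> np.ndarray:
    """'Same'-length convolution of one channel with every kernel in the bank.

    Returns an (l, n) array.  Kernels are even-symmetric, so convolution and
    correlation coincide (zero-phase filtering).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 1:
        raise ValueError("sinc_convolve expects a single 1-D channel")
    kernels = np.stack([band_pass_kernel(b, bank.kernel_length, window) for b in bank.theta])
    half = (bank.kernel_length - 1) // 2
    padded = np.pad(channel, half)
    cols = np.lib.stride_tricks.sliding_window_view(padded, bank.kernel_length)
    return kernels @ cols.T  # (l, L) @ (L, n) -> (l, n)


class SincLayer(Layer):
    """Trainable sinc filter bank applied to a single-channel signal.

    Input (B, 1, N) -> output (B, l, T) with symmetric zero padding and an
    optional stride.  The trainable tensor is the raw (l, 2) cutoff array fed
    through :func:`constrain_bands`; gradients flow to the cutoffs only (the
    layer is meant as the first layer of a network, so no input gradient is
    produced).
    """

    def __init__(self, bank: FilterBank, stride: int = 1, name: str = "sinc") -> None:
        raw = np.array([[b.f1, b.f2] for b in bank.theta], dtype=np.float64)
        self.raw = Param(raw, f"{name}.cutoffs")
        self.kernel_length = bank.kernel_length
        self.stride = stride
        self._grid = _tap_grid(bank.kernel_length)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.raw]

    def bands(self) -> list[BandPair]:
        return [constrain_bands(row) for row in self.raw.value]

    def _kernels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        bands = self.bands()
        f1 = np.array([b.f1 for b in bands])
        f2 = np.array([b.f2 for b in bands])
        n = self._grid
        k = (2 * f2[:, None] * sinc(2 * np.pi * np.outer(f2, n))
             - 2 * f1[:, None] * sinc(2 * np.pi * np.outer(f1, n)))
        return k, f1, f2

    def forward(self, x, training=False):
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError("SincLayer expects input of shape (B, 1, N)")
        kernels, f1, f2 = self._kernels()
        half = (self.kernel_length - 1) // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (half, half)))
        patches = im2col(xpad, self.kernel_length, self.stride)[:, 0]  # (B, T, L)
        self._cache = (patches, f1, f2)
        return np.einsum("btk,lk->blt", patches, kernels, optimize=True)

    def backward(self, gout):
        patches, f1, f2 = self._cache
        gk = np.einsum("blt,btk->lk", gout, patches, optimize=True)  # (l, L)
        n = self._grid
        # d g[n] / d f = 2 cos(2 pi f n): 2f sinc(2 pi f n) = sin(2 pi f n)/(pi n)
        gf2 = (gk * 2 * np.cos(2 * np.pi * np.outer(f2, n))).sum(axis=1)
        gf1 = -(gk * 2 * np.cos(2 * np.pi * np.outer(f1, n))).sum(axis=1)
        r1 = self.raw.value[:, 0]
        r2 = self.raw.value[:, 1]
        s1 = np.sign(r1)
        s2 = np.sign(r2 - r1)
        clip1 = np.abs(r1) < 0.5
        clip2 = (np.minimum(np.abs(r1), 0.5) + np.abs(r2 - r1)) < 0.5
        # f1 = |r1| (clipped); f2 = f1 + |r2 - r1| (clipped)
        d_f1_r1 = s1 * clip1
        self.raw.grad[:, 0] += gf1 * d_f1_r1 + gf2 * clip2 * (d_f1_r1 - s2)
        self.raw.grad[:, 1] += gf2 * clip2 * s2
        return None  # first layer: no gradient to the raw signal
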