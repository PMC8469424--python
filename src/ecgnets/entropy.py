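"""Per-channel entropy features and the stationarity screen.

Nine estimators are computed for every channel of a 12x1000 ECG matrix:
Shannon, approximate, sample, permutation, spectral, SVD, Renyi, Tsallis
entropy and extropy.  Distribution-based measures (Shannon, Renyi, Tsallis,
extropy) operate on an equal-width histogram of the channel amplitudes;
dynamical measures (ApEn, SampEn, permutation, SVD) operate on delay
embeddings; spectral entropy operates on the periodogram.

The augmented Dickey-Fuller screen quantifies how often ten-second chunks
behave as (weakly) stationary series, which justifies treating the per-chunk
entropy values as meaningful features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "EntropyConfig",
    "ENTROPY_NAMES",
    "discretize",
    "shannon_entropy",
    "renyi_entropy",
    "tsallis_entropy",
    "extropy",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "spectral_entropy",
    "svd_entropy",
    "entropy_matrix",
    "adf_stationary_fraction",
]

#: Fixed column order of the 12x9 entropy matrix (channel-major flattening).
ENTROPY_NAMES = (
    "shannon", "approx", "sample", "perm", "spectral", "svd",
    "renyi", "tsallis", "extropy",
)


@dataclass
class EntropyConfig:
    """Estimator hyperparameters.

    bins:        histogram bins for the distribution-based entropies.
    embed_m:     embedding dimension m for ApEn/SampEn.
    tol_r:       tolerance coefficient; the match radius is tol_r * SD(channel).
    perm_order:  ordinal pattern length for permutation entropy.
    delay:       embedding delay for permutation and SVD entropy.
    svd_order:   embedding dimension for SVD entropy.
    renyi_alpha: Renyi order (> 0, != 1).
    tsallis_q:   Tsallis order (!= 1).
    sample_rate: Hz, used by spectral entropy.
    adf_maxlag:  maximum lag for the ADF regression (order chosen by AIC).
    """

    bins: int = 16
    embed_m: int = 2
    tol_r: float = 0.2
    perm_order: int = 3
    delay: int = 1
    svd_order: int = 3
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    sample_rate: float = 100.0
    adf_maxlag: int = 10

    def __post_init__(self) -> None:
        if self.bins < 2 or self.embed_m < 1 or self.perm_order < 2 or self.delay < 1:
            raise ValueError("invalid entropy configuration")
        if self.tol_r <= 0:
            raise ValueError("tol_r must be positive")


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def discretize(channel: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width histogram probabilities over [min, max] of the channel."""
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = channel.min(), channel.max()
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(channel, bins=bins, range=(lo, hi))
    return counts / counts.sum()


def shannon_entropy(p: np.ndarray) -> float:
    """-sum p log2 p in bits, with 0 log 0 := 0."""
    p = _validate_probs(p)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def renyi_entropy(p: np.ndarray, alpha: float) -> float:
    """(1/(1-alpha)) log2 sum p^alpha, bits."""
    if alpha <= 0 or alpha == 1.0:
        raise ValueError("Renyi order must be positive and != 1 (use shannon_entropy)")
    p = _validate_probs(p)
    nz = p > 0
    return float(np.log2((p[nz] ** alpha).sum()) / (1.0 - alpha))


def tsallis_entropy(p: np.ndarray, q: float) -> float:
    """(1 - sum p^q) / (q - 1)."""
    if q == 1.0:
        raise ValueError("Tsallis order must be != 1 (use Shannon entropy in nats)")
    p = _validate_probs(p)
    nz = p > 0
    return float((1.0 - (p[nz] ** q).sum()) / (q - 1.0))


def extropy(p: np.ndarray) -> float:
    """-sum (1 - p) log2 (1 - p) in bits, complement-dual of Shannon entropy."""
    p = _validate_probs(p)
    c = 1.0 - p
    nz = c > 0
    return float(-(c[nz] * np.log2(c[nz])).sum())


def _embed(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n = len(x) - (order - 1) * delay
    if n < 1:
        raise ValueError("series too short for the requested embedding")
    return np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]


try:  # optional numba acceleration; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _counts_jit(x, m, r):  # pragma: no cover - exercised via the wrapper
        n = x.shape[0]
        ntm = n - m + 1
        nt = n - m
        c_m = np.zeros(ntm, dtype=np.int64)
        c_m1 = np.zeros(nt, dtype=np.int64)
        a = 0
        b = 0
        for i in range(ntm):
            c_m[i] += 1  # self-match (ApEn convention)
            if i < nt:
                c_m1[i] += 1
        for i in range(ntm):
            for j in range(i + 1, ntm):
                d = 0.0
                for k in range(m):
                    v = abs(x[i + k] - x[j + k])
                    if v > d:
                        d = v
                    if d > r:
                        break
                if d <= r:
                    c_m[i] += 1
                    c_m[j] += 1
                    if j < nt:
                        b += 1
                        v = abs(x[i + m] - x[j + m])
                        if v > d:
                            d = v
                        if d <= r:
                            a += 1
                            c_m1[i] += 1
                            c_m1[j] += 1
        return c_m, c_m1, a, b
except ImportError:  # pragma: no cover
    _counts_jit = None


def _chebyshev_counts(x: np.ndarray, m: int, r: float):
    """Template-match counts for ApEn/SampEn via Chebyshev distance.

    Returns (c_m, c_m1, a, b): per-template counts including self-matches for
    embedding dimensions m and m+1 (truncated to the same number of templates,
    the Pincus convention), plus the SampEn pair totals A (m+1) and B (m)
    excluding self-matches over the n-m templates.
    """
    n = len(x)
    ntm = n - m + 1  # number of m-templates
    nt = n - m       # number of (m+1)-templates
    if nt < 1:
        raise ValueError("series too short")
    if _counts_jit is not None and n >= 256:
        return _counts_jit(np.ascontiguousarray(x, dtype=np.float64), m, float(r))
    dm = np.abs(x[:ntm, None] - x[None, :ntm])
    for j in range(1, m):
        np.maximum(dm, np.abs(x[j:j + ntm, None] - x[None, j:j + ntm]), out=dm)
    c_m = (dm <= r).sum(axis=1)  # ApEn: all m-templates, self-matches included
    b = int((dm[:nt, :nt] <= r).sum() - nt) // 2  # SampEn B over first n-m templates
    d1 = np.maximum(dm[:nt, :nt], np.abs(x[m:m + nt, None] - x[None, m:m + nt]))
    within_m1 = d1 <= r
    c_m1 = within_m1.sum(axis=1)
    a = int(within_m1.sum() - nt) // 2
    return c_m, c_m1, a, b


def approximate_entropy(channel: np.ndarray, m: int = 2, r_coeff: float = 0.2) -> float:
    """Pincus ApEn = Phi_m - Phi_{m+1}, Chebyshev distance, self-matches included."""
    x = np.asarray(channel, dtype=np.float64)
    if len(x) < m + 2:
        raise ValueError("series too short for approximate entropy")
    r = r_coeff * x.std()
    c_m, c_m1, _, _ = _chebyshev_counts(x, m, r)
    phi_m = np.log(c_m / len(c_m)).mean()
    phi_m1 = np.log(c_m1 / len(c_m1)).mean()
    return float(phi_m - phi_m1)


def sample_entropy(channel: np.ndarray, m: int = 2, r_coeff: float = 0.2) -> float:
    """SampEn = -log(A/B), self-matches excluded; A = 0 returns the finite cap
    log(N (N-1)) with N = n - m, documented stand-in for +infinity."""
    x = np.asarray(channel, dtype=np.float64)
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    r = r_coeff * x.std()
    _, _, a, b = _chebyshev_counts(x, m, r)
    cap = math.log((n - m) * (n - m - 1))
    if b == 0:
        return cap
    if a == 0:
        return cap
    return float(-math.log(a / b))


def permutation_entropy(channel: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy (bits) of ordinal patterns; ties broken by index order."""
    x = np.asarray(channel, dtype=np.float64)
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    return shannon_entropy(counts / counts.sum())


def spectral_entropy(channel: np.ndarray, sample_rate: float = 100.0) -> float:
    """Shannon entropy of the normalized periodogram / log2(#bins), in [0, 1]."""
    x = np.asarray(channel, dtype=np.float64)
    _, psd = periodogram(x, fs=sample_rate)
    total = psd.sum()
    if total == 0:
        return 0.0
    p = psd / total
    nz = p > 0
    h = -(p[nz] * np.log2(p[nz])).sum()
    return float(h / np.log2(len(psd)))


def svd_entropy(channel: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized Shannon entropy of singular values of the delay embedding."""
    x = np.asarray(channel, dtype=np.float64)
    emb = _embed(x, order, delay)
    sv = np.linalg.svd(emb, compute_uv=False)
    total = sv.sum()
    if total == 0:
        return 0.0
    s = sv / total
    nz = s > 0
    h = -(s[nz] * np.log2(s[nz])).sum()
    return float(h / np.log2(order))


def entropy_matrix(signal: np.ndarray, config: EntropyConfig | None = None) -> np.ndarray:
    """12x9 matrix of entropies, channels in stored lead order, columns in
    :data:`ENTROPY_NAMES` order.  Flatten channel-major for the 108-vector."""
    config = config or EntropyConfig()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise ValueError("expected a (channels, samples) matrix")
    if not np.isfinite(signal).all():
        raise ValueError("signal contains non-finite values")
    out = np.empty((signal.shape[0], len(ENTROPY_NAMES)))
    for ch, x in enumerate(signal):
        try:
            p = discretize(x, config.bins)
            constant = x.min() == x.max()
            out[ch, 0] = shannon_entropy(p)
            out[ch, 1] = 0.0 if constant else approximate_entropy(x, config.embed_m, config.tol_r)
            out[ch, 2] = 0.0 if constant else sample_entropy(x, config.embed_m, config.tol_r)
            out[ch, 3] = permutation_entropy(x, config.perm_order, config.delay)
            out[ch, 4] = spectral_entropy(x, config.sample_rate)
            out[ch, 5] = svd_entropy(x, config.svd_order, config.delay)
            out[ch, 6] = renyi_entropy(p, config.renyi_alpha)
            out[ch, 7] = tsallis_entropy(p, config.tsallis_q)
            out[ch, 8] = extropy(p)
        except ValueError as exc:
            raise ValueError(f"entropy computation failed on channel {ch}: {exc}") from exc
    return out


def adf_stationary_fraction(signals, significance: float = 0.05,
                            maxlag: int | None = 10) -> float:
    """Fraction of records whose channels all reject the ADF unit-root null.

    A record counts as stationary only if every one of its channels rejects
    at the given significance; the regression includes a constant and no
    trend, with lag order selected by AIC up to ``maxlag``.
    """
    from statsmodels.tsa.stattools import adfuller

    signals = list(signals)
    if not signals:
        raise ValueError("no signals to test")
    stationary = 0
    for sig in signals:
        sig = np.atleast_2d(np.asarray(sig, dtype=np.float64))
        ok = True
        for x in sig:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pval = adfuller(x, regression="c", autolag="AIC", maxlag=maxlag)[1]
            if pval >= significance:
                ok = False
                break
        stationary += ok
    return stationary / len(signals)
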