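"""The three classifier families and the parameter-budget solver.

The target parameter totals constrain the hyperparameters they do not state
directly:
both convolutional families have heads that are affine in the number of
classes K, so the per-class increment pins the width feeding the output
layer and the remaining budget pins the backbone.

  plain convnet        total = 6,832 + 1,025 K   (8,882 / 11,957 / 27,332)
  entropy convnet      total = 58,124 + 27 K     (58,178 / 58,259 / 58,664)

:func:`solve_budget` re-derives, by deterministic ordered enumeration, a
configuration matching those totals exactly for every K in {2, 5, 20}; the
first solutions it finds are committed below as the reference configurations.
The SincNet family's target totals are mutually inconsistent (the same
number is listed for 2 and 5 classes, impossible with a K-dependent output
layer), so its reference configuration targets the magnitude (~6.1 M)
rather than an exact total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import nn
from .sincnet import SincLayer, mel_initialize

__all__ = [
    "ConvNetConfig",
    "EntropyConvNetConfig",
    "SincNetConfig",
    "REFERENCE_CONVNET",
    "REFERENCE_ENTROPY_CONVNET",
    "REFERENCE_SINCNET",
    "TABLE_TOTALS",
    "count_parameters",
    "solve_budget",
    "build_convnet",
    "build_entropy_convnet",
    "build_sincnet_classifier",
    "build_model",
    "predict_classes",
]

#: Published trainable-parameter totals per family and class count.
TABLE_TOTALS: dict[str, dict[int, int]] = {
    "convnet": {2: 8_882, 5: 11_957, 20: 27_332},
    "entropy": {2: 58_178, 5: 58_259, 20: 58_664},
    "sincnet": {2: 6_109_922, 5: 6_109_922, 20: 6_269_204},
}

N_CHANNELS = 12
N_SAMPLES = 1000
N_ENTROPY_FEATURES = 108


@dataclass(frozen=True)
class ConvNetConfig:
    """Five conv layers -> adaptive average pool -> one fully connected head."""

    widths: tuple[int, ...] = (12, 12, 12, 12, 64)
    kernel: int = 5
    stride: int = 2
    pool_to: int = 16

    @property
    def flatten(self) -> int:
        return self.widths[-1] * self.pool_to


@dataclass(frozen=True)
class EntropyConvNetConfig:
    """Five stride-2 conv layers with pooled-raw residuals, entropy branch,
    three fully connected layers."""

    widths: tuple[int, ...] = (12, 12, 12, 12, 20)
    kernel: int = 5
    pool_to: int = 16
    hidden1: int = 118
    hidden2: int = 26
    dropout_p: float = 0.20

    @property
    def flatten(self) -> int:
        return self.widths[-1] * self.pool_to


@dataclass(frozen=True)
class SincNetConfig:
    """Twelve per-channel sinc blocks feeding a shared fully connected head.

    Each block pools its conv features to ``pool_to`` time bins before the
    fully connected stack, so the block summarizes band-limited morphology
    rather than sample-level detail."""

    n_filters: int = 16
    kernel_length: int = 129
    sinc_stride: int = 4
    conv_width: int = 16
    conv_kernel: int = 9
    conv_stride: int = 2
    pool_to: int = 16
    fc_sizes: tuple[int, int, int] = (960, 256, 32)
    shared_hidden: int = 64


REFERENCE_CONVNET = ConvNetConfig()
REFERENCE_ENTROPY_CONVNET = EntropyConvNetConfig()
REFERENCE_SINCNET = SincNetConfig()

_WIDTH_CANDIDATES = (12, 8, 16, 20, 24, 28, 32, 40, 48, 64)
_KERNEL_CANDIDATES = (5, 3, 7)


def count_parameters(model: nn.Layer) -> int:
    """Total number of trainable weights and biases."""
    return int(sum(p.value.size for p in model.params()))


def _conv_params(c_in: int, c_out: int, k: int) -> int:
    return c_in * c_out * k + c_out


def _affine_increment(target_totals: dict[int, int]) -> int:
    ks = sorted(target_totals)
    if len(ks) < 2:
        raise ValueError("need totals for at least two class counts")
    incs = {
        (target_totals[b] - target_totals[a]) / (b - a)
        for a, b in itertools.combinations(ks, 2)
    }
    if len(incs) != 1 or not float(next(iter(incs))).is_integer():
        raise ValueError(
            f"totals {target_totals} are not affine in the class count; "
            "no configuration with a K-dependent output layer can match them"
        )
    return int(next(iter(incs)))


def solve_budget(family: str, target_totals: dict[int, int] | None = None,
                 n_samples: int = N_SAMPLES, n_channels: int = N_CHANNELS):
    """Find a configuration whose totals match ``target_totals`` exactly.

    The search is a deterministic ordered enumeration over non-decreasing
    channel widths and a small kernel-size menu; the head structure is pinned
    analytically first (per-class increment -> width feeding the output
    layer; base budget -> backbone).  Raises with the nearest achievable
    totals when the family cannot meet the targets.
    """
    if family == "sincnet":
        # Printed totals are inconsistent (same number for 2 and 5 classes);
        # return the documented magnitude-matched reference configuration.
        return REFERENCE_SINCNET
    target_totals = target_totals or TABLE_TOTALS[family]
    inc = _affine_increment(target_totals)
    k0 = min(target_totals)
    base = target_totals[k0] - inc * k0

    if family == "convnet":
        flatten = inc - 1  # head: flatten*K + K per class
        conv_budget = base
        nearest = None
        for kern in _KERNEL_CANDIDATES:
            for ws in itertools.product(_WIDTH_CANDIDATES, repeat=5):
                if any(ws[i + 1] < ws[i] for i in range(4)):
                    continue
                if flatten % ws[-1]:
                    continue
                cs = (n_channels,) + ws
                tot = sum(_conv_params(cs[i], cs[i + 1], kern) for i in range(5))
                if tot == conv_budget:
                    return ConvNetConfig(widths=ws, kernel=kern,
                                         pool_to=flatten // ws[-1])
                if nearest is None or abs(tot - conv_budget) < abs(nearest - conv_budget):
                    nearest = tot
        raise ValueError(
            f"no convnet configuration reaches a {conv_budget}-parameter "
            f"backbone; nearest achievable: {nearest}"
        )

    if family == "entropy":
        hidden2 = inc - 1  # head: hidden2*K + K per class
        nearest = None
        for kern in _KERNEL_CANDIDATES:
            for pool_to in (16, 32, 8, 4):
                for ws in itertools.product(_WIDTH_CANDIDATES, repeat=5):
                    if any(ws[i + 1] < ws[i] for i in range(4)):
                        continue
                    cs = (n_channels,) + ws
                    conv = sum(_conv_params(cs[i], cs[i + 1], kern) for i in range(5))
                    proj = sum((n_channels + 1) * w for w in ws if w != n_channels)
                    feats = ws[-1] * pool_to + N_ENTROPY_FEATURES
                    # base = conv + proj + (feats*h1 + h1) + (h1*hidden2 + hidden2)
                    rem = base - conv - proj - hidden2
                    if rem <= 0:
                        continue
                    if rem % (feats + 1 + hidden2) == 0:
                        h1 = rem // (feats + 1 + hidden2)
                        if 8 <= h1 <= 512:
                            return EntropyConvNetConfig(
                                widths=ws, kernel=kern, pool_to=pool_to,
                                hidden1=h1, hidden2=hidden2)
                    if nearest is None:
                        nearest = conv + proj
        raise ValueError(
            f"no entropy-convnet configuration matches base {base}; "
            f"nearest backbone explored: {nearest}"
        )

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# model classes


class ConvNet(nn.Sequential):
    """12x1000 signal -> 5 conv + LeakyReLU -> pool -> flatten -> FC -> softmax."""

    def __init__(self, n_classes: int, config: ConvNetConfig, rng: np.random.Generator):
        layers: list[nn.Layer] = []
        c_prev = N_CHANNELS
        for i, w in enumerate(config.widths):
            layers.append(nn.Conv1d(c_prev, w, config.kernel, rng,
                                    stride=config.stride, padding=config.kernel // 2,
                                    name=f"conv{i}"))
            layers.append(nn.LeakyReLU())
            c_prev = w
        layers += [
            nn.AdaptiveAvgPool1d(config.pool_to),
            nn.Flatten(),
            nn.Dense(config.flatten, n_classes, rng, name="head"),
            nn.Softmax(),
        ]
        super().__init__(*layers)
        self.n_classes = n_classes
        self.config = config

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1:] != (N_CHANNELS, N_SAMPLES):
            raise ValueError(f"expected input (B, {N_CHANNELS}, {N_SAMPLES})")
        return super().forward(x, training=training)


class EntropyConvNet(nn.Layer):
    """Two-branch network: a stride-2 conv encoder with pooled-raw residual
    connections, concatenated with the 108 per-channel entropy features, then
    three fully connected layers (dropout 20% before each, off at eval)."""

    def __init__(self, n_classes: int, config: EntropyConvNetConfig,
                 rng: np.random.Generator):
        self.config = config
        self.n_classes = n_classes
        self.convs: list[nn.Conv1d] = []
        self.acts: list[nn.LeakyReLU] = []
        self.pools: list[nn.AvgPool1d] = []
        self.projs: list[nn.Dense | None] = []
        c_prev = N_CHANNELS
        for i, w in enumerate(config.widths):
            self.convs.append(nn.Conv1d(c_prev, w, config.kernel, rng, stride=2,
                                        padding=config.kernel // 2, name=f"conv{i}"))
            self.acts.append(nn.LeakyReLU())
            self.pools.append(nn.AvgPool1d(2))
            # residual from the pooled raw signal; 1x1 projection when widths differ
            self.projs.append(
                None if w == N_CHANNELS
                else nn.Dense(N_CHANNELS, w, rng, name=f"proj{i}")
            )
            c_prev = w
        self.pool_out = nn.AdaptiveAvgPool1d(config.pool_to)
        self.flatten = nn.Flatten()
        self.drop1 = nn.Dropout(config.dropout_p, rng)
        self.fc1 = nn.Dense(config.flatten + N_ENTROPY_FEATURES, config.hidden1,
                            rng, name="fc1")
        self.act1 = nn.LeakyReLU()
        self.drop2 = nn.Dropout(config.dropout_p, rng)
        self.fc2 = nn.Dense(config.hidden1, config.hidden2, rng, name="fc2")
        self.act2 = nn.LeakyReLU()
        self.drop3 = nn.Dropout(config.dropout_p, rng)
        self.head = nn.Dense(config.hidden2, n_classes, rng, name="head")
        self.softmax = nn.Softmax()
        self._entropy_dim = 0

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for conv, proj in zip(self.convs, self.projs):
            out.extend(conv.params())
            if proj is not None:
                out.extend(proj.params())
        for lyr in (self.fc1, self.fc2, self.head):
            out.extend(lyr.params())
        return out

    def forward(self, inputs, training=False):
        x, e = inputs
        x = np.asarray(x, dtype=np.float64)
        e = np.asarray(e, dtype=np.float64)
        if e.ndim != 2 or e.shape[1] != N_ENTROPY_FEATURES:
            raise ValueError(f"expected a (B, {N_ENTROPY_FEATURES}) entropy matrix")
        raw = x
        h = x
        for conv, act, pool, proj in zip(self.convs, self.acts, self.pools, self.projs):
            raw = pool.forward(raw, training)
            z = conv.forward(h, training)
            if proj is None:
                res = raw
            else:
                # 1x1 projection across channels: apply Dense on the channel axis
                res = np.moveaxis(proj.forward(
                    np.moveaxis(raw, 1, 2).reshape(-1, N_CHANNELS), training
                ).reshape(raw.shape[0], raw.shape[2], -1), 2, 1)
            h = act.forward(z + res, training)
        h = self.pool_out.forward(h, training)
        h = self.flatten.forward(h, training)
        h = np.concatenate([h, e], axis=1)
        h = self.drop1.forward(h, training)
        h = self.act1.forward(self.fc1.forward(h, training), training)
        h = self.drop2.forward(h, training)
        h = self.act2.forward(self.fc2.forward(h, training), training)
        h = self.drop3.forward(h, training)
        return self.softmax.forward(self.head.forward(h, training), training)

    def backward(self, gout):
        g = self.softmax.backward(gout)
        g = self.head.backward(g)
        g = self.drop3.backward(g)
        g = self.fc2.backward(self.act2.backward(g))
        g = self.drop2.backward(g)
        g = self.fc1.backward(self.act1.backward(g))
        g = self.drop1.backward(g)
        g_flat = g[:, : self.config.flatten]
        g = self.flatten.backward(g_flat)
        g = self.pool_out.backward(g)
        g_raw = None  # gradient flowing along the pooled-raw residual chain
        for conv, act, pool, proj in zip(
            reversed(self.convs), reversed(self.acts),
            reversed(self.pools), reversed(self.projs)
        ):
            g = act.backward(g)
            if proj is None:
                g_res = g
            else:
                b, _, t = g.shape
                g2 = proj.backward(np.moveaxis(g, 1, 2).reshape(-1, g.shape[1]))
                g_res = np.moveaxis(g2.reshape(b, t, N_CHANNELS), 2, 1)
            g_pool = g_res if g_raw is None else g_res + g_raw
            g_raw = pool.backward(g_pool)
            g = conv.backward(g)
        return g + g_raw


class SincNetClassifier(nn.Layer):
    """Twelve weight-independent per-channel sinc blocks, concatenated into a
    shared fully connected head with a softmax output."""

    def __init__(self, n_classes: int, config: SincNetConfig, rng: np.random.Generator):
        self.config = config
        self.n_classes = n_classes
        self.blocks: list[nn.Sequential] = []
        flat = config.conv_width * config.pool_to
        for ch in range(N_CHANNELS):
            bank = mel_initialize(config.n_filters, 100.0, config.kernel_length)
            f1, f2, f3 = config.fc_sizes
            self.blocks.append(nn.Sequential(
                SincLayer(bank, stride=config.sinc_stride, name=f"b{ch}.sinc"),
                nn.Conv1d(config.n_filters, config.conv_width, config.conv_kernel,
                          rng, stride=config.conv_stride,
                          padding=config.conv_kernel // 2, name=f"b{ch}.conv0"),
                nn.LayerNorm(config.conv_width, name=f"b{ch}.ln0"),
                nn.LeakyReLU(),
                nn.Conv1d(config.conv_width, config.conv_width, config.conv_kernel,
                          rng, stride=config.conv_stride,
                          padding=config.conv_kernel // 2, name=f"b{ch}.conv1"),
                nn.LayerNorm(config.conv_width, name=f"b{ch}.ln1"),
                nn.LeakyReLU(),
                nn.AdaptiveAvgPool1d(config.pool_to),
                nn.Flatten(),
                nn.Dense(flat, f1, rng, name=f"b{ch}.fc0"),
                nn.BatchNorm1d(f1, name=f"b{ch}.bn0"),
                nn.LeakyReLU(),
                nn.Dense(f1, f2, rng, name=f"b{ch}.fc1"),
                nn.BatchNorm1d(f2, name=f"b{ch}.bn1"),
                nn.LeakyReLU(),
                nn.Dense(f2, f3, rng, name=f"b{ch}.fc2"),
                nn.BatchNorm1d(f3, name=f"b{ch}.bn2"),
                nn.LeakyReLU(),
            ))
        self.head = nn.Sequential(
            nn.Dense(N_CHANNELS * config.fc_sizes[-1], config.shared_hidden, rng,
                     name="head.fc0"),
            nn.LeakyReLU(),
            nn.Dense(config.shared_hidden, n_classes, rng, name="head.fc1"),
            nn.Softmax(),
        )

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def block_features(self, x, training=False) -> np.ndarray:
        feats = [
            blk.forward(x[:, ch : ch + 1, :], training=training)
            for ch, blk in enumerate(self.blocks)
        ]
        return np.concatenate(feats, axis=1)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != N_CHANNELS:
            raise ValueError(f"expected input (B, {N_CHANNELS}, N)")
        return self.head.forward(self.block_features(x, training), training=training)

    def backward(self, gout):
        g = self.head.backward(gout)
        f3 = self.config.fc_sizes[-1]
        for ch, blk in enumerate(self.blocks):
            blk.backward(g[:, ch * f3 : (ch + 1) * f3])
        return None  # sinc layers are first; no raw-signal gradient


# ---------------------------------------------------------------------------
# builders


def build_convnet(n_classes: int, config: ConvNetConfig | None = None,
                  rng: np.random.Generator | None = None) -> ConvNet:
    return ConvNet(n_classes, config or REFERENCE_CONVNET,
                   rng or np.random.default_rng(0))


def build_entropy_convnet(n_classes: int, config: EntropyConvNetConfig | None = None,
                          rng: np.random.Generator | None = None) -> EntropyConvNet:
    return EntropyConvNet(n_classes, config or REFERENCE_ENTROPY_CONVNET,
                          rng or np.random.default_rng(0))


def build_sincnet_classifier(n_classes: int, config: SincNetConfig | None = None,
                             rng: np.random.Generator | None = None) -> SincNetClassifier:
    return SincNetClassifier(n_classes, config or REFERENCE_SINCNET,
                             rng or np.random.default_rng(0))


def build_model(family: str, n_classes: int,
                rng: np.random.Generator | None = None) -> nn.Layer:
    builders = {
        "convnet": build_convnet,
        "entropy": build_entropy_convnet,
        "sincnet": build_sincnet_classifier,
    }
    if family not in builders:
        raise ValueError(f"unknown family {family!r}; expected one of {sorted(builders)}")
    return builders[family](n_classes, rng=rng)


def predict_classes(probs: np.ndarray) -> np.ndarray:
    """Class = index of the maximum of the output probability vector."""
    return np.asarray(probs).argmax(axis=-1)
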