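"""Dense convolutional backbone with squeeze-and-excitation channel attention.

The backbone is the standard 121-layer densely connected network: a
7x7/stride-2 stem with 3x3 max pooling, four dense blocks of
(6, 12, 24, 16) layers at growth rate k=32, and three transition layers
(1x1 convolution with compression 0.5 followed by 2x2/stride-2 average
pooling).  Each dense-block layer maps the concatenation of every earlier
feature map through BN-ReLU-1x1conv(4k)-BN-ReLU-3x3conv(k), so a block's
output width is C_in + n_layers*k.

Channel attention comes from squeeze-and-excitation (SE) blocks.  The plain
squeeze is global average pooling (one scalar per channel); the optimized
squeeze concatenates three per-channel statistics — global mean, the
maximum of the 2x2-average-pooled map (local pooling), and the spatial
variance — giving a 3C descriptor.  Excitation is the usual bottlenecked
two-layer transform FC(3C -> C/r) -> ReLU -> FC(C/r -> C) -> sigmoid, and the
resulting gates rescale channels multiplicatively.

Three attention variants differ only in where the optimized SE blocks sit:

* variant C — after each of the four dense-block outputs,
* variant B — after each of the three transition outputs,
* variant A — at all seven positions (the union of B and C).

Because the SE blocks are independent add-ons, the parameter overhead of A
over the baseline equals the sum of B's and C's overheads, for every
configuration, and none of the overheads depends on the class count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import avg_pool2d, concat, global_avg_pool, max_pool2d

logger = logging.getLogger(__name__)

VARIANTS = ("baseline", "A", "B", "C")


@dataclass
class ArchitectureSpec:
    """Declarative description of a network variant."""

    variant: str = "A"
    num_classes: int = 2
    growth_rate: int = 32
    block_config: tuple[int, int, int, int] = (6, 12, 24, 16)
    compression: float = 0.5
    se_reduction: int = 16
    head_width: int | None = None
    input_size: int = 224

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if len(self.block_config) != 4:
            raise ValueError("block_config must list four dense-block sizes")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must lie in (0, 1]")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        self.block_config = tuple(int(b) for b in self.block_config)

    @property
    def num_init_features(self) -> int:
        return 2 * self.growth_rate

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "num_classes": self.num_classes,
            "growth_rate": self.growth_rate,
            "block_config": list(self.block_config),
            "compression": self.compression,
            "se_reduction": self.se_reduction,
            "head_width": self.head_width,
            "input_size": self.input_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        if "block_config" in d:
            d["block_config"] = tuple(d["block_config"])
        return cls(**d)


@dataclass
class ChannelStats:
    """Per-channel squeeze descriptor: global mean, local-pool max, variance."""

    global_mean: np.ndarray
    local_max: np.ndarray
    variance: np.ndarray

    def stacked(self, optimized: bool = True) -> np.ndarray:
        if optimized:
            return np.concatenate(
                [self.global_mean, self.local_max, self.variance], axis=-1
            )
        return self.global_mean


def squeeze_statistics(x: np.ndarray) -> ChannelStats:
    """Compute the optimized-squeeze statistics of a feature map.

    ``x`` is (C, H, W) or (N, C, H, W).  The local-pool max is the maximum
    of the 2x2 stride-2 average-pooled map (spatial variance uses the
    population convention, divisor H*W); maps smaller than the pooling
    window fall back to the plain spatial maximum.
    """
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 3
    if squeeze_batch:
        x = x[None]
    gm = x.mean(axis=(2, 3))
    var = x.var(axis=(2, 3))
    H, W = x.shape[2:]
    if H >= 2 and W >= 2:
        win = x[:, :, : H // 2 * 2, : W // 2 * 2]
        pooled = win.reshape(x.shape[0], x.shape[1], H // 2, 2, W // 2, 2).mean(axis=(3, 5))
        lm = pooled.max(axis=(2, 3))
    else:
        lm = x.max(axis=(2, 3))
    if squeeze_batch:
        gm, lm, var = gm[0], lm[0], var[0]
    return ChannelStats(global_mean=gm, local_max=lm, variance=var)


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention.

    ``optimized=True`` uses the 3C squeeze descriptor (mean, local-pool max,
    variance); ``optimized=False`` is the classic mean-only squeeze.  Setting
    ``identity=True`` bypasses the block entirely (ablation hook).
    """

    def __init__(self, channels: int, reduction: int = 16, optimized: bool = True,
                 rng=None):
        super().__init__()
        self.channels = channels
        self.optimized = optimized
        self.identity = False
        mid = channels // reduction
        if mid < 1:
            warnings.warn(
                f"SE bottleneck {channels}/{reduction} < 1; clamped to 1", stacklevel=2
            )
            mid = 1
        in_features = 3 * channels if optimized else channels
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(in_features, mid, bias=True, rng=rng)
        self.fc2 = nn.Linear(mid, channels, bias=True, rng=rng)

    def _squeeze(self, x: Tensor) -> Tensor:
        gm = x.mean(axis=(2, 3))
        if not self.optimized:
            return gm
        H, W = x.shape[2:]
        if H >= 2 and W >= 2:
            lm = avg_pool2d(x, 2, 2).amax(axis=(2, 3))
        else:
            lm = x.amax(axis=(2, 3))
        var = (x * x).mean(axis=(2, 3)) - gm * gm
        return concat([gm, lm, var], axis=1)

    def gates(self, stats: Tensor) -> Tensor:
        return self.fc2(self.fc1(stats).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        if x.shape[1] != self.channels:
            raise ValueError(f"SE block built for {self.channels} channels, got {x.shape[1]}")
        g = self.gates(self._squeeze(x))
        N, C = g.shape
        return x * g.reshape(N, C, 1, 1)


def se_gate(stats: ChannelStats | np.ndarray, r: int, channels: int | None = None,
            optimized: bool = True, seed: int = 0) -> np.ndarray:
    """Run the excitation transform on squeeze statistics.

    Builds a seeded SE gate for ``channels`` (inferred from the statistics
    when omitted) and returns the per-channel gates, each strictly in (0, 1).
    """
    if isinstance(stats, ChannelStats):
        vec = stats.stacked(optimized)
    else:
        vec = np.asarray(stats, dtype=float)
    squeeze_batch = vec.ndim == 1
    if squeeze_batch:
        vec = vec[None]
    if channels is None:
        channels = vec.shape[1] // (3 if optimized else 1)
    block = SEBlock(channels, reduction=r, optimized=optimized,
                    rng=np.random.default_rng(seed))
    out = block.gates(Tensor(vec)).data
    return out[0] if squeeze_batch else out


def apply_se_block(x: np.ndarray, block: SEBlock) -> np.ndarray:
    """Channel-wise rescaling of a feature map by a built SE block."""
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 3
    if squeeze_batch:
        x = x[None]
    with nn.no_grad():
        out = block(Tensor(x)).data
    return out[0] if squeeze_batch else out


class _DenseLayer(nn.Module):
    def __init__(self, in_channels: int, growth_rate: int, rng):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_channels)
        self.conv1 = nn.Conv2d(in_channels, 4 * growth_rate, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(4 * growth_rate)
        self.conv2 = nn.Conv2d(4 * growth_rate, growth_rate, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(self.bn1(x).relu())
        return self.conv2(self.bn2(y).relu())


class DenseBlock(nn.Module):
    """``n_layers`` densely connected layers; output C_in + n_layers*k."""

    def __init__(self, in_channels: int, n_layers: int, growth_rate: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.layers = [
            _DenseLayer(in_channels + i * growth_rate, growth_rate, rng)
            for i in range(n_layers)
        ]
        self.out_channels = in_channels + n_layers * growth_rate

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        for layer in self.layers:
            inp = features[0] if len(features) == 1 else concat(features, axis=1)
            features.append(layer(inp))
        return features[0] if len(features) == 1 else concat(features, axis=1)


class Transition(nn.Module):
    """1x1 compression convolution + 2x2 stride-2 average pooling."""

    def __init__(self, in_channels: int, compression: float, rng=None):
        super().__init__()
        self.out_channels = int(np.floor(in_channels * compression))
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, self.out_channels, 1, rng=rng or np.random.default_rng(0))

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(self.conv(self.bn(x).relu()), 2, 2)


class MFSCNet(nn.Module):
    """Dense backbone with SE attention at variant-dependent positions."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.growth_rate
        c = spec.num_init_features
        self.stem_conv = nn.Conv2d(3, c, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c)

        se_after_block = spec.variant in ("A", "C")
        se_after_transition = spec.variant in ("A", "B")
        self.blocks: list[DenseBlock] = []
        self.block_se: list[SEBlock | None] = []
        self.transitions: list[Transition] = []
        self.transition_se: list[SEBlock | None] = []
        for i, n_layers in enumerate(spec.block_config):
            block = DenseBlock(c, n_layers, k, rng)
            self.blocks.append(block)
            c = block.out_channels
            self.block_se.append(
                SEBlock(c, spec.se_reduction, optimized=True, rng=rng)
                if se_after_block else None
            )
            if i < len(spec.block_config) - 1:
                trans = Transition(c, spec.compression, rng)
                self.transitions.append(trans)
                c = trans.out_channels
                self.transition_se.append(
                    SEBlock(c, spec.se_reduction, optimized=True, rng=rng)
                    if se_after_transition else None
                )
        self.final_bn = nn.BatchNorm2d(c)
        self.feature_channels = c
        if spec.head_width is not None:
            self.head = nn.Linear(c, spec.head_width, rng=rng)
            self.classifier = nn.Linear(spec.head_width, spec.num_classes, rng=rng)
        else:
            self.head = None
            self.classifier = nn.Linear(c, spec.num_classes, rng=rng)

    # ordered SE blocks, dense-block positions first (None where absent)
    def se_blocks(self) -> list[SEBlock | None]:
        return list(self.block_se) + list(self.transition_se)

    def set_se_identity(self, identity: bool = True) -> None:
        for se in self.se_blocks():
            if se is not None:
                se.identity = identity

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        h = max_pool2d(self.stem_bn(self.stem_conv(x)).relu(), 3, 2, 1)
        for i, block in enumerate(self.blocks):
            h = block(h)
            if self.block_se[i] is not None:
                h = self.block_se[i](h)
            if i < len(self.transitions):
                h = self.transitions[i](h)
                if self.transition_se[i] is not None:
                    h = self.transition_se[i](h)
        h = global_avg_pool(self.final_bn(h).relu())
        if self.head is not None:
            h = self.head(h).relu()
        return self.classifier(h)

    @property
    def parameter_count(self) -> int:
        return self.num_parameters()


def build_network(spec: ArchitectureSpec, seed: int = 0) -> MFSCNet:
    """Build a network variant with seeded initialization."""
    return MFSCNet(spec, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalars (conv kernels, FC weights/biases,
    normalization scale/shift; running statistics excluded)."""
    return model.num_parameters()


def dense_block_forward(x: np.ndarray, n_layers: int, k: int, seed: int = 0,
                        training: bool = False) -> np.ndarray:
    """Run a seeded dense block on a feature map (N,C,H,W) or (C,H,W)."""
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 3
    if squeeze_batch:
        x = x[None]
    block = DenseBlock(x.shape[1], n_layers, k, rng=np.random.default_rng(seed))
    block.train(training)
    with nn.no_grad():
        out = block(Tensor(x)).data
    return out[0] if squeeze_batch else out


def transition_forward(x: np.ndarray, compression: float, seed: int = 0,
                       training: bool = False) -> np.ndarray:
    """Run a seeded transition layer on a feature map."""
    x = np.asarray(x, dtype=float)
    squeeze_batch = x.ndim == 3
    if squeeze_batch:
        x = x[None]
    trans = Transition(x.shape[1], compression, rng=np.random.default_rng(seed))
    trans.train(training)
    with nn.no_grad():
        out = trans(Tensor(x)).data
    return out[0] if squeeze_batch else out


def save_model(model: MFSCNet, out_dir) -> None:
    """Persist a network: spec as JSON, weights and BN statistics as npz."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(json.dumps(model.spec.to_dict(), indent=1))
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    for i, bn in enumerate(bns):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(out / "weights.npz", **arrays)


def load_model(model_dir) -> MFSCNet:
    """Rebuild a network saved by :func:`save_model`."""
    import json
    from pathlib import Path

    d = Path(model_dir)
    spec = ArchitectureSpec.from_dict(json.loads((d / "spec.json").read_text()))
    model = MFSCNet(spec, seed=0)
    with np.load(d / "weights.npz") as z:
        model.load_state_arrays(
            [z[f"p{i}"] for i in range(sum(1 for _ in model.parameters()))]
        )
        bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = z[f"bn{i}_mean"].copy()
            bn.running_var = z[f"bn{i}_var"].copy()
    return model


def se_parameter_overhead(spec: ArchitectureSpec) -> int:
    """Closed-form SE parameter overhead of a variant over the baseline."""
    k = spec.growth_rate
    c = spec.num_init_features
    block_channels, transition_channels = [], []
    for i, n in enumerate(spec.block_config):
        c += n * k
        block_channels.append(c)
        if i < 3:
            c = int(np.floor(c * spec.compression))
            transition_channels.append(c)
    channels = []
    if spec.variant in ("A", "C"):
        channels += block_channels
    if spec.variant in ("A", "B"):
        channels += transition_channels

    def one(cc: int) -> int:
        mid = max(cc // spec.se_reduction, 1)
        return (3 * cc) * mid + mid + mid * cc + cc

    return sum(one(cc) for cc in channels)
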