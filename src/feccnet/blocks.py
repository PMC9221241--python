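"""Reusable network building blocks.

Four composites assembled from the `_nn` layers:

* :class:`ConvBlock` — 3x3 convolution, batch normalisation, ReLU;
* :class:`SEBlock` — squeeze-and-excitation channel attention;
* :class:`DepthwiseSeparableBlock` — 3x3 depthwise + 1x1 pointwise
  convolution, each followed by BN and ReLU;
* :class:`ASPP` — atrous spatial pyramid pooling: parallel 3x3 atrous
  branches at distinct dilation rates, concatenated and fused by a learned
  1x1 convolution.

All blocks are stride-1 and size-preserving; only explicit pooling and
upsampling stages in the architecture change resolution.  Convolutions
immediately followed by BN carry no bias.

Module-level functions (``conv_block``, ``se_block``, ...) are thin
single-image wrappers over the composites, operating on (H, W, C) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    BatchNorm2d,
    Conv2d,
    Dense,
    DepthwiseConv2d,
    GlobalAvgPool2d,
    ReLU,
    Sigmoid,
)
from .errors import ConfigurationError


@dataclass
class BlockConfig:
    """Configuration shared by the block constructors.

    ``out_channels`` must be divisible by ``se_reduction`` so the SE
    bottleneck width is integral.
    """

    out_channels: int
    kernel_size: int = 3
    se_reduction: int = 8
    dilation_rates: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.out_channels < 1:
            raise ConfigurationError("out_channels must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be a positive odd integer")
        if self.se_reduction < 1 or self.out_channels % self.se_reduction:
            raise ConfigurationError("out_channels must be divisible by se_reduction")


class Module:
    """Base class for composites: parameter collection + count."""

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def _layers(self):  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


class ConvBlock(Module):
    """Convolution (no bias) -> batch norm -> ReLU."""

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1,
                 rng=None, dtype=np.float32):
        self.conv = Conv2d(in_channels, out_channels, kernel_size, dilation,
                           bias=False, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)
        self.act = ReLU()
        self.out_channels = out_channels

    def _layers(self):
        return [self.conv, self.bn]

    def forward(self, x, train=True):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


class SEBlock(Module):
    """Squeeze-and-excitation: per-channel spatial mean -> bottleneck MLP ->
    sigmoid gates in (0,1) -> channel-wise rescale of the input.

    ``gate_override`` is a test hook: set to a scalar (e.g. 1.0) to force all
    gates to that constant, making the block the identity at 1.0.
    """

    def __init__(self, channels, reduction=8, rng=None, dtype=np.float32):
        if reduction < 1 or channels % reduction:
            raise ConfigurationError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        self.channels = channels
        self.pool = GlobalAvgPool2d()
        self.fc1 = Dense(channels, channels // reduction, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.fc2 = Dense(channels // reduction, channels, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()
        self.gate_override: float | None = None

    def _layers(self):
        return [self.fc1, self.fc2]

    def squeeze(self, x):
        """The squeeze vector: per-channel spatial mean, shape (N, C)."""
        return x.mean(axis=(2, 3))

    def forward(self, x, train=True):
        if self.gate_override is not None:
            g = np.full((x.shape[0], x.shape[1]), self.gate_override, dtype=x.dtype)
        else:
            m = self.pool.forward(x, train)
            g = self.sigmoid.forward(
                self.fc2.forward(self.relu.forward(self.fc1.forward(m, train), train), train),
                train,
            )
        self._x, self._g = x, g
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, g = self._x, self._g
        dx = dy * g[:, :, None, None]
        if self.gate_override is not None:
            return dx
        dg = np.einsum("nchw,nchw->nc", dy, x, optimize=True)
        dm = self.fc1.backward(
            self.relu.backward(self.fc2.backward(self.sigmoid.backward(dg)))
        )
        dx += self.pool.backward(dm)
        return dx


class DepthwiseSeparableBlock(Module):
    """3x3 depthwise conv -> BN -> ReLU -> 1x1 pointwise conv -> BN -> ReLU.

    Parameter cost k^2*C_in + C_in*C_out (+4 BN scalars per channel) versus
    k^2*C_in*C_out for the dense equivalent.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3, rng=None, dtype=np.float32):
        self.dw = DepthwiseConv2d(in_channels, kernel_size, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(in_channels, dtype=dtype)
        self.act1 = ReLU()
        self.pw = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        self.act2 = ReLU()
        self.out_channels = out_channels

    def _layers(self):
        return [self.dw, self.bn1, self.pw, self.bn2]

    def forward(self, x, train=True):
        h = self.act1.forward(self.bn1.forward(self.dw.forward(x, train), train), train)
        return self.act2.forward(self.bn2.forward(self.pw.forward(h, train), train), train)

    def backward(self, dy):
        dh = self.pw.backward(self.bn2.backward(self.act2.backward(dy)))
        return self.dw.backward(self.bn1.backward(self.act1.backward(dh)))


class ASPP(Module):
    """Atrous spatial pyramid pooling.

    One 3x3 atrous ConvBlock per dilation rate, run in parallel on the same
    input; branch outputs are concatenated on the channel axis and fused by
    a learned 1x1 ConvBlock. No image-level pooling branch (keeps the
    parameter budget small).
    """

    def __init__(self, in_channels, branch_channels, out_channels, rates,
                 rng=None, dtype=np.float32):
        rates = list(rates)
        if not rates:
            raise ConfigurationError("ASPP needs at least one dilation rate")
        if len(set(rates)) != len(rates):
            raise ConfigurationError("ASPP dilation rates must be distinct")
        if any(r < 1 for r in rates):
            raise ConfigurationError("ASPP dilation rates must be positive")
        self.rates = rates
        self.branches = [
            ConvBlock(in_channels, branch_channels, 3, dilation=r, rng=rng, dtype=dtype)
            for r in rates
        ]
        self.fuse = ConvBlock(len(rates) * branch_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.branch_channels = branch_channels
        self.out_channels = out_channels

    def _layers(self):
        out = []
        for b in self.branches:
            out.extend(b._layers())
        out.extend(self.fuse._layers())
        return out

    def forward(self, x, train=True):
        outs = [b.forward(x, train) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        return self.fuse.forward(cat, train)

    def backward(self, dy):
        dcat = self.fuse.backward(dy)
        bw = self.branch_channels
        dx = None
        for i, b in enumerate(self.branches):
            d = b.backward(dcat[:, i * bw : (i + 1) * bw])
            dx = d if dx is None else dx + d
        return dx


def _single_image(module, x_hwc, train=False):
    x = np.ascontiguousarray(np.asarray(x_hwc, dtype=np.float64).transpose(2, 0, 1)[None])
    y = module.forward(x, train=train)
    return y[0].transpose(1, 2, 0)


def conv_block(x, cfg: BlockConfig, seed: int = 0):
    """Apply a freshly initialised ConvBlock to one (H, W, C) feature map."""
    rng = np.random.default_rng(seed)
    m = ConvBlock(x.shape[2], cfg.out_channels, cfg.kernel_size, rng=rng, dtype=np.float64)
    return _single_image(m, x, train=True)


def se_block(x, reduction: int, seed: int = 0):
    """Apply a freshly initialised SEBlock to one (H, W, C) feature map."""
    rng = np.random.default_rng(seed)
    m = SEBlock(x.shape[2], reduction, rng=rng, dtype=np.float64)
    return _single_image(m, x)


def depthwise_separable_block(x, cfg: BlockConfig, seed: int = 0):
    """Apply a freshly initialised DepthwiseSeparableBlock to one (H, W, C) map."""
    rng = np.random.default_rng(seed)
    m = DepthwiseSeparableBlock(x.shape[2], cfg.out_channels, cfg.kernel_size,
                                rng=rng, dtype=np.float64)
    return _single_image(m, x, train=True)


def aspp(x, cfg: BlockConfig, seed: int = 0):
    """Apply a freshly initialised ASPP module to one (H, W, C) feature map."""
    if not cfg.dilation_rates:
        raise ConfigurationError("cfg.dilation_rates must be non-empty for aspp")
    rng = np.random.default_rng(seed)
    m = ASPP(x.shape[2], cfg.out_channels, cfg.out_channels, cfg.dilation_rates,
             rng=rng, dtype=np.float64)
    return _single_image(m, x, train=True)
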