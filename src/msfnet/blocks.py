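"""The three building blocks of MSF-Net.

* ``SConvBlock`` — a double 3x3 convolution block whose output is gated
  elementwise by a sigmoid spatial-attention map computed from the block
  input by a single 1x1 convolution.
* ``MDCModule`` — four 3x3 dilated-convolution branches (rates 1, 2, 4, 10
  by default) sharing one kernel, fused pairwise by attention
  (``FusePair``) in a binary tree, with a residual connection.
* ``MFFModule`` — an Inception-style three-branch fusion block with output
  widths C/4, C/2, C/4, channel concatenation, a 1x1 smoothing convolution
  and a residual connection.

All blocks preserve the input shape (B, C, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.autograd import Tensor, concat, sigmoid, softmax_channels

__all__ = [
    "DilationSet",
    "BlockConfig",
    "dilated_receptive_field",
    "conv_param_count",
    "ConvBlock",
    "SConvBlock",
    "FusePair",
    "MDCModule",
    "MFFModule",
]


def dilated_receptive_field(r: int) -> int:
    """Side length of the receptive field of a 3x3 kernel at dilation ``r``:
    2(r - 1) + 3.  Rates 1, 2, 4, 10 give 3, 5, 9, 21."""
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    return 2 * (r - 1) + 3


def conv_param_count(k: int, c_in: int, c_out: int) -> int:
    """Weight count K*K*C1*C2 of a conv layer (biases excluded)."""
    if min(k, c_in, c_out) < 1:
        raise ValueError("kernel size and channel counts must be >= 1")
    return k * k * c_in * c_out


@dataclass(frozen=True)
class DilationSet:
    """Ordered dilation rates for the multi-branch dilated extractor."""

    rates: tuple[int, ...] = (1, 2, 4, 10)

    def __post_init__(self):
        rates = tuple(int(r) for r in self.rates)
        object.__setattr__(self, "rates", rates)
        if any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be positive, got {rates}")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError(f"dilation rates must be strictly increasing, got {rates}")

    @property
    def max_receptive_field(self) -> int:
        return dilated_receptive_field(self.rates[-1])


@dataclass
class BlockConfig:
    """Plain configuration record the blocks are built from."""

    in_channels: int
    out_channels: int | None = None
    use_batchnorm: bool = True
    share_dilated_weights: bool = True
    dilation_set: DilationSet = field(default_factory=DilationSet)

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.out_channels is None:
            self.out_channels = self.in_channels


class _ConvBNRelu(nn.Module):
    """conv -> (BN) -> ReLU, the unit every block here is assembled from."""

    def __init__(self, cin, cout, k, rng, use_bn=True, padding=None, bias=True):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, padding=k // 2 if padding is None else padding,
                              bias=bias, rng=rng)
        self.bn = nn.BatchNorm2d(cout) if use_bn else nn.Identity()
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class ConvBlock(nn.Module):
    """Plain double-3x3 convolution block (the non-gated encoder unit)."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.in_channels = cfg.in_channels
        self.out_channels = cfg.out_channels
        self.c1 = _ConvBNRelu(cfg.in_channels, cfg.out_channels, 3, rng, cfg.use_batchnorm)
        self.c2 = _ConvBNRelu(cfg.out_channels, cfg.out_channels, 3, rng, cfg.use_batchnorm)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class SConvBlock(nn.Module):
    """Spatially gated convolution block.

    One branch is the usual pair of 3x3 convolutions (feature extraction,
    ``Yr1``); the other reduces the block *input* to a single channel with a
    1x1 convolution (``Yr2``) and squashes it through a sigmoid, giving a
    per-pixel attention coefficient in [0, 1] that rescales ``Yr1``
    (broadcast across channels).
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.in_channels = cfg.in_channels
        self.out_channels = cfg.out_channels
        self.features = ConvBlock(cfg, rng)
        self.gate = nn.Conv2d(cfg.in_channels, 1, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"SConvBlock configured for {self.in_channels} input channels, got {x.shape[1]}"
            )
        yr1 = self.features(x)
        attn = sigmoid(self.gate(x))
        return yr1 * attn


def _channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[:, start:stop], _parents=(x,))

    def bw(g):
        dx = np.zeros_like(x.data)
        dx[:, start:stop] = g
        x._accum(dx)

    out._backward = bw
    return out


class FusePair(nn.Module):
    """The attention fusion (F) sub-module over a pair of feature maps.

    The pair is concatenated to 2C channels.  A softmax branch (1x1 conv to
    C with BN + ReLU, then 3x3 conv to 2 channels, per-pixel softmax) yields
    two convex mixing maps applied to the two inputs.  A sigmoid branch
    (1x1 conv to one channel) recalibrates the concatenated pair, which a
    final 1x1 convolution returns to C channels.  The two paths are summed.

    The pre-softmax and pre-sigmoid projections and the channel-recovery
    convolution carry no BN/ReLU so their logits stay unsquashed.
    """

    def __init__(self, channels: int, rng: np.random.Generator, use_batchnorm: bool = True):
        super().__init__()
        self.channels = channels
        self.reduce = _ConvBNRelu(2 * channels, channels, 1, rng, use_batchnorm)
        self.att = nn.Conv2d(channels, 2, 3, padding=1, bias=True, rng=rng)
        self.gate = nn.Conv2d(2 * channels, 1, 1, bias=True, rng=rng)
        self.recover = nn.Conv2d(2 * channels, channels, 1, bias=True, rng=rng)

    def forward(self, ya: Tensor, yb: Tensor) -> Tensor:
        if ya.shape != yb.shape:
            raise ValueError(f"FusePair inputs must match, got {ya.shape} vs {yb.shape}")
        pair = concat([ya, yb], axis=1)                      # Y12'
        ma = softmax_channels(self.att(self.reduce(pair)))   # Ma1, Ma2
        ym1 = ya * _channel_slice(ma, 0, 1) + yb * _channel_slice(ma, 1, 2)
        ma3 = sigmoid(self.gate(pair))
        ym2 = self.recover(pair * ma3)
        return ym1 + ym2

    def attention_maps(self, ya: Tensor, yb: Tensor):
        """The (Ma1, Ma2) softmax pair and Ma3 sigmoid map, for inspection."""
        pair = concat([ya, yb], axis=1)
        ma = softmax_channels(self.att(self.reduce(pair)))
        ma3 = sigmoid(self.gate(pair))
        return ma, ma3


class MDCModule(nn.Module):
    """Multi-scale dilated convolution module with pairwise attention fusion.

    Four 3x3 branches run at the configured dilation rates with padding
    equal to the rate, so each branch preserves the spatial size.  With
    ``share_dilated_weights`` on (the default) all branches apply the same
    kernel tensor, so a larger receptive field costs no extra parameters;
    each branch keeps its own batch normalisation.  Branch outputs are
    fused pairwise in a binary tree — (Y1,Y2) -> Y12, (Y3,Y4) -> Y34,
    (Y12,Y34) -> Y1234 — and the result is added to the input.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.in_channels
        self.channels = c
        self.rates = cfg.dilation_set.rates
        self.share_dilated_weights = cfg.share_dilated_weights
        n = len(self.rates)
        if cfg.share_dilated_weights:
            self.dconv = nn.Conv2d(c, c, 3, bias=True, rng=rng)
        else:
            for i in range(n):
                self.add_module(f"dconv{i}", nn.Conv2d(c, c, 3, bias=True, rng=rng))
        for i in range(n):
            self.add_module(f"dbn{i}", nn.BatchNorm2d(c) if cfg.use_batchnorm else nn.Identity())
        self._n_branches = n
        # binary fusion tree over the branch outputs: n - 1 pairwise fusions
        for i in range(n - 1):
            self.add_module(f"fuse{i}", FusePair(c, rng, cfg.use_batchnorm))

    def _check_size(self, h: int, w: int):
        for r in self.rates:
            rf = dilated_receptive_field(r)
            if min(h, w) < rf:
                raise ValueError(
                    f"feature map {h}x{w} is smaller than the {rf}x{rf} receptive field "
                    f"of dilation rate {r}"
                )

    def extract(self, x: Tensor) -> list[Tensor]:
        """The four dilated branch outputs Y1..Y4, shape-preserving."""
        if x.shape[1] != self.channels:
            raise ValueError(f"MDC configured for {self.channels} channels, got {x.shape[1]}")
        self._check_size(x.shape[2], x.shape[3])
        ys = []
        for i, r in enumerate(self.rates):
            conv = self.dconv if self.share_dilated_weights else getattr(self, f"dconv{i}")
            y = conv(x, padding=r, dilation=r)
            bn = getattr(self, f"dbn{i}")
            ys.append(nn.relu(bn(y)))
        return ys

    @property
    def fuse_pairs(self) -> list[FusePair]:
        return [getattr(self, f"fuse{i}") for i in range(self._n_branches - 1)]

    def forward(self, x: Tensor) -> Tensor:
        ys = self.extract(x)
        # pairwise tree: (Y1,Y2)->Y12, (Y3,Y4)->Y34, ..., then fuse the
        # fused maps, an odd leftover passing through to the next round
        k = 0
        while len(ys) > 1:
            nxt = []
            for a, b in zip(ys[0::2], ys[1::2]):
                nxt.append(getattr(self, f"fuse{k}")(a, b))
                k += 1
            if len(ys) % 2:
                nxt.append(ys[-1])
            ys = nxt
        return ys[0] + x


class MFFModule(nn.Module):
    """Three-branch multi-scale feature fusion with a residual connection.

    Branch widths are C/4, C/2 and C/4.  Depth grows with the branch: the
    C/4 branch is a single 1x1 conv, the C/2 branch adds a 3x3 conv, and
    the deepest C/4 branch stacks two 3x3 convs — the two-3x3 substitute
    for a 5x5 kernel (18C^2 weights instead of 25C^2) with the same 5x5
    receptive field.  Outputs are concatenated back to C channels, smoothed
    by a 1x1 conv and added to the input.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.in_channels
        if c % 4 != 0:
            raise ValueError(f"MFF needs channels divisible by 4, got {c}")
        self.channels = c
        q, h = c // 4, c // 2
        bn = cfg.use_batchnorm
        self.branch1 = _ConvBNRelu(c, q, 1, rng, bn)
        self.branch2 = nn.Sequential(
            _ConvBNRelu(c, h, 1, rng, bn),
            _ConvBNRelu(h, h, 3, rng, bn),
        )
        self.branch3 = nn.Sequential(
            _ConvBNRelu(c, q, 1, rng, bn),
            _ConvBNRelu(q, q, 3, rng, bn),
            _ConvBNRelu(q, q, 3, rng, bn),
        )
        self.smooth = _ConvBNRelu(c, c, 1, rng, bn)

    @property
    def branch_widths(self) -> tuple[int, int, int]:
        return (self.channels // 4, self.channels // 2, self.channels // 4)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"MFF configured for {self.channels} channels, got {x.shape[1]}")
        f1 = self.branch1(x)
        f2 = self.branch2(x)
        f3 = self.branch3(x)
        return self.smooth(concat([f1, f2, f3], axis=1)) + x
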