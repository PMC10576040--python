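"""Building blocks of the lightweight detector.

Constructors for the CBS unit (conv + batch-norm + SiLU), squeeze-excitation
and efficient-channel-attention gates, the two inverted-residual block
flavours (MBConv and its fused variant), Ghost convolution and the Ghost
bottleneck, and the fast spatial-pyramid-pooling block — plus exact
trainable-parameter accounting and the closed-form parameter/multiply ratio
of Ghost vs. traditional convolution.

Accounting convention (used throughout the package): convolution weights
count ``k*k*c_in*c_out/groups``; biases only where declared; a normalisation
layer contributes ``2*C`` (scale + shift); running statistics, poolings and
activations contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

from . import autodiff as ad
from . import layers as layers_mod
from .layers import (BatchNorm2d, Conv2d, Identity, Linear, MaxPool2d, Module,
                     Sequential, SiLU)

BlockKind = Literal["CBS", "SE", "MBConv", "FusedMBConv", "GhostConv",
                    "GhostBottleneck", "ECA", "SPPF"]


def silu(x: float) -> float:
    """Scalar SiLU, x * sigmoid(x)."""
    return float(x) * sigmoid(x)


def sigmoid(x: float) -> float:
    x = float(x)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return float(e / (1.0 + e))


# ---------------------------------------------------------------------------
# descriptors / reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockDescriptor:
    """Declarative description of one building block."""

    kind: BlockKind
    in_channels: int
    out_channels: int
    stride: int = 1
    kernel: int = 3
    expansion: Fraction | float | int = 1
    se_ratio: Fraction | float = 0
    ghost_ratio: int = 2       # s — fraction of maps produced cheaply
    cheap_kernel: int = 3      # d — depthwise kernel of the cheap operation

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {self.kernel}")
        if self.cheap_kernel % 2 == 0:
            raise ValueError(f"cheap_kernel must be odd, got {self.cheap_kernel}")
        if self.kind == "GhostConv":
            if self.ghost_ratio < 2:
                raise ValueError("ghost_ratio must be >= 2")
            if self.out_channels % self.ghost_ratio:
                raise ValueError("out_channels must be divisible by ghost_ratio")

    @property
    def has_shortcut(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


@dataclass
class ParamReport:
    """Per-layer and total trainable-parameter accounting."""

    per_layer: list[tuple[int, str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.per_layer)

    def to_json(self) -> list[dict]:
        return [{"layer": i, "name": name, "params": n}
                for i, name, n in self.per_layer]

    def to_text(self) -> str:
        width = max([len(name) for _, name, _ in self.per_layer] + [5])
        lines = [f"{'Layer':>5}  {'Name':<{width}}  {'Params':>10}"]
        for i, name, n in self.per_layer:
            lines.append(f"{i:>5}  {name:<{width}}  {n:>10,}")
        lines.append(f"{'':>5}  {'total':<{width}}  {self.total:>10,}")
        return "\n".join(lines)


def count_params(block: Module) -> ParamReport:
    """Analytic parameter accounting, one row per immediate child module.

    Counts derive from layer hyper-parameters (kernel, channels, groups,
    declared biases, 2*C per norm layer), never from stored array shapes, so
    the report can be cross-validated against a brute-force weight walk.
    """
    children = list(block._children())
    rep = ParamReport()
    if not children:
        rep.per_layer.append((1, type(block).__name__, block.param_count()))
        return rep
    for i, (name, child) in enumerate(children, start=1):
        rep.per_layer.append((i, f"{type(child).__name__}:{name}",
                              child.param_count()))
    return rep


# ---------------------------------------------------------------------------
# Ghost convolution analytics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GhostAccounting:
    """Closed-form parameter / multiply counts for one convolution site.

    ``p1``/``q1`` follow the traditional convolution, ``p2``/``q2`` the Ghost
    factorisation that produces ``n/s`` maps with a k x k convolution and the
    remaining ``(s-1) * n/s`` maps with cheap d x d depthwise operations.
    """

    c: int            # input channels
    n: int            # output maps
    s: int = 2        # ghost ratio
    k: int = 3        # primary kernel
    d: int = 3        # cheap-operation kernel
    h_out: int = 1
    w_out: int = 1

    def __post_init__(self):
        if self.s < 2:
            raise ValueError("ghost ratio s must be >= 2")
        if self.n % self.s:
            raise ValueError("n must be divisible by s")

    @property
    def p1(self) -> int:
        return self.n * self.c * self.k * self.k

    @property
    def p2(self) -> int:
        m = self.n // self.s
        return m * self.c * self.k * self.k + (self.s - 1) * m * self.d * self.d

    @property
    def q1(self) -> int:
        return self.n * self.h_out * self.w_out * self.c * self.k * self.k

    @property
    def q2(self) -> int:
        m = self.n // self.s
        hw = self.h_out * self.w_out
        return (m * hw * self.c * self.k * self.k
                + (self.s - 1) * m * hw * self.d * self.d)


def ghost_ratios(acct: GhostAccounting) -> tuple[float, float]:
    """Exact compression ratios (p1/p2, q1/q2); both tend to s as c grows."""
    return acct.p1 / acct.p2, acct.q1 / acct.q2


# ---------------------------------------------------------------------------
# concrete blocks
# ---------------------------------------------------------------------------

class CBS(Module):
    """Conv2d (bias-free) + BatchNorm + SiLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, groups: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel, stride=stride,
                           groups=groups, bias=False)
        self.bn = BatchNorm2d(out_channels)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class SE(Module):
    """Squeeze-and-excitation channel gate (biased bottleneck MLP)."""

    def __init__(self, channels: int, se_ratio: float):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        hidden = max(1, round(channels * float(se_ratio)))
        self.reduce = Linear(channels, hidden, bias=True)
        self.expand = Linear(hidden, channels, bias=True)

    def forward(self, x):
        v = ad.global_avg_pool(x)
        v = ad.silu(self.reduce(v))
        gate = ad.sigmoid(self.expand(v))
        n, c = gate.shape
        return x * ad.reshape(gate, (n, c, 1, 1))


class ECA(Module):
    """Efficient channel attention: GAP + shared 1-D conv across channels.

    No dimensionality reduction of the channel descriptor; the only
    trainable state is one odd-width kernel shared by all channels.
    """

    def __init__(self, channels: int, k: int = 3):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"ECA kernel must be odd, got {k}")
        self.channels = channels
        self.k = k
        self.weight = layers_mod.Parameter(
            layers_mod._rng.normal(0.0, 1.0 / np.sqrt(k), size=k))

    def forward(self, x):
        v = ad.global_avg_pool(x)
        gate = ad.sigmoid(ad.channel_conv1d(v, self.weight))
        n, c = gate.shape
        return x * ad.reshape(gate, (n, c, 1, 1))

    def param_count(self) -> int:
        return self.k


class FusedMBConv(Module):
    """Fused inverted-residual block: one 3x3 conv replaces expand+depthwise.

    expansion == 1 collapses to a single 3x3 CBS; otherwise a 3x3 CBS expands
    to ``e*in`` channels and a linear 1x1 conv projects to ``out``.
    """

    def __init__(self, desc: BlockDescriptor):
        super().__init__()
        e = Fraction(desc.expansion).limit_denominator()
        if e < 1:
            raise ValueError("expansion must be >= 1")
        hidden_frac = e * desc.in_channels
        if hidden_frac.denominator != 1:
            raise ValueError(f"expansion {e} * in={desc.in_channels} is fractional")
        hidden = int(hidden_frac)
        self.desc = desc
        self.has_shortcut = desc.has_shortcut
        if e == 1:
            self.main = Sequential(
                CBS(desc.in_channels, desc.out_channels, desc.kernel, desc.stride))
        else:
            mods: list[Module] = [
                CBS(desc.in_channels, hidden, desc.kernel, desc.stride)]
            if desc.se_ratio:
                mods.append(SE(hidden, desc.se_ratio))
            mods.append(CBS(hidden, desc.out_channels, 1, 1, act=False))
            self.main = Sequential(*mods)

    def forward(self, x):
        out = self.main(x)
        return out + x if self.has_shortcut else out


class MBConv(Module):
    """Inverted residual: 1x1 expand, 3x3 depthwise, optional SE, 1x1 project."""

    def __init__(self, desc: BlockDescriptor):
        super().__init__()
        e = Fraction(desc.expansion).limit_denominator()
        if e < 1:
            raise ValueError("expansion must be >= 1")
        hidden_frac = e * desc.in_channels
        if hidden_frac.denominator != 1:
            raise ValueError(f"expansion {e} * in={desc.in_channels} is fractional")
        hidden = int(hidden_frac)
        self.desc = desc
        self.has_shortcut = desc.has_shortcut
        mods: list[Module] = [
            CBS(desc.in_channels, hidden, 1, 1),
            CBS(hidden, hidden, desc.kernel, desc.stride, groups=hidden),
        ]
        if desc.se_ratio:
            mods.append(SE(hidden, desc.se_ratio))
        mods.append(CBS(hidden, desc.out_channels, 1, 1, act=False))
        self.main = Sequential(*mods)

    def forward(self, x):
        out = self.main(x)
        return out + x if self.has_shortcut else out


class GhostConv(Module):
    """Ghost convolution: a thin primary conv plus cheap depthwise maps.

    The primary k x k convolution emits ``out/s`` maps; depthwise d x d
    convolutions derive the remaining ``(s-1)*out/s`` maps from them; the
    output concatenates primary-first.
    """

    def __init__(self, in_channels: int, out_channels: int, *, s: int = 2,
                 k: int = 1, d: int = 3, stride: int = 1, act: bool = True):
        super().__init__()
        if out_channels % s:
            raise ValueError(f"out_channels={out_channels} not divisible by s={s}")
        m = out_channels // s
        self.primary = CBS(in_channels, m, k, stride, act=act)
        self.cheap = CBS(m, m * (s - 1), d, 1, groups=m, act=act)

    def forward(self, x):
        y = self.primary(x)
        return ad.concat([y, self.cheap(y)], axis=1)


class GhostBottleneck(Module):
    """Two Ghost convolutions around an optional stride-2 depthwise stage.

    Stride 1 with matching channels keeps an identity shortcut; otherwise a
    depthwise + pointwise downsample path carries the residual.
    """

    def __init__(self, desc: BlockDescriptor):
        super().__init__()
        e = Fraction(desc.expansion).limit_denominator()
        hidden_frac = e * desc.in_channels
        if hidden_frac.denominator != 1:
            raise ValueError("fractional hidden width")
        hidden = int(hidden_frac)
        s, d = desc.ghost_ratio, desc.cheap_kernel
        if hidden % s:
            hidden += s - hidden % s  # keep divisibility for the ghost split
        self.expand = GhostConv(desc.in_channels, hidden, s=s, d=d, act=True)
        self.dw = (CBS(hidden, hidden, 3, 2, groups=hidden, act=False)
                   if desc.stride == 2 else Identity())
        self.project = GhostConv(hidden, desc.out_channels, s=s, d=d, act=False)
        if desc.has_shortcut:
            self.shortcut = Identity()
            self._identity = True
        else:
            self.shortcut = Sequential(
                CBS(desc.in_channels, desc.in_channels, 3, desc.stride,
                    groups=desc.in_channels, act=False),
                CBS(desc.in_channels, desc.out_channels, 1, 1, act=False))
            self._identity = False

    def forward(self, x):
        out = self.project(self.dw(self.expand(x)))
        return out + self.shortcut(x)


class SPPF(Module):
    """Fast spatial pyramid pooling: cascaded max-pools, concatenated."""

    def __init__(self, in_channels: int, hidden: int, out_channels: int,
                 pool_k: int = 5):
        super().__init__()
        self.pre = CBS(in_channels, hidden, 1, 1)
        self.pool = MaxPool2d(pool_k, stride=1)
        self.post = CBS(hidden * 4, out_channels, 1, 1)

    def forward(self, x):
        y0 = self.pre(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.post(ad.concat([y0, y1, y2, y3], axis=1))


# ---------------------------------------------------------------------------
# spec-surface constructors
# ---------------------------------------------------------------------------

def make_cbs(desc: BlockDescriptor) -> CBS:
    _expect_kind(desc, "CBS")
    return CBS(desc.in_channels, desc.out_channels, desc.kernel, desc.stride)


def make_se(channels: int, se_ratio) -> SE:
    return SE(channels, se_ratio)


def make_fused_mbconv(desc: BlockDescriptor) -> FusedMBConv:
    _expect_kind(desc, "FusedMBConv")
    return FusedMBConv(desc)


def make_mbconv(desc: BlockDescriptor) -> MBConv:
    _expect_kind(desc, "MBConv")
    return MBConv(desc)


def make_ghost_conv(desc: BlockDescriptor) -> GhostConv:
    _expect_kind(desc, "GhostConv")
    return GhostConv(desc.in_channels, desc.out_channels, s=desc.ghost_ratio,
                     k=desc.kernel, d=desc.cheap_kernel, stride=desc.stride)


def make_ghost_bottleneck(desc: BlockDescriptor) -> GhostBottleneck:
    _expect_kind(desc, "GhostBottleneck")
    return GhostBottleneck(desc)


def make_eca(channels: int, k: int = 3) -> ECA:
    return ECA(channels, k)


def make_sppf(in_channels: int, hidden: int, out_channels: int,
              pool_k: int = 5) -> SPPF:
    return SPPF(in_channels, hidden, out_channels, pool_k)


def _expect_kind(desc: BlockDescriptor, kind: str) -> None:
    if desc.kind != kind:
        raise ValueError(f"descriptor kind {desc.kind!r} != {kind!r}")
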