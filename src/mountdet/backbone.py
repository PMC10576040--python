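"""The 13-stage lightweight backbone and its parameter-count validation.

The stage table is declarative (:class:`StageSpec`): block kind, stride,
output channels, repeat count, expansion and — when known — the expected
trainable-parameter count, which :func:`build_backbone` enforces exactly.

Stage 11 is printed with stride 2 in the source table, but that would push
the final feature map to stride 64 and contradict the documented 20x20 grid
for a 640 input; the default spec therefore runs it at stride 1 (parameter
counts are stride-independent).  ``default_spec(strict_strides=True)``
reproduces the printed strides verbatim.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Sequence

import numpy as np
import yaml

from .autodiff import Tensor
from .layers import Module, Sequential
from .nn_blocks import (CBS, SPPF, BlockDescriptor, FusedMBConv, MBConv,
                        ParamReport)

#: expected total of the default spec's per-stage parameter counts
DEFAULT_TOTAL_PARAMS = 238_272

TAP_STAGES = (6, 8, 13)  # last stage at strides 8, 16, 32


@dataclass(frozen=True)
class StageSpec:
    """One row of the backbone table."""

    index: int
    kind: str                      # CBS | FusedMBConv | MBConv | SPPF
    stride: int | None             # None for SPPF
    out_channels: int
    repeats: int = 1
    expansion: float = 1
    expected_params: int | None = None

    def __post_init__(self):
        if not 1 <= self.index <= 99:
            raise ValueError("bad stage index")
        if self.repeats < 1:
            raise ValueError("repeats must be positive")
        if self.kind != "SPPF" and self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        object.__setattr__(self, "expansion", float(self.expansion))


def default_spec(strict_strides: bool = False) -> list[StageSpec]:
    """The 13 default stages (channel chain 3→16→…→32→512).

    ``strict_strides`` restores the printed stride 2 at stage 11 instead of
    the corrected stride 1 (see module docstring).
    """
    s11 = 2 if strict_strides else 1
    rows = [
        (1,  "CBS",         2,    16, 1, 1, 464),
        (2,  "FusedMBConv", 1,    16, 1, 1, 2_336),
        (3,  "FusedMBConv", 2,    24, 1, 4, 10_928),
        (4,  "FusedMBConv", 1,    24, 1, 4, 23_280),
        (5,  "FusedMBConv", 2,    32, 1, 4, 24_064),
        (6,  "FusedMBConv", 1,    32, 1, 4, 41_280),
        (7,  "MBConv",      2,    16, 1, 4, 7_840),
        (8,  "MBConv",      1,    16, 2, 4, 5_824),
        (9,  "MBConv",      2,    24, 1, 6, 5_136),
        (10, "MBConv",      1,    24, 3, 6, 26_496),
        (11, "MBConv",      s11,  32, 1, 4, 6_688),
        (12, "MBConv",      1,    32, 5, 4, 49_600),
        (13, "SPPF",        None, 512, 1, 1, 34_336),
    ]
    return [StageSpec(i, k, st, ch, rep, e, p) for i, k, st, ch, rep, e, p in rows]


def _validate_chain(spec: Sequence[StageSpec]) -> list[int]:
    """Check stage ordering and return the in-channel of each stage."""
    ins = []
    prev_out = 3
    for pos, st in enumerate(spec):
        if st.index != pos + 1:
            raise ValueError(f"stage indices must be 1..N in order, got {st.index}")
        ins.append(prev_out)
        if st.repeats > 1 and st.out_channels != prev_out:
            raise ValueError(
                f"stage {st.index}: repeated blocks need in == out channels")
        prev_out = st.out_channels
    return ins


def _build_stage(st: StageSpec, in_channels: int) -> Module:
    if st.kind == "CBS":
        return CBS(in_channels, st.out_channels, 3, st.stride)
    if st.kind == "SPPF":
        return SPPF(in_channels, in_channels // 2, st.out_channels)
    blocks = []
    for r in range(st.repeats):
        desc = BlockDescriptor(
            kind=st.kind, in_channels=in_channels if r == 0 else st.out_channels,
            out_channels=st.out_channels,
            stride=st.stride if r == 0 else 1,
            expansion=Fraction(st.expansion).limit_denominator())
        cls = FusedMBConv if st.kind == "FusedMBConv" else MBConv
        blocks.append(cls(desc))
    return blocks[0] if len(blocks) == 1 else Sequential(*blocks)


class Backbone(Module):
    """Sequential stage stack exposing taps at strides 8 / 16 / 32."""

    def __init__(self, spec: Sequence[StageSpec],
                 tap_stages: tuple[int, int, int] = TAP_STAGES):
        super().__init__()
        ins = _validate_chain(spec)
        self.spec = list(spec)
        self.tap_stages = tap_stages
        self.stages = [_build_stage(st, c_in) for st, c_in in zip(spec, ins)]
        out_by_stage = {st.index: st.out_channels for st in spec}
        self.tap_channels = tuple(out_by_stage[i] for i in tap_stages)

    def forward(self, x):
        taps = []
        for st, stage in zip(self.spec, self.stages):
            x = stage(x)
            if st.index in self.tap_stages:
                taps.append(x)
        return tuple(taps)

    def stage_param_report(self) -> ParamReport:
        rep = ParamReport()
        for st, stage in zip(self.spec, self.stages):
            rep.per_layer.append((st.index, st.kind, stage.param_count()))
        return rep


@dataclass
class FeaturePyramid:
    """The three backbone taps at strides 8, 16 and 32."""

    p3: Tensor
    p4: Tensor
    p5: Tensor

    def __iter__(self):
        return iter((self.p3, self.p4, self.p5))


def build_backbone(spec: Sequence[StageSpec] | None = None) -> Backbone:
    """Build and validate; mismatching expected_params raises, naming the stage."""
    if spec is None:
        spec = default_spec()
    net = Backbone(spec)
    for st, stage in zip(net.spec, net.stages):
        if st.expected_params is not None:
            got = stage.param_count()
            if got != st.expected_params:
                raise ValueError(
                    f"stage {st.index} ({st.kind}): parameter count {got} "
                    f"!= expected {st.expected_params}")
    return net


def validate_against_table2(backbone: Backbone) -> ParamReport:
    """Per-stage counts with pass/fail annotation against expected_params."""
    rep = ParamReport()
    for st, stage in zip(backbone.spec, backbone.stages):
        got = stage.param_count()
        if st.expected_params is None:
            tag = "n/a"
        else:
            tag = "pass" if got == st.expected_params else (
                f"FAIL(delta={got - st.expected_params:+d})")
        rep.per_layer.append((st.index, f"{st.kind}[{tag}]", got))
    return rep


def forward_features(backbone: Backbone, image_batch) -> FeaturePyramid:
    """Run the backbone; input spatial dims must be divisible by 32."""
    x = image_batch if isinstance(image_batch, Tensor) else Tensor(image_batch)
    h, w = x.shape[2], x.shape[3]
    if h % 32 or w % 32:
        raise ValueError(
            f"input spatial dims ({h}x{w}) must be multiples of 32")
    p3, p4, p5 = backbone(x)
    return FeaturePyramid(p3, p4, p5)


# ---------------------------------------------------------------------------
# config round-trip
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: Sequence[StageSpec]) -> str:
    rows = []
    for st in spec:
        d = asdict(st)
        d["expansion"] = float(d["expansion"])
        rows.append(d)
    return yaml.safe_dump({"stages": rows}, sort_keys=False)


def spec_from_yaml(text: str) -> list[StageSpec]:
    doc = yaml.safe_load(io.StringIO(text))
    return [StageSpec(**row) for row in doc["stages"]]
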