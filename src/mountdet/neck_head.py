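"""FPN+PAN neck with ghost/ECA feature enhancement, detection heads, decode.

The neck follows the usual two-pass fusion: a top-down path upsamples deep
features and merges them with shallower taps, then a bottom-up path returns
with stride-2 convolutions.  All four merge points use the C3ECAGhost block:
a split into two 1x1-projected branches, three ghost bottlenecks on the
first branch, concat, 1x1 fusion conv and an efficient-channel-attention
gate.

Heads are plain 1x1 convolutions (with bias) emitting, per scale, three
anchors x (4 box + 1 objectness + num_classes) raw logits; ``decode`` turns
them into pixel-space candidate boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import Backbone, build_backbone
from .layers import Conv2d, Module, Sequential, UpsampleNearest2x
from .nn_blocks import CBS, ECA, BlockDescriptor, GhostBottleneck

#: standard COCO anchor priors (input-pixel units), small → large scale
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

#: neck width calibrated once so the 1-class model totals ~2.0 M parameters
#: (width 108 -> 1,971,873 trainable parameters, i.e. 2.0 M at one decimal)
DEFAULT_WIDTH = 108


@dataclass(frozen=True)
class C3ECAGhostConfig:
    in_channels: int
    out_channels: int
    n_bottlenecks: int = 3
    ghost_ratio: int = 2
    eca_kernel: int = 3

    def __post_init__(self):
        if self.out_channels % 2:
            raise ValueError("out_channels must be even (two half-width branches)")
        if self.n_bottlenecks < 1:
            raise ValueError("need at least one bottleneck")


@dataclass(frozen=True)
class HeadConfig:
    num_classes: int = 1
    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")
        if len(self.anchors) != len(self.strides):
            raise ValueError("one anchor triple per stride")

    @property
    def out_channels(self) -> int:
        return 3 * (5 + self.num_classes)


@dataclass
class Detection:
    """One decoded candidate box in input-pixel units."""

    box: tuple[float, float, float, float]   # (cx, cy, w, h)
    objectness: float
    class_scores: np.ndarray
    class_id: int = 0

    @property
    def confidence(self) -> float:
        return float(self.objectness * self.class_scores.max())


class C3ECAGhost(Module):
    """Two-branch ghost-bottleneck block with channel-attention fusion."""

    def __init__(self, cfg: C3ECAGhostConfig):
        super().__init__()
        half = cfg.out_channels // 2
        bottlenecks = [
            GhostBottleneck(BlockDescriptor(
                kind="GhostBottleneck", in_channels=half, out_channels=half,
                stride=1, expansion=2, ghost_ratio=cfg.ghost_ratio))
            for _ in range(cfg.n_bottlenecks)
        ]
        self.branch1 = Sequential(CBS(cfg.in_channels, half, 1, 1), *bottlenecks)
        self.branch2 = CBS(cfg.in_channels, half, 1, 1)
        self.fuse = CBS(cfg.out_channels, cfg.out_channels, 1, 1)
        self.eca = ECA(cfg.out_channels, cfg.eca_kernel)

    def forward(self, x):
        y = ad.concat([self.branch1(x), self.branch2(x)], axis=1)
        return self.eca(self.fuse(y))


def make_c3ecaghost(cfg: C3ECAGhostConfig) -> C3ECAGhost:
    return C3ECAGhost(cfg)


class Neck(Module):
    """Top-down + bottom-up fusion emitting (width, 2*width, 4*width) maps."""

    def __init__(self, p_channels: tuple[int, int, int], width: int = DEFAULT_WIDTH):
        super().__init__()
        if width % 2:
            raise ValueError("width must be even")
        c3, c4, c5 = p_channels
        w = width
        self.reduce5 = CBS(c5, 2 * w, 1, 1)
        self.up = UpsampleNearest2x()
        self.td4 = C3ECAGhost(C3ECAGhostConfig(2 * w + c4, 2 * w))
        self.reduce4 = CBS(2 * w, w, 1, 1)
        self.td3 = C3ECAGhost(C3ECAGhostConfig(w + c3, w))
        self.down3 = CBS(w, w, 3, 2)
        self.bu4 = C3ECAGhost(C3ECAGhostConfig(2 * w, 2 * w))
        self.down4 = CBS(2 * w, 2 * w, 3, 2)
        self.bu5 = C3ECAGhost(C3ECAGhostConfig(4 * w, 4 * w))
        self.out_channels = (w, 2 * w, 4 * w)

    def forward(self, p3, p4, p5):
        r5 = self.reduce5(p5)
        t4 = self.td4(ad.concat([self.up(r5), p4], axis=1))
        r4 = self.reduce4(t4)
        n3 = self.td3(ad.concat([self.up(r4), p3], axis=1))
        n4 = self.bu4(ad.concat([self.down3(n3), r4], axis=1))
        n5 = self.bu5(ad.concat([self.down4(n4), r5], axis=1))
        return n3, n4, n5


def build_neck(p_channels: tuple[int, int, int], width: int = DEFAULT_WIDTH) -> Neck:
    return Neck(p_channels, width)


class Heads(Module):
    """One biased 1x1 conv per scale; raw logits out."""

    def __init__(self, cfg: HeadConfig, neck_widths: tuple[int, int, int]):
        super().__init__()
        self.cfg = cfg
        self.convs = [Conv2d(cin, cfg.out_channels, 1, bias=True)
                      for cin in neck_widths]
        # bias priors: start objectness rare so early training is stable
        for conv in self.convs:
            b = conv.bias.data.reshape(3, 5 + cfg.num_classes)
            b[:, 4] = -4.0
            conv.bias.data = b.reshape(-1)

    def forward(self, feats):
        return [conv(f) for conv, f in zip(self.convs, feats)]


def build_heads(cfg: HeadConfig, neck_widths: tuple[int, int, int]) -> Heads:
    if len(neck_widths) != 3:
        raise ValueError("expected three neck widths")
    return Heads(cfg, neck_widths)


class Detector(Module):
    """Backbone + neck + heads; forward returns raw per-scale logits."""

    def __init__(self, head_cfg: HeadConfig | None = None,
                 width: int = DEFAULT_WIDTH, backbone: Backbone | None = None):
        super().__init__()
        self.backbone = backbone if backbone is not None else build_backbone()
        self.head_cfg = head_cfg or HeadConfig()
        self.neck = build_neck(self.backbone.tap_channels, width)
        self.heads = build_heads(self.head_cfg, self.neck.out_channels)
        self.width = width

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input dims ({h}x{w}) must be multiples of 32")
        p3, p4, p5 = self.backbone(x)
        return self.heads(self.neck(p3, p4, p5))


# ---------------------------------------------------------------------------
# decode / encode
# ---------------------------------------------------------------------------

def _split_raw(raw: np.ndarray, num_classes: int):
    """(N, 3*(5+nc), H, W) -> (N, 3, H, W, 5+nc)."""
    n, c, h, w = raw.shape
    return raw.reshape(n, 3, 5 + num_classes, h, w).transpose(0, 1, 3, 4, 2)


def decode(outputs, cfg: HeadConfig, conf_threshold: float = 0.0):
    """Raw head logits -> per-image arrays of candidate boxes.

    Per cell and anchor: center ``(2*sig(t) - 0.5 + cell) * stride``, size
    ``(2*sig(t))**2 * anchor``; objectness/class scores through sigmoids;
    confidence = objectness * class score.

    Returns one ``(M, 6 + num_classes)`` array per image with columns
    ``cx, cy, w, h, confidence, class_id, class scores...``.
    """
    nc = cfg.num_classes
    batch = None
    per_scale = []
    for raw, anchors, stride in zip(outputs, cfg.anchors, cfg.strides):
        data = raw.data if isinstance(raw, Tensor) else np.asarray(raw)
        n, _, h, w = data.shape
        batch = n if batch is None else batch
        p = _split_raw(data, nc)
        sig = expit(p)
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        a = np.asarray(anchors, dtype=np.float32)        # (3, 2)
        cx = (2 * sig[..., 0] - 0.5 + gx) * stride
        cy = (2 * sig[..., 1] - 0.5 + gy) * stride
        bw = (2 * sig[..., 2]) ** 2 * a[:, 0][None, :, None, None]
        bh = (2 * sig[..., 3]) ** 2 * a[:, 1][None, :, None, None]
        obj = sig[..., 4]
        cls = sig[..., 5:]
        conf = obj[..., None] * cls
        best = conf.max(axis=-1)
        cls_id = conf.argmax(axis=-1)
        flat = np.stack([cx, cy, bw, bh, best, cls_id.astype(np.float32)], axis=-1)
        flat = np.concatenate([flat, cls], axis=-1).reshape(n, -1, 6 + nc)
        per_scale.append(flat)
    merged = np.concatenate(per_scale, axis=1)
    return [img[img[:, 4] >= conf_threshold] for img in merged]


def encode_box(box, anchor, stride, cell) -> np.ndarray:
    """Algebraic inverse of the decode transform (for boxes in valid range)."""
    cx, cy, w, h = box
    aw, ah = anchor
    ci, cj = cell  # (col, row)

    def logit(p):
        return np.log(p / (1.0 - p))

    tx = logit(np.clip((cx / stride - ci + 0.5) / 2.0, 1e-7, 1 - 1e-7))
    ty = logit(np.clip((cy / stride - cj + 0.5) / 2.0, 1e-7, 1 - 1e-7))
    tw = logit(np.clip(np.sqrt(w / aw) / 2.0, 1e-7, 1 - 1e-7))
    th = logit(np.clip(np.sqrt(h / ah) / 2.0, 1e-7, 1 - 1e-7))
    return np.array([tx, ty, tw, th], dtype=np.float64)


def to_detections(decoded: np.ndarray, num_classes: int = 1) -> list[Detection]:
    """Expand one decoded array into Detection records."""
    dets = []
    for row in decoded:
        cls_scores = row[6:6 + num_classes]
        obj = row[4] / max(cls_scores.max(), 1e-12)
        dets.append(Detection(box=tuple(row[:4]), objectness=min(obj, 1.0),
                              class_scores=cls_scores, class_id=int(row[5])))
    return dets


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def detections_to_yolo_txt(decoded: np.ndarray, img_w: int, img_h: int) -> str:
    """Decoded rows -> normalised YOLO label lines with confidence."""
    lines = []
    for row in decoded:
        cx, cy, w, h, conf, cls_id = row[:6]
        lines.append(f"{int(cls_id)} {cx / img_w:.6f} {cy / img_h:.6f} "
                     f"{w / img_w:.6f} {h / img_h:.6f} {conf:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def detections_to_coco(decoded: np.ndarray, image_id: int) -> list[dict]:
    """Decoded rows -> COCO detection records (xywh, top-left origin)."""
    recs = []
    for row in decoded:
        cx, cy, w, h, conf, cls_id = row[:6]
        recs.append({
            "image_id": image_id,
            "category_id": int(cls_id),
            "bbox": [float(cx - w / 2), float(cy - h / 2), float(w), float(h)],
            "score": float(conf),
        })
    return recs
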