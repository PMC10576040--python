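"""Dataset I/O, video-grouped splitting, augmentation, synthetic scenes.

Labels travel as normalised YOLO-txt rows (``class cx cy w h``).  Because the
original barn footage is private, :func:`generate_scene` renders stand-in
scenes with the same statistical shape: dense elliptical animal silhouettes
at near/far camera scales, day/night lighting regimes, and mounting events
drawn as high-overlap silhouette pairs labelled by one union box.  Labels
are exact by construction (closed-form ellipse extents), which gives the
test-suite an independent pixel-mask oracle to check them against.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, warp


@dataclass
class LabeledImage:
    """An RGB frame plus its normalised class-tagged boxes."""

    image: np.ndarray                      # H x W x 3 uint8
    boxes: np.ndarray                      # (N, 5): class, cx, cy, w, h in [0,1]
    source_video: str = ""
    lighting_tag: str = "day"

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 5)


# ---------------------------------------------------------------------------
# YOLO-txt labels
# ---------------------------------------------------------------------------

def read_yolo_labels(path) -> np.ndarray:
    """Parse a YOLO label file into an (N, 5) array.

    Malformed rows raise with their line number; out-of-range coordinates are
    clipped into [0, 1] with a warning.
    """
    rows = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: expected 'class cx cy w h', "
                             f"got {line!r}")
        try:
            cls = int(float(parts[0]))
            vals = [float(p) for p in parts[1:5]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
        clipped = np.clip(vals, 0.0, 1.0)
        if not np.allclose(clipped, vals):
            warnings.warn(f"{path}:{lineno}: coordinates outside [0,1] clipped")
        rows.append([cls, *clipped])
    return np.asarray(rows, dtype=np.float64).reshape(-1, 5)


def write_yolo_labels(boxes: np.ndarray, path) -> None:
    boxes = np.asarray(boxes).reshape(-1, 5)
    lines = [f"{int(b[0])} {b[1]:.6f} {b[2]:.6f} {b[3]:.6f} {b[4]:.6f}"
             for b in boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def split_by_video(videos: Sequence, ratio: float = 0.8):
    """Deterministic video-level split: first floor(ratio*N) train, rest test."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    videos = list(videos)
    if not videos:
        raise ValueError("empty video list")
    n_train = int(math.floor(ratio * len(videos)))
    return videos[:n_train], videos[n_train:]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

#: member-transform ranges for mosaic placement
MOSAIC_ROTATION_DEG = 10.0
MOSAIC_TRANSLATE_FRAC = 0.10
MOSAIC_SCALE_RANGE = (0.5, 1.5)
MOSAIC_FILL = 114

#: box survival rule after clipping
MIN_BOX_AREA_FRAC = 0.10
MIN_BOX_SIDE_PX = 2.0


def _member_transform(sw, sh, quad, rng, *, identity=False):
    """Forward affine mapping sample pixels into a canvas quadrant."""
    qx0, qy0, qx1, qy1 = quad
    qw, qh = qx1 - qx0, qy1 - qy0
    fit = min(qw / sw, qh / sh)
    if identity:
        theta, scale, tx, ty = 0.0, fit, 0.0, 0.0
    else:
        theta = math.radians(rng.uniform(-MOSAIC_ROTATION_DEG, MOSAIC_ROTATION_DEG))
        scale = fit * rng.uniform(*MOSAIC_SCALE_RANGE)
        tx = rng.uniform(-MOSAIC_TRANSLATE_FRAC, MOSAIC_TRANSLATE_FRAC) * qw
        ty = rng.uniform(-MOSAIC_TRANSLATE_FRAC, MOSAIC_TRANSLATE_FRAC) * qh
    centre = AffineTransform(translation=(-sw / 2.0, -sh / 2.0))
    spin = AffineTransform(scale=(scale, scale), rotation=theta)
    place = AffineTransform(translation=(qx0 + qw / 2.0 + tx, qy0 + qh / 2.0 + ty))
    return centre + spin + place


def mosaic4(samples: Sequence[LabeledImage], out_size: int,
            rng: np.random.Generator, *, identity: bool = False) -> LabeledImage:
    """Stitch four samples into one canvas with transformed boxes.

    A random centre partitions the canvas into quadrants; each member is
    scaled/rotated/translated into its quadrant.  Boxes are re-fit from
    transformed corners, clipped to the quadrant, and dropped when the
    residual area falls under 10% of the transformed box or a side shrinks
    below 2 px.  ``identity=True`` forces the degenerate (no-jitter)
    placement used by shape oracles.
    """
    if len(samples) != 4:
        raise ValueError("mosaic4 needs exactly 4 samples")
    s = out_size
    if identity:
        mx = my = s // 2
    else:
        mx = int(rng.uniform(0.25, 0.75) * s)
        my = int(rng.uniform(0.25, 0.75) * s)
    quads = [(0, 0, mx, my), (mx, 0, s, my), (0, my, mx, s), (mx, my, s, s)]
    canvas = np.full((s, s, 3), MOSAIC_FILL, dtype=np.uint8)
    out_boxes = []
    for sample, quad in zip(samples, quads):
        sh, sw = sample.image.shape[:2]
        tform = _member_transform(sw, sh, quad, rng, identity=identity)
        warped = warp(sample.image, inverse_map=tform.inverse,
                      output_shape=(s, s), order=1, cval=MOSAIC_FILL / 255.0,
                      preserve_range=True)
        qx0, qy0, qx1, qy1 = quad
        canvas[qy0:qy1, qx0:qx1] = warped[qy0:qy1, qx0:qx1].round().astype(np.uint8)
        for cls, cx, cy, w, h in sample.boxes:
            corners = np.array([
                [(cx - w / 2) * sw, (cy - h / 2) * sh],
                [(cx + w / 2) * sw, (cy - h / 2) * sh],
                [(cx + w / 2) * sw, (cy + h / 2) * sh],
                [(cx - w / 2) * sw, (cy + h / 2) * sh]])
            moved = tform(corners)
            x0, y0 = moved.min(axis=0)
            x1, y1 = moved.max(axis=0)
            area = (x1 - x0) * (y1 - y0)
            cx0, cy0 = max(x0, qx0), max(y0, qy0)
            cx1, cy1 = min(x1, qx1), min(y1, qy1)
            if cx1 - cx0 < MIN_BOX_SIDE_PX or cy1 - cy0 < MIN_BOX_SIDE_PX:
                continue
            if (cx1 - cx0) * (cy1 - cy0) < MIN_BOX_AREA_FRAC * area:
                continue
            out_boxes.append([cls, (cx0 + cx1) / 2 / s, (cy0 + cy1) / 2 / s,
                              (cx1 - cx0) / s, (cy1 - cy0) / s])
    videos = ",".join(dict.fromkeys(s_.source_video for s_ in samples))
    return LabeledImage(canvas, np.asarray(out_boxes, dtype=np.float64),
                        source_video=videos, lighting_tag=samples[0].lighting_tag)


def photometric_jitter(img: np.ndarray, rng: np.random.Generator,
                       hue: float = 0.015, saturation: float = 0.7,
                       value: float = 0.4, contrast: float = 0.2) -> np.ndarray:
    """Random bounded gains on hue/saturation/value plus a contrast stretch."""
    gains = 1.0 + rng.uniform(-1, 1, size=4) * [hue, saturation, value, contrast]
    if np.all(gains == 1.0):
        return img.copy()
    hsv = rgb2hsv(img.astype(np.float32) / 255.0)
    hsv[..., 0] = np.mod(hsv[..., 0] * gains[0], 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * gains[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * gains[2], 0, 1)
    out = hsv2rgb(hsv)
    out = np.clip((out - 0.5) * gains[3] + 0.5, 0, 1)
    return (out * 255.0).round().astype(np.uint8)


def vflip(sample: LabeledImage, p: float = 0.5,
          rng: np.random.Generator | None = None) -> LabeledImage:
    """Mirror rows with probability ``p``; box centres map cy -> 1 - cy."""
    if rng is not None and rng.random() >= p:
        return sample
    boxes = sample.boxes.copy()
    if len(boxes):
        boxes[:, 2] = 1.0 - boxes[:, 2]
    return replace(sample, image=sample.image[::-1].copy(), boxes=boxes)


# ---------------------------------------------------------------------------
# synthetic barn scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Statistical shape of a rendered barn frame."""

    canvas: tuple[int, int] = (2560, 1440)        # (width, height)
    n_animals: tuple[int, int] = (6, 14)          # bystander herd size range
    mounting_pairs: tuple[int, int] = (1, 2)
    scale_range: tuple[float, float] = (0.5, 1.0)  # far -> near camera factor
    overlap_frac: float = 0.35                     # min silhouette overlap
    night_prob: float = 0.3

    def __post_init__(self):
        w, h = self.canvas
        if min(w, h) < 64:
            raise ValueError("canvas too small for the configured scales")
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0,1)")


def _ellipse_bbox(cx, cy, a, b, theta):
    """Axis-aligned extents of a rotated ellipse (closed form)."""
    hw = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    hh = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    return cx - hw, cy - hh, cx + hw, cy + hh


def _draw_ellipse(img, cx, cy, a, b, theta, color, yy, xx):
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[mask] = color
    return mask


def generate_scene(cfg: SceneConfig, rng: np.random.Generator) -> LabeledImage:
    """Render one labelled frame; label boxes come from ellipse geometry."""
    w, h = cfg.canvas
    base = np.array([126, 112, 90], dtype=np.float32)
    noise = gaussian_filter(rng.normal(0, 22, size=(h, w, 1)), sigma=(6, 6, 0))
    img = np.clip(base + noise + rng.normal(0, 4, size=(h, w, 3)), 0, 255)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    unit = 0.11 * min(w, h)  # reference body half-length
    # bystander herd: single mid-brown silhouettes
    n_animals = int(rng.integers(cfg.n_animals[0], cfg.n_animals[1] + 1))
    for _ in range(n_animals):
        f = rng.uniform(*cfg.scale_range)
        a, b = unit * f, unit * f * rng.uniform(0.42, 0.55)
        cx, cy = rng.uniform(a, w - a), rng.uniform(b, h - b)
        theta = rng.uniform(0, math.pi)
        shade = rng.uniform(55, 115)
        color = np.array([shade * 1.15, shade, shade * 0.85])
        _draw_ellipse(img, cx, cy, a, b, theta, color, yy, xx)

    # mounting events: one pale + one dark silhouette with forced overlap
    boxes = []
    n_pairs = int(rng.integers(cfg.mounting_pairs[0], cfg.mounting_pairs[1] + 1))
    for _ in range(n_pairs):
        f = rng.uniform(*cfg.scale_range)
        a1, b1 = unit * f, unit * f * rng.uniform(0.45, 0.55)
        margin = 2.2 * a1
        cx1 = rng.uniform(margin, w - margin)
        cy1 = rng.uniform(margin, h - margin)
        th1 = rng.uniform(0, math.pi)
        # partner offset short enough to guarantee the configured overlap
        d = (1.0 - cfg.overlap_frac) * (a1 + b1) / 2.0
        phi = rng.uniform(0, 2 * math.pi)
        cx2, cy2 = cx1 + d * math.cos(phi), cy1 + d * math.sin(phi)
        a2, b2 = a1 * rng.uniform(0.85, 1.0), b1 * rng.uniform(0.85, 1.0)
        th2 = th1 + rng.uniform(-0.5, 0.5)
        _draw_ellipse(img, cx1, cy1, a1, b1, th1,
                      np.array([228, 224, 214]), yy, xx)
        _draw_ellipse(img, cx2, cy2, a2, b2, th2,
                      np.array([34, 30, 30]), yy, xx)
        x0a, y0a, x1a, y1a = _ellipse_bbox(cx1, cy1, a1, b1, th1)
        x0b, y0b, x1b, y1b = _ellipse_bbox(cx2, cy2, a2, b2, th2)
        x0, y0 = max(min(x0a, x0b), 0.0), max(min(y0a, y0b), 0.0)
        x1, y1 = min(max(x1a, x1b), float(w)), min(max(y1a, y1b), float(h))
        boxes.append([0, (x0 + x1) / 2 / w, (y0 + y1) / 2 / h,
                      (x1 - x0) / w, (y1 - y0) / h])

    night = rng.random() < cfg.night_prob
    if night:
        grey = img.mean(axis=2, keepdims=True)
        img = 0.35 * (0.6 * img + 0.4 * grey)
    return LabeledImage(img.round().astype(np.uint8),
                        np.asarray(boxes, dtype=np.float64),
                        lighting_tag="night" if night else "day")


def generate_dataset(cfg: SceneConfig, n_videos: int, frames_per_video: int,
                     out_dir, seed: int = 0, overwrite: bool = False) -> dict:
    """Write a video-grouped image/label tree plus a JSON manifest.

    Frames of one synthetic "video" share a lighting regime and camera
    distance, mirroring how real clips behave; the manifest is compatible
    with :func:`split_by_video` over its video ids.
    """
    out_dir = Path(out_dir)
    img_dir, lbl_dir = out_dir / "images", out_dir / "labels"
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "canvas": list(cfg.canvas), "videos": {}}
    for v in range(n_videos):
        vid = f"vid{v:03d}"
        night = rng.random() < cfg.night_prob
        lo, hi = cfg.scale_range
        mid = rng.uniform(lo, hi)  # per-video camera distance
        vid_cfg = replace(cfg, night_prob=1.0 if night else 0.0,
                          scale_range=(max(lo, mid * 0.8), min(hi, mid * 1.2)))
        frames = []
        for f in range(frames_per_video):
            scene = generate_scene(vid_cfg, rng)
            stem = f"{vid}_f{f:03d}"
            Image.fromarray(scene.image).save(img_dir / f"{stem}.png")
            write_yolo_labels(scene.boxes, lbl_dir / f"{stem}.txt")
            frames.append({"stem": stem, "n_boxes": int(len(scene.boxes))})
        manifest["videos"][vid] = {
            "lighting": "night" if night else "day",
            "n_frames": frames_per_video,
            "frames": frames,
        }
    manifest["n_images"] = n_videos * frames_per_video
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(root) -> list[LabeledImage]:
    """Read an image/label tree written by :func:`generate_dataset`."""
    root = Path(root)
    samples = []
    manifest = json.loads((root / "manifest.json").read_text())
    for vid, info in manifest["videos"].items():
        for fr in info["frames"]:
            img = np.asarray(Image.open(root / "images" / f"{fr['stem']}.png").convert("RGB"))
            boxes = read_yolo_labels(root / "labels" / f"{fr['stem']}.txt")
            samples.append(LabeledImage(img, boxes, source_video=vid,
                                        lighting_tag=info["lighting"]))
    return samples


def dataset_to_coco(samples: Sequence[LabeledImage], class_names=("mounting",)) -> dict:
    """Export ground truth as a COCO-JSON dictionary."""
    images, annotations = [], []
    ann_id = 1
    for i, s in enumerate(samples):
        h, w = s.image.shape[:2]
        images.append({"id": i, "width": w, "height": h,
                       "file_name": f"{s.source_video}_{i}.png"})
        for cls, cx, cy, bw, bh in s.boxes:
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": int(cls),
                "bbox": [(cx - bw / 2) * w, (cy - bh / 2) * h, bw * w, bh * h],
                "area": bw * w * bh * h, "iscrowd": 0})
            ann_id += 1
    return {"images": images, "annotations": annotations,
            "categories": [{"id": i, "name": n} for i, n in enumerate(class_names)]}
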