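"""Detection metrics: IoU, NMS, TP/FP matching, AP and mAP.

Detections are ``(M, 6)`` arrays — ``cx, cy, w, h, confidence, class_id`` —
and ground truths ``(K, 5)`` arrays — ``class_id, cx, cy, w, h`` — in any
consistent unit.  Matching is greedy in confidence order with a one-to-one
IoU >= threshold rule; AP integrates the monotone precision envelope over
all recall change points (all-point integration), with a 101-point
interpolated variant behind a flag.

Recall = TP/(TP+FN), precision = TP/(TP+FP); mAP averages the per-class AP,
and for a ranged IoU spec additionally averages over thresholds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

RANGED_IOU = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


def _to_corners(box, fmt: str):
    box = np.asarray(box, dtype=np.float64)
    if fmt == "xyxy":
        return box
    cx, cy, w, h = box[..., 0], box[..., 1], box[..., 2], box[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def iou(a, b, fmt: str = "cxcywh") -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if fmt == "cxcywh" and (a[2] < 0 or a[3] < 0 or b[2] < 0 or b[3] < 0):
        raise ValueError("negative box dimensions")
    ax0, ay0, ax1, ay1 = _to_corners(a, fmt)
    bx0, by0, bx1, by1 = _to_corners(b, fmt)
    if fmt == "xyxy" and (ax1 < ax0 or ay1 < ay0 or bx1 < bx0 or by1 < by0):
        raise ValueError("negative box dimensions")
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray, fmt: str = "cxcywh") -> np.ndarray:
    """Pairwise IoU, (len(a), len(b))."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ac = _to_corners(np.asarray(a, dtype=np.float64), fmt)
    bc = _to_corners(np.asarray(b, dtype=np.float64), fmt)
    x0 = np.maximum(ac[:, None, 0], bc[None, :, 0])
    y0 = np.maximum(ac[:, None, 1], bc[None, :, 1])
    x1 = np.minimum(ac[:, None, 2], bc[None, :, 2])
    y1 = np.minimum(ac[:, None, 3], bc[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = (ac[:, 2] - ac[:, 0]) * (ac[:, 3] - ac[:, 1])
    area_b = (bc[:, 2] - bc[:, 0]) * (bc[:, 3] - bc[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(union)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def _sort_order(dets: np.ndarray) -> np.ndarray:
    """Deterministic ordering: confidence desc, then box area desc."""
    area = dets[:, 2] * dets[:, 3]
    return np.lexsort((-area, -dets[:, 4]))


def nms(dets: np.ndarray, iou_threshold: float = 0.45,
        conf_threshold: float = 0.001) -> np.ndarray:
    """Class-aware greedy non-maximum suppression."""
    dets = np.asarray(dets, dtype=np.float64)
    if dets.size == 0:
        return dets.reshape(0, 6)
    dets = dets.reshape(-1, dets.shape[-1])
    dets = dets[dets[:, 4] >= conf_threshold]
    if len(dets) == 0:
        return dets
    dets = dets[_sort_order(dets)]
    keep = []
    alive = np.ones(len(dets), dtype=bool)
    for i in range(len(dets)):
        if not alive[i]:
            continue
        keep.append(i)
        rest = np.where(alive[i + 1:])[0] + i + 1
        if len(rest) == 0:
            continue
        same = dets[rest, 5] == dets[i, 5]
        ious = iou_matrix(dets[i:i + 1, :4], dets[rest, :4])[0]
        alive[rest[same & (ious > iou_threshold)]] = False
    return dets[keep]


@dataclass
class MatchResult:
    """Confidence-ordered TP/FP flags for one image set at one IoU level."""

    tp: np.ndarray                 # bool per detection, confidence-ordered
    conf: np.ndarray
    n_gt: int

    @property
    def fn(self) -> int:
        return self.n_gt - int(self.tp.sum())

    def precision_recall(self) -> tuple[np.ndarray, np.ndarray]:
        tp_cum = np.cumsum(self.tp)
        fp_cum = np.cumsum(~self.tp)
        p = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
        r = tp_cum / max(self.n_gt, 1e-12)
        return p, r


def match_detections(dets: np.ndarray, gts: np.ndarray,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching: best unmatched same-class GT wins."""
    dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
    order = _sort_order(dets) if len(dets) else np.zeros(0, dtype=int)
    dets = dets[order]
    taken = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i, d in enumerate(dets):
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if taken[j] or int(g[0]) != int(d[5]):
                continue
            v = iou(d[:4], g[1:5])
            if v >= best_iou and v > 0:
                if v > best_iou or best_j == -1:
                    best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            tp[i] = True
    return MatchResult(tp=tp, conf=dets[:, 4].copy(), n_gt=len(gts))


def average_precision(match: MatchResult, interpolation: str = "all") -> float | None:
    """Area under the enveloped PR curve; None when there is no ground truth.

    ``interpolation='all'`` integrates precision over every recall change
    point; ``'101'`` samples the envelope on the 101-point recall grid.
    """
    if match.n_gt == 0:
        return None
    if len(match.tp) == 0:
        return 0.0
    p, r = match.precision_recall()
    mrec = np.concatenate([[0.0], r, [r[-1]]])
    mpre = np.concatenate([[1.0], p, [0.0]])
    # monotone-decreasing precision envelope
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    if interpolation == "101":
        grid = np.linspace(0, 1, 101)
        env = np.array([mpre[np.searchsorted(mrec, g, side="left")]
                        if g <= mrec[-1] else 0.0 for g in grid])
        return float(env.mean())
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass
class EvalResult:
    """Per-class AP, mAP and operating-point precision/recall."""

    per_class_ap: dict[int, float | None]
    map: float
    iou_spec: str
    precision: float | None = None
    recall: float | None = None
    pr_points: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "iou_spec": self.iou_spec,
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "mAP": self.map,
            "precision": self.precision,
            "recall": self.recall,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    def write_pr_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["class", "recall", "precision"])
            for cls, (p, r) in self.pr_points.items():
                for pi, ri in zip(p, r):
                    wr.writerow([cls, f"{ri:.6f}", f"{pi:.6f}"])


def coco_to_arrays(coco_gt: dict, detections: list[dict] | None = None):
    """COCO-JSON ground truth (+ optional detection records) -> per-image
    arrays in the package's native layout (pixel units, centre boxes)."""
    ids = [img["id"] for img in coco_gt["images"]]
    gts = {i: [] for i in ids}
    for ann in coco_gt["annotations"]:
        x, y, w, h = ann["bbox"]
        gts[ann["image_id"]].append(
            [ann["category_id"], x + w / 2, y + h / 2, w, h])
    dets = {i: [] for i in ids}
    for rec in detections or []:
        x, y, w, h = rec["bbox"]
        dets[rec["image_id"]].append(
            [x + w / 2, y + h / 2, w, h, rec["score"], rec["category_id"]])
    gts_per_image = [np.asarray(gts[i], dtype=np.float64).reshape(-1, 5)
                     for i in ids]
    dets_per_image = [np.asarray(dets[i], dtype=np.float64).reshape(-1, 6)
                      for i in ids]
    return dets_per_image, gts_per_image


def _dataset_match(dets_per_image: Sequence[np.ndarray],
                   gts_per_image: Sequence[np.ndarray],
                   cls: int, thr: float) -> MatchResult:
    """Dataset-level matching for one class: global confidence order,
    per-image one-to-one assignment."""
    recs = []  # (conf, area, img, box)
    n_gt = 0
    per_img_gt = []
    for img, (dets, gts) in enumerate(zip(dets_per_image, gts_per_image)):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
        g = gts[gts[:, 0].astype(int) == cls]
        per_img_gt.append(g)
        n_gt += len(g)
        for d in dets[dets[:, 5].astype(int) == cls]:
            recs.append((d[4], d[2] * d[3], img, d[:4]))
    recs.sort(key=lambda t: (-t[0], -t[1]))
    taken = [np.zeros(len(g), dtype=bool) for g in per_img_gt]
    tp = np.zeros(len(recs), dtype=bool)
    conf = np.array([r[0] for r in recs])
    for i, (c, _, img, box) in enumerate(recs):
        g = per_img_gt[img]
        if len(g) == 0:
            continue
        ious = iou_matrix(box[None], g[:, 1:5])[0]
        ious[taken[img]] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= thr and ious[j] > 0:
            taken[img][j] = True
            tp[i] = True
    return MatchResult(tp=tp, conf=conf, n_gt=n_gt)


def mean_average_precision(dets_per_image: Sequence[np.ndarray],
                           gts_per_image: Sequence[np.ndarray],
                           iou_spec="0.5",
                           conf_threshold: float | None = None,
                           interpolation: str = "all") -> EvalResult:
    """mAP over classes and (optionally) the 0.5:0.95 threshold range.

    ``iou_spec`` is a float, an iterable of thresholds, or one of the strings
    ``"0.5"`` / ``"0.5:0.95"``.
    """
    if isinstance(iou_spec, str):
        thresholds = RANGED_IOU if iou_spec == "0.5:0.95" else (float(iou_spec),)
        spec_name = iou_spec
    elif isinstance(iou_spec, (int, float)):
        thresholds = (float(iou_spec),)
        spec_name = f"{iou_spec:g}"
    else:
        thresholds = tuple(float(t) for t in iou_spec)
        spec_name = ",".join(f"{t:g}" for t in thresholds)

    classes = sorted({int(c) for g in gts_per_image
                      for c in np.asarray(g).reshape(-1, 5)[:, 0]})
    per_class: dict[int, float | None] = {}
    pr_points: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cls in classes:
        aps = []
        for thr in thresholds:
            m = _dataset_match(dets_per_image, gts_per_image, cls, thr)
            ap = average_precision(m, interpolation)
            if ap is not None:
                aps.append(ap)
            if thr == thresholds[0]:
                pr_points[cls] = m.precision_recall()
        per_class[cls] = float(np.mean(aps)) if aps else None
    valid = [v for v in per_class.values() if v is not None]
    result = EvalResult(per_class_ap=per_class,
                        map=float(np.mean(valid)) if valid else 0.0,
                        iou_spec=spec_name, pr_points=pr_points)

    if conf_threshold is not None and classes:
        tp = fp = fn = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
            strong = dets[dets[:, 4] >= conf_threshold]
            m = match_detections(strong, gts, thresholds[0])
            tp += int(m.tp.sum())
            fp += int((~m.tp).sum())
            fn += m.fn
        result.precision = tp / (tp + fp) if tp + fp else None
        result.recall = tp / (tp + fn) if tp + fn else None
    return result
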