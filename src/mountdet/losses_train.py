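"""Target assignment, three-part detection loss, schedule and training loop.

The loss follows the anchor-based recipe the detector is built on: a CIoU
regression term over positive cells, a binary cross-entropy objectness term
over every cell (scored against the achieved IoU), and a binary
cross-entropy classification term with smoothed labels.  Assignment is
multi-positive: a ground truth claims an anchor when the width/height ratio
test passes, in its own cell plus the two nearest neighbour cells.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor
from .data_io_aug import LabeledImage, mosaic4, photometric_jitter, vflip
from .evaluation import mean_average_precision, nms
from .neck_head import Detector, HeadConfig, decode

_BALANCE = (4.0, 1.0, 0.4)        # per-scale objectness weighting
_ANCHOR_T = 4.0                   # anchor-ratio gate


@dataclass
class TrainConfig:
    """Training recipe; defaults mirror the published settings."""

    input_size: int = 640
    batch_size: int = 40
    epochs: int = 200
    lr0: float = 0.01
    lr_final_fraction: float = 0.01
    label_smoothing: float = 0.1
    lambda_box: float = 0.05
    lambda_obj: float = 1.0
    lambda_cls: float = 0.5
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    mosaic: bool = True
    vflip_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.label_smoothing <= 0.3:
            raise ValueError("label_smoothing must be in [0, 0.3]")
        if self.input_size % 32:
            raise ValueError("input_size must be a multiple of 32")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate from lr0 down to lr0*lr_final_fraction."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    lr_min = cfg.lr0 * cfg.lr_final_fraction
    return lr_min + 0.5 * (cfg.lr0 - lr_min) * (1 + math.cos(math.pi * epoch / cfg.epochs))


def smooth_labels(eps: float) -> tuple[float, float]:
    """Positive/negative class targets under label smoothing."""
    if not 0 <= eps <= 0.3:
        raise ValueError("smoothing must be in [0, 0.3]")
    return 1.0 - eps / 2.0, eps / 2.0


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclass
class ScaleTargets:
    img: np.ndarray          # (M,) image indices
    anchor: np.ndarray       # (M,) anchor indices
    gj: np.ndarray           # (M,) cell row
    gi: np.ndarray           # (M,) cell col
    txy: np.ndarray          # (M, 2) centre offset from cell origin, in (-0.5, 1.5)
    twh: np.ndarray          # (M, 2) box size in grid units
    tcls: np.ndarray         # (M,) class ids
    anchors_grid: np.ndarray  # (3, 2) anchors in grid units


@dataclass
class AssignedTargets:
    per_scale: list[ScaleTargets]
    n_dropped_degenerate: int = 0


def assign_targets(labels: Sequence[np.ndarray], cfg: HeadConfig,
                   input_size: int) -> AssignedTargets:
    """Multi-positive anchor assignment over all scales.

    ``labels`` holds one ``(N, 5)`` normalised array per image.  A ground
    truth matches anchor ``a`` at a scale iff
    ``max(w/a_w, a_w/w, h/a_h, a_h/h) < 4``; the matched cell plus up to two
    nearest neighbour cells become positives.
    """
    dropped = 0
    clean = []
    for img_idx, arr in enumerate(labels):
        arr = np.asarray(arr, dtype=np.float64).reshape(-1, 5)
        ok = (arr[:, 3] > 0) & (arr[:, 4] > 0)
        dropped += int((~ok).sum())
        arr = arr[ok]
        if len(arr):
            clean.append(np.column_stack([np.full(len(arr), img_idx), arr]))
    gt = np.concatenate(clean, axis=0) if clean else np.zeros((0, 6))

    per_scale = []
    for anchors, stride in zip(cfg.anchors, cfg.strides):
        grid = input_size // stride
        a_grid = np.asarray(anchors, dtype=np.float64) / stride
        if len(gt) == 0:
            per_scale.append(ScaleTargets(*[np.zeros(0, dtype=int)] * 4,
                                          np.zeros((0, 2)), np.zeros((0, 2)),
                                          np.zeros(0, dtype=int), a_grid))
            continue
        gxy = gt[:, 2:4] * grid
        gwh = gt[:, 4:6] * grid
        recs = []
        for ai, (aw, ah) in enumerate(a_grid):
            r = np.stack([gwh[:, 0] / aw, aw / gwh[:, 0],
                          gwh[:, 1] / ah, ah / gwh[:, 1]], axis=1)
            keep = r.max(axis=1) < _ANCHOR_T
            for t in np.where(keep)[0]:
                cx, cy = gxy[t]
                cells = [(int(cx), int(cy))]
                fx, fy = cx - int(cx), cy - int(cy)
                cells.append((int(cx) + (1 if fx >= 0.5 else -1), int(cy)))
                cells.append((int(cx), int(cy) + (1 if fy >= 0.5 else -1)))
                for ci, cj in cells:
                    if not (0 <= ci < grid and 0 <= cj < grid):
                        continue
                    dx, dy = cx - ci, cy - cj
                    if not (-0.5 <= dx < 1.5 and -0.5 <= dy < 1.5):
                        continue
                    recs.append((int(gt[t, 0]), ai, cj, ci, dx, dy,
                                 gwh[t, 0], gwh[t, 1], int(gt[t, 1])))
        if recs:
            # one positive per (img, anchor, cell): keep the first claimant
            seen = set()
            uniq = []
            for rec in recs:
                key = rec[:4]
                if key not in seen:
                    seen.add(key)
                    uniq.append(rec)
            arr = np.array(uniq, dtype=np.float64)
            per_scale.append(ScaleTargets(
                img=arr[:, 0].astype(int), anchor=arr[:, 1].astype(int),
                gj=arr[:, 2].astype(int), gi=arr[:, 3].astype(int),
                txy=arr[:, 4:6], twh=arr[:, 6:8],
                tcls=arr[:, 8].astype(int), anchors_grid=a_grid))
        else:
            per_scale.append(ScaleTargets(*[np.zeros(0, dtype=int)] * 4,
                                          np.zeros((0, 2)), np.zeros((0, 2)),
                                          np.zeros(0, dtype=int), a_grid))
    return AssignedTargets(per_scale, dropped)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _ciou(pred_xy: Tensor, pred_wh: Tensor, txy: np.ndarray,
          twh: np.ndarray) -> Tensor:
    """Complete-IoU between predicted and target boxes (grid units)."""
    eps = 1e-7
    px1 = pred_xy[:, 0] - pred_wh[:, 0] * 0.5
    px2 = pred_xy[:, 0] + pred_wh[:, 0] * 0.5
    py1 = pred_xy[:, 1] - pred_wh[:, 1] * 0.5
    py2 = pred_xy[:, 1] + pred_wh[:, 1] * 0.5
    tx1, tx2 = txy[:, 0] - twh[:, 0] / 2, txy[:, 0] + twh[:, 0] / 2
    ty1, ty2 = txy[:, 1] - twh[:, 1] / 2, txy[:, 1] + twh[:, 1] / 2

    iw = ad.clamp(ad.minimum(px2, tx2) - ad.maximum(px1, tx1), lo=0.0)
    ih = ad.clamp(ad.minimum(py2, ty2) - ad.maximum(py1, ty1), lo=0.0)
    inter = iw * ih
    union = (pred_wh[:, 0] * pred_wh[:, 1] + twh[:, 0] * twh[:, 1]
             - inter + eps)
    iou_t = inter / union

    cw = ad.maximum(px2, tx2) - ad.minimum(px1, tx1)
    ch = ad.maximum(py2, ty2) - ad.minimum(py1, ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((pred_xy[:, 0] - txy[:, 0]) ** 2
            + (pred_xy[:, 1] - txy[:, 1]) ** 2)
    v = (4.0 / math.pi ** 2) * (
        ad.atan(Tensor(twh[:, 0] / (twh[:, 1] + eps)))
        - ad.atan(pred_wh[:, 0] / (pred_wh[:, 1] + eps))) ** 2
    alpha = v.data / (1.0 - iou_t.data + v.data + eps)  # detached
    return iou_t - rho2 / c2 - v * alpha


def detection_loss(predictions: Sequence[Tensor], targets: AssignedTargets,
                   cfg: TrainConfig, head_cfg: HeadConfig):
    """Weighted sum of box (1-CIoU), objectness (BCE) and class (BCE) terms."""
    nc = head_cfg.num_classes
    pos_t, neg_t = smooth_labels(cfg.label_smoothing)
    box_terms, cls_terms = [], []
    obj_term = None
    n_pos = 0
    for raw, st, balance in zip(predictions, targets.per_scale, _BALANCE):
        n, _, h, w = raw.shape
        p = ad.transpose(ad.reshape(raw, (n, 3, 5 + nc, h, w)), (0, 1, 3, 4, 2))
        tobj = np.zeros((n, 3, h, w), dtype=np.float32)
        if len(st.img):
            n_pos += len(st.img)
            ps = p[st.img, st.anchor, st.gj, st.gi]        # (M, 5+nc)
            pxy = ad.sigmoid(ps[:, 0:2]) * 2.0 - 0.5
            pwh = (ad.sigmoid(ps[:, 2:4]) * 2.0) ** 2 * st.anchors_grid[st.anchor]
            ciou = _ciou(pxy, pwh, st.txy, st.twh)
            box_terms.append((1.0 - ciou).mean())
            tobj[st.img, st.anchor, st.gj, st.gi] = np.clip(ciou.data, 0, None)
            if nc == 1:
                tcls_arr = np.full((len(st.img), 1), pos_t, dtype=np.float32)
            else:
                tcls_arr = np.full((len(st.img), nc), neg_t, dtype=np.float32)
                tcls_arr[np.arange(len(st.img)), st.tcls] = pos_t
            cls_terms.append(ad.bce_with_logits(ps[:, 5:], tcls_arr).mean())
        scale_obj = ad.bce_with_logits(p[:, :, :, :, 4], tobj).mean() * balance
        obj_term = scale_obj if obj_term is None else obj_term + scale_obj

    zero = Tensor(np.zeros(()))
    box = (sum(box_terms[1:], box_terms[0]) * (1.0 / len(box_terms))
           if box_terms else zero)
    cls = (sum(cls_terms[1:], cls_terms[0]) * (1.0 / len(cls_terms))
           if cls_terms else zero)
    # per-image weighted sum, scaled by batch size (reference convention:
    # gradients grow with the number of images contributing to the step)
    batch = predictions[0].shape[0]
    total = (cfg.lambda_box * box + cfg.lambda_obj * obj_term
             + cfg.lambda_cls * cls) * float(batch)
    return total, box, obj_term, cls


# ---------------------------------------------------------------------------
# optimiser and loop
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD; weight decay skips biases and norm parameters."""

    def __init__(self, named_params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.entries = []
        for name, p in named_params:
            decay = weight_decay if ("bn" not in name and "bias" not in name
                                     and p.data.ndim > 1) else 0.0
            self.entries.append((p, np.zeros_like(p.data), decay))
        self.lr = lr
        self.momentum = momentum

    def step(self):
        for p, buf, decay in self.entries:
            if p.grad is None:
                continue
            g = p.grad + decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self):
        for p, _, _ in self.entries:
            p.zero_grad()


@dataclass
class DetectionDataset:
    train: list[LabeledImage]
    val: list[LabeledImage] = field(default_factory=list)

    def __post_init__(self):
        if not self.train:
            raise ValueError("empty training set")


def _resize_sample(sample: LabeledImage, size: int) -> LabeledImage:
    if sample.image.shape[:2] == (size, size):
        return sample
    img = np.asarray(Image.fromarray(sample.image).resize(
        (size, size), Image.BILINEAR))
    return LabeledImage(img, sample.boxes, sample.source_video,
                        sample.lighting_tag)


def _to_batch(samples: Sequence[LabeledImage], size: int):
    imgs = np.stack([
        _resize_sample(s, size).image.astype(np.float32).transpose(2, 0, 1) / 255.0
        for s in samples])
    labels = [s.boxes for s in samples]
    return imgs, labels


def _augmented(samples: list[LabeledImage], size: int,
               cfg: TrainConfig, rng: np.random.Generator) -> LabeledImage:
    if cfg.mosaic:
        members = [samples[rng.integers(len(samples))] for _ in range(4)]
        out = mosaic4(members, size, rng)
    else:
        out = _resize_sample(samples[rng.integers(len(samples))], size)
    out = LabeledImage(photometric_jitter(out.image, rng), out.boxes,
                       out.source_video, out.lighting_tag)
    return vflip(out, p=cfg.vflip_p, rng=rng)


def evaluate_model(model: Detector, samples: Sequence[LabeledImage],
                   input_size: int, conf: float = 0.001, iou_nms: float = 0.45,
                   iou_spec="0.5", batch: int = 8):
    """Decode + NMS + mAP for a sample list; returns an EvalResult."""
    model.eval()
    dets, gts = [], []
    for i in range(0, len(samples), batch):
        chunk = samples[i:i + batch]
        imgs, labels = _to_batch(chunk, input_size)
        with ad.no_grad():
            outs = model(imgs)
        for img_dets, boxes in zip(decode(outs, model.head_cfg, conf), labels):
            kept = nms(img_dets[:, :6], iou_threshold=iou_nms, conf_threshold=conf)
            dets.append(kept)
            g = np.asarray(boxes, dtype=np.float64).reshape(-1, 5).copy()
            g[:, 1:] *= input_size
            gts.append(g)
    return mean_average_precision(dets, gts, iou_spec=iou_spec,
                                  conf_threshold=0.25)


HISTORY_FIELDS = ("epoch", "lr", "box", "obj", "cls", "total",
                  "P", "R", "mAP50", "mAP50_95")


def train(model: Detector, dataset: DetectionDataset, cfg: TrainConfig,
          out_dir=None, eval_ranged: bool = False,
          stop_at_map50: float | None = None, verbose: bool = False):
    """Run the training recipe; returns (best_state, history).

    Keeps the weights of the epoch with the highest validation mAP@0.5; with
    ``out_dir`` set, writes ``checkpoint.npz``, ``metrics.csv`` and the
    resolved config.  ``stop_at_map50`` ends the loop early once the
    validation mAP@0.5 reaches the given level.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.input_size
    opt = SGD(model.named_parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    n_iters = max(1, math.ceil(len(dataset.train) / cfg.batch_size))
    warmup_iters = cfg.warmup_epochs * n_iters
    history: list[dict] = []
    best = {"map50": -1.0, "state": model.state_dict(), "epoch": -1}

    for epoch in range(cfg.epochs):
        model.train()
        base_lr = cosine_lr(epoch, cfg)
        epoch_sums = np.zeros(4)
        for it in range(n_iters):
            step = epoch * n_iters + it
            lr = base_lr * min(1.0, (step + 1) / warmup_iters) if warmup_iters else base_lr
            opt.lr = lr
            batch_samples = [_augmented(dataset.train, size, cfg, rng)
                             for _ in range(min(cfg.batch_size, len(dataset.train)))]
            imgs, labels = _to_batch(batch_samples, size)
            preds = model(imgs)
            targets = assign_targets(labels, model.head_cfg, size)
            total, box, obj, cls = detection_loss(preds, targets, cfg,
                                                  model.head_cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_sums += [box.data.item() if box.size else 0.0,
                           obj.data.item(), cls.data.item() if cls.size else 0.0,
                           total.data.item()]
        means = epoch_sums / n_iters
        row = {"epoch": epoch, "lr": cosine_lr(epoch, cfg),
               "box": means[0], "obj": means[1], "cls": means[2],
               "total": means[3], "P": None, "R": None,
               "mAP50": None, "mAP50_95": None}
        if dataset.val:
            res = evaluate_model(model, dataset.val, size)
            row.update(P=res.precision, R=res.recall, mAP50=res.map)
            if eval_ranged:
                row["mAP50_95"] = evaluate_model(model, dataset.val, size,
                                                 iou_spec="0.5:0.95").map
            if res.map >= best["map50"]:
                best = {"map50": res.map, "state": model.state_dict(),
                        "epoch": epoch}
        else:
            best = {"map50": float("nan"), "state": model.state_dict(),
                    "epoch": epoch}
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: total={row['total']:.4f} "
                  f"mAP50={row['mAP50']}", flush=True)
        if stop_at_map50 is not None and best["map50"] >= stop_at_map50:
            break

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, cfg, out_dir / "checkpoint.npz",
                        best_state=best["state"], best_map=best["map50"])
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=HISTORY_FIELDS)
            wr.writeheader()
            for row in history:
                wr.writerow(row)
        (out_dir / "train_config.json").write_text(json.dumps(asdict(cfg), indent=1))
    return best, history


def save_checkpoint(model: Detector, cfg: TrainConfig, path,
                    best_state=None, best_map: float = float("nan")) -> None:
    meta = {
        "train_config": asdict(cfg),
        "head_cfg": {"num_classes": model.head_cfg.num_classes,
                     "anchors": [[list(a) for a in sc]
                                 for sc in model.head_cfg.anchors],
                     "strides": list(model.head_cfg.strides)},
        "width": model.width,
        "best_map50": best_map,
    }
    state = best_state if best_state is not None else model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[Detector, TrainConfig, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    hc = meta["head_cfg"]
    head_cfg = HeadConfig(num_classes=hc["num_classes"],
                          anchors=tuple(tuple(tuple(a) for a in sc)
                                        for sc in hc["anchors"]),
                          strides=tuple(hc["strides"]))
    model = Detector(head_cfg, width=meta["width"])
    model.load_state_dict(state)
    cfg = TrainConfig(**meta["train_config"])
    return model, cfg, meta
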