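# mountdet

A lightweight, CPU-only object detector for recognising cow **mounting
behaviour** (the visual sign of estrus) in dense barn scenes. The package
re-implements the full pipeline of a compact single-class detector:

- a 13-stage backbone built from Fused-MBConv / MBConv inverted-residual
  blocks with an exact, audited per-stage trainable-parameter budget
  (238,272 parameters; the assembled 1-class model rounds to 2.0 M);
- a feature-enhancement neck (FPN + PAN) whose fusion blocks combine Ghost
  bottlenecks with efficient channel attention (`C3ECAGhost`);
- three anchor-based detection heads with YOLO-style box decoding and NMS;
- the training recipe: mosaic / photometric / vertical-flip augmentation,
  multi-positive anchor assignment, CIoU + BCE losses with label smoothing,
  cosine-annealed SGD;
- a metric stack (precision, recall, AP by enveloped PR integration, mAP at
  a single or ranged IoU threshold);
- a synthetic barn-scene generator that emulates the statistical structure
  of the (private) source footage — multi-scale elliptical silhouettes,
  day/night regimes, video-grouped 8:2 splits — so everything is testable
  offline.

Everything runs on plain scientific Python: the network layer is a small
numpy reverse-mode autodiff engine bundled with the package
(`mountdet.autodiff` / `mountdet.layers`), so no deep-learning framework is
required.

## CLI

```bash
# render a synthetic video-grouped dataset (images + YOLO-txt labels)
mountdet make-synthetic data/synth --n-videos 20 --frames 10 --canvas 640 --seed 0

# audit the backbone parameter table and the full-model budget
mountdet inspect-params          # text table; --json for JSON; --strict exits 1 on mismatch

# train / detect / evaluate
mountdet train data/synth --out runs/exp1 --epochs 20 --img-size 320 --batch-size 8 --seed 0
mountdet detect runs/exp1/checkpoint.npz data/synth/images --out runs/det --conf 0.25
mountdet eval runs/det data/synth/labels --iou-spec 0.5 --out eval.json
```

All commands accept `--seed` and are deterministic given one. A YAML config
file (`--config`) can pre-set any option; explicit flags win.

## Layout

| module | contents |
| --- | --- |
| `mountdet.autodiff` | numpy tape-based autodiff (conv, BN, pooling, elementwise) |
| `mountdet.layers` | Module/Parameter system, Conv2d/BatchNorm2d/Linear, analytic parameter accounting |
| `mountdet.nn_blocks` | CBS, SE, ECA, MBConv, Fused-MBConv, GhostConv, Ghost bottleneck, SPPF; Ghost parameter/FLOP ratio analytics |
| `mountdet.backbone` | the 13-stage table-driven backbone, validation, feature taps |
| `mountdet.neck_head` | C3ECAGhost, FPN+PAN neck, heads, decode/encode, exports |
| `mountdet.losses_train` | assignment, CIoU/BCE loss, cosine schedule, SGD, training loop |
| `mountdet.data_io_aug` | YOLO-txt I/O, video splits, mosaic/jitter/flip, synthetic scenes |
| `mountdet.evaluation` | IoU, NMS, matching, AP/mAP, PR exports |
| `mountdet.cli` | `mountdet` console entry point |
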