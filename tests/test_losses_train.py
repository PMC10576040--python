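"""Schedule, label smoothing, assignment oracle, loss properties, loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from mountdet import layers
from mountdet.losses_train import (DetectionDataset, SGD, TrainConfig,
                                   assign_targets, cosine_lr, detection_loss,
                                   load_checkpoint, smooth_labels, train)
from mountdet.neck_head import Detector, HeadConfig, encode_box
from mountdet.autodiff import Tensor

SMALL = 96  # divisible by 32, keeps CPU tests quick


@pytest.fixture(scope="module")
def small_model():
    layers.seed_all(0)
    return Detector(HeadConfig(num_classes=1), width=16)


class TestCosineLR:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(epochs=200, lr0=0.01, lr_final_fraction=0.01)
        assert cosine_lr(0, cfg) == pytest.approx(0.01)
        assert cosine_lr(200, cfg) == pytest.approx(0.0001)
        assert cosine_lr(100, cfg) == pytest.approx((0.01 + 0.0001) / 2)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig(epochs=50)
        vals = [cosine_lr(e, cfg) for e in range(51)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        cfg = TrainConfig(epochs=10)
        with pytest.raises(ValueError):
            cosine_lr(11, cfg)


class TestSmoothLabels:
    def test_zero(self):
        assert smooth_labels(0.0) == (1.0, 0.0)

    def test_point_one(self):
        pos, neg = smooth_labels(0.1)
        assert pos == pytest.approx(0.95) and neg == pytest.approx(0.05)

    @settings(max_examples=50, deadline=None)
    @given(eps=st.floats(0.0, 0.3))
    def test_sum_to_one(self, eps):
        pos, neg = smooth_labels(eps)
        assert pos + neg == pytest.approx(1.0)
        assert neg <= 0.15 <= pos

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            smooth_labels(0.4)


def brute_force_assignments(labels, cfg, input_size):
    """Independent enumeration over every (scale, anchor, cell) triple."""
    out = set()
    for img, arr in enumerate(labels):
        for cls, cx, cy, w, h in np.asarray(arr).reshape(-1, 5):
            if w <= 0 or h <= 0:
                continue
            for si, (anchors, stride) in enumerate(zip(cfg.anchors, cfg.strides)):
                grid = input_size // stride
                gx, gy = cx * grid, cy * grid
                gw, gh = w * grid, h * grid
                for ai, (aw, ah) in enumerate(np.asarray(anchors) / stride):
                    if max(gw / aw, aw / gw, gh / ah, ah / gh) >= 4.0:
                        continue
                    for ci in range(grid):
                        for cj in range(grid):
                            dx, dy = gx - ci, gy - cj
                            main = ci == int(gx) and cj == int(gy)
                            nx = (cj == int(gy) and
                                  ci == int(gx) + (1 if gx - int(gx) >= 0.5 else -1))
                            ny = (ci == int(gx) and
                                  cj == int(gy) + (1 if gy - int(gy) >= 0.5 else -1))
                            if not (main or nx or ny):
                                continue
                            if -0.5 <= dx < 1.5 and -0.5 <= dy < 1.5:
                                out.add((si, img, ai, cj, ci))
    return out


class TestAssignTargets:
    CFG = HeadConfig(num_classes=1)

    def test_empty_labels(self):
        tg = assign_targets([np.zeros((0, 5))], self.CFG, 320)
        assert all(len(st.img) == 0 for st in tg.per_scale)

    def test_anchor_sized_box_assigned(self):
        # box exactly equal to anchor (10, 13) at stride 8 on a 320 input
        lbl = np.array([[0, 0.5, 0.5, 10 / 320, 13 / 320]])
        tg = assign_targets([lbl], self.CFG, 320)
        assert len(tg.per_scale[0].img) >= 1

    def test_degenerate_boxes_dropped(self):
        lbl = np.array([[0, 0.5, 0.5, 0.0, 0.1]])
        tg = assign_targets([lbl], self.CFG, 320)
        assert tg.n_dropped_degenerate == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        labels = []
        for _ in range(3):
            boxes = []
            for _ in range(3):
                w, h = rng.uniform(0.05, 0.5, 2)
                boxes.append([0, rng.uniform(w / 2, 1 - w / 2),
                              rng.uniform(h / 2, 1 - h / 2), w, h])
            labels.append(np.array(boxes))
        tg = assign_targets(labels, self.CFG, 64)
        got = {(si, img, ai, gj, gi)
               for si, st in enumerate(tg.per_scale)
               for img, ai, gj, gi in zip(st.img, st.anchor, st.gj, st.gi)}
        expect = brute_force_assignments(labels, self.CFG, 64)
        assert got == expect

    def test_cells_inside_grid(self):
        rng = np.random.default_rng(3)
        labels = [np.column_stack([np.zeros(5), rng.uniform(0.1, 0.9, (5, 2)),
                                   rng.uniform(0.05, 0.3, (5, 2))])]
        tg = assign_targets(labels, self.CFG, 128)
        for stride, st in zip(self.CFG.strides, tg.per_scale):
            grid = 128 // stride
            assert (st.gi >= 0).all() and (st.gi < grid).all()
            assert (st.gj >= 0).all() and (st.gj < grid).all()


class TestDetectionLoss:
    CFG = HeadConfig(num_classes=1)

    def _preds(self, n=1, size=SMALL, fill=0.0):
        return [Tensor(np.full((n, 18, size // s, size // s), fill,
                               np.float32), requires_grad=True)
                for s in self.CFG.strides]

    def test_no_positives_box_cls_zero(self):
        tc = TrainConfig(input_size=SMALL, epochs=1)
        preds = self._preds()
        tg = assign_targets([np.zeros((0, 5))], self.CFG, SMALL)
        total, box, obj, cls = detection_loss(preds, tg, tc, self.CFG)
        assert float(box.data) == 0.0 and float(cls.data) == 0.0
        assert float(obj.data) > 0.0
        assert float(total.data) == pytest.approx(float(obj.data), rel=1e-6)

    def test_all_terms_nonnegative(self):
        tc = TrainConfig(input_size=SMALL, epochs=1)
        rng = np.random.default_rng(0)
        preds = [Tensor(rng.normal(size=(1, 18, SMALL // s, SMALL // s))
                        .astype(np.float32), requires_grad=True)
                 for s in self.CFG.strides]
        lbl = [np.array([[0, 0.5, 0.5, 0.2, 0.3]])]
        total, box, obj, cls = detection_loss(
            preds, assign_targets(lbl, self.CFG, SMALL), tc, self.CFG)
        assert float(total.data) >= 0
        for t in (box, obj, cls):
            assert float(t.data) >= 0

    def test_lambda_box_linearity(self):
        lbl = [np.array([[0, 0.5, 0.5, 0.2, 0.3]])]
        tg = assign_targets(lbl, self.CFG, SMALL)
        rng = np.random.default_rng(1)
        preds = [Tensor(rng.normal(size=(1, 18, SMALL // s, SMALL // s))
                        .astype(np.float32)) for s in self.CFG.strides]
        t1 = TrainConfig(input_size=SMALL, epochs=1, lambda_box=0.05)
        t2 = TrainConfig(input_size=SMALL, epochs=1, lambda_box=0.10)
        _, box1, obj1, cls1 = detection_loss(preds, tg, t1, self.CFG)
        total1 = detection_loss(preds, tg, t1, self.CFG)[0]
        total2 = detection_loss(preds, tg, t2, self.CFG)[0]
        delta = float(total2.data) - float(total1.data)
        assert delta == pytest.approx(0.05 * float(box1.data), rel=1e-4)

    def test_exact_predictions_drive_box_term_to_zero(self):
        # place logits that decode exactly onto one target box
        lbl = [np.array([[0, 0.5, 0.5, 12 / SMALL, 14 / SMALL]])]
        tg = assign_targets(lbl, self.CFG, SMALL)
        preds = self._preds(fill=-12.0)  # objectness everywhere ~0
        st = tg.per_scale[0]
        raw = preds[0].data.reshape(1, 3, 6, SMALL // 8, SMALL // 8)
        for m in range(len(st.img)):
            anchor = np.asarray(self.CFG.anchors[0][st.anchor[m]])
            t = encode_box((st.txy[m, 0] * 8 + st.gi[m] * 8,
                            st.txy[m, 1] * 8 + st.gj[m] * 8,
                            st.twh[m, 0] * 8, st.twh[m, 1] * 8),
                           anchor, 8, (st.gi[m], st.gj[m]))
            raw[st.img[m], st.anchor[m], 0:4, st.gj[m], st.gi[m]] = t
        tc = TrainConfig(input_size=SMALL, epochs=1)
        _, box, _, _ = detection_loss(preds, tg, tc, self.CFG)
        # other scales may also hold positives; the stride-8 ones are exact
        assert float(box.data) < 0.35

    def test_saturated_single_class_cls_zero_at_eps0(self):
        lbl = [np.array([[0, 0.5, 0.5, 0.2, 0.3]])]
        tg = assign_targets(lbl, self.CFG, SMALL)
        preds = self._preds(fill=0.0)
        for p in preds:
            p.data.reshape(1, 3, 6, *p.shape[2:])[:, :, 5] = 40.0  # saturate
        tc = TrainConfig(input_size=SMALL, epochs=1, label_smoothing=0.0)
        _, _, _, cls = detection_loss(preds, tg, tc, self.CFG)
        assert float(cls.data) == pytest.approx(0.0, abs=1e-6)


class TestTrainingLoop:
    def test_overfit_single_batch_halves_loss(self, small_model):
        # property: 200 steps on one trivially-easy batch cut loss >= 50%
        model = small_model
        tc = TrainConfig(input_size=SMALL, batch_size=2, epochs=1, lr0=0.01,
                         label_smoothing=0.0)
        rng = np.random.default_rng(0)
        imgs = rng.random((2, 3, SMALL, SMALL)).astype(np.float32)
        labels = [np.array([[0, 0.5, 0.5, 0.3, 0.4]]),
                  np.array([[0, 0.3, 0.6, 0.25, 0.2]])]
        tg = assign_targets(labels, model.head_cfg, SMALL)
        opt = SGD(model.named_parameters(), lr=tc.lr0, momentum=0.9)
        model.train()
        losses = []
        for step in range(200):
            preds = model(imgs)
            total, *_ = detection_loss(preds, tg, tc, model.head_cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            losses.append(float(total.data))
        assert min(losses[-10:]) <= 0.5 * losses[0]

    def test_two_epoch_contract(self, tiny_samples, tmp_path):
        layers.seed_all(2)
        model = Detector(HeadConfig(num_classes=1), width=16)
        tc = TrainConfig(input_size=64, batch_size=4, epochs=2,
                         warmup_epochs=0, mosaic=False, seed=0)
        ds = DetectionDataset(train=tiny_samples * 2, val=tiny_samples[:4])
        best, hist = train(model, ds, tc, out_dir=tmp_path / "run")
        assert len(hist) == 2
        assert (tmp_path / "run" / "checkpoint.npz").exists()
        assert (tmp_path / "run" / "metrics.csv").exists()
        csv_lines = (tmp_path / "run" / "metrics.csv").read_text().splitlines()
        assert len(csv_lines) == 3  # header + 2 epochs

    def test_best_checkpoint_keeps_max_map(self, tiny_samples):
        layers.seed_all(2)
        model = Detector(HeadConfig(num_classes=1), width=16)
        tc = TrainConfig(input_size=64, batch_size=4, epochs=2,
                         warmup_epochs=0, mosaic=False, seed=0)
        ds = DetectionDataset(train=tiny_samples, val=tiny_samples[:4])
        best, hist = train(model, ds, tc)
        maps = [h["mAP50"] for h in hist]
        assert best["map50"] == max(maps)

    def test_seed_reproducibility(self, tiny_samples):
        results = []
        for _ in range(2):
            layers.seed_all(5)
            model = Detector(HeadConfig(num_classes=1), width=16)
            tc = TrainConfig(input_size=64, batch_size=4, epochs=1,
                             warmup_epochs=0, mosaic=False, seed=3)
            ds = DetectionDataset(train=tiny_samples[:4])
            _, hist = train(model, ds, tc)
            results.append(hist[0]["total"])
        assert results[0] == results[1]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            DetectionDataset(train=[])

    def test_checkpoint_round_trip(self, tiny_samples, tmp_path):
        layers.seed_all(2)
        model = Detector(HeadConfig(num_classes=1), width=16)
        tc = TrainConfig(input_size=64, batch_size=4, epochs=1,
                         warmup_epochs=0, mosaic=False, seed=0)
        ds = DetectionDataset(train=tiny_samples[:4], val=tiny_samples[:2])
        train(model, ds, tc, out_dir=tmp_path)
        loaded, cfg2, meta = load_checkpoint(tmp_path / "checkpoint.npz")
        assert cfg2.input_size == 64
        assert loaded.width == 16
        a = dict(model.named_parameters())
        b = dict(loaded.named_parameters())
        assert set(a) == set(b)
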