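"""Label I/O, splits, augmentation invariants, synthetic scene fidelity."""

import json

import numpy as np
import pytest

from mountdet.data_io_aug import (LabeledImage, SceneConfig, dataset_to_coco,
                                  generate_dataset, generate_scene,
                                  load_dataset, mosaic4, photometric_jitter,
                                  read_yolo_labels, split_by_video, vflip,
                                  write_yolo_labels)
from tests.conftest import random_labeled_image


class TestYoloLabels:
    def test_parse_single_row(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n")
        boxes = read_yolo_labels(p)
        assert boxes.shape == (1, 5)
        assert boxes[0].tolist() == [0, 0.5, 0.5, 0.2, 0.1]

    def test_round_trip_100_random(self, tmp_path, rng):
        boxes = np.column_stack([
            rng.integers(0, 3, 100),
            rng.uniform(0.2, 0.8, (100, 2)),
            rng.uniform(0.01, 0.3, (100, 2))])
        p = tmp_path / "b.txt"
        write_yolo_labels(boxes, p)
        back = read_yolo_labels(p)
        np.testing.assert_allclose(back, boxes, atol=1e-6)

    def test_out_of_range_clipped_with_warning(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("0 1.2 0.5 0.2 0.1\n")
        with pytest.warns(UserWarning, match="clipped"):
            boxes = read_yolo_labels(p)
        assert boxes[0, 1] == 1.0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n0 nope 0.5 0.2 0.1\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        assert len(read_yolo_labels(p)) == 0


class TestSplit:
    def test_144_videos_published_ratio(self):
        train, test = split_by_video([f"v{i}" for i in range(144)], 0.8)
        assert len(train) == 115 and len(test) == 29

    def test_ten_videos(self):
        train, test = split_by_video(list(range(10)), 0.8)
        assert len(train) == 8 and len(test) == 2

    def test_partition(self):
        vids = [f"v{i}" for i in range(23)]
        train, test = split_by_video(vids, 0.8)
        assert sorted(train + test) == sorted(vids)
        assert not set(train) & set(test)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_by_video([], 0.8)

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            split_by_video([1, 2], 1.5)


class TestMosaic:
    def test_requires_four(self, rng):
        with pytest.raises(ValueError):
            mosaic4([random_labeled_image(rng)] * 3, 64, rng)

    def test_output_size_and_no_uninitialised_pixels(self, rng):
        samples = [random_labeled_image(rng) for _ in range(4)]
        out = mosaic4(samples, 96, rng)
        assert out.image.shape == (96, 96, 3)
        assert out.image.dtype == np.uint8

    def test_boxes_inside_canvas(self, rng):
        for _ in range(25):
            samples = [random_labeled_image(rng, n_boxes=3) for _ in range(4)]
            out = mosaic4(samples, 64, rng)
            if len(out.boxes):
                x0 = out.boxes[:, 1] - out.boxes[:, 3] / 2
                x1 = out.boxes[:, 1] + out.boxes[:, 3] / 2
                y0 = out.boxes[:, 2] - out.boxes[:, 4] / 2
                y1 = out.boxes[:, 2] + out.boxes[:, 4] / 2
                assert (x0 >= -1e-9).all() and (x1 <= 1 + 1e-9).all()
                assert (y0 >= -1e-9).all() and (y1 <= 1 + 1e-9).all()

    def test_centered_large_boxes_survive(self, rng):
        samples = []
        for _ in range(4):
            img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
            samples.append(LabeledImage(img, np.array([[0, .5, .5, .6, .6]])))
        out = mosaic4(samples, 128, rng)
        assert 1 <= len(out.boxes) <= 4

    def test_identity_placement_closed_form(self, rng):
        # hand-derived: with the degenerate transform a sample of size s fits
        # its quadrant scaled by fit=min(qw,qh)/s about the quadrant centre
        size = 128
        samples = []
        for _ in range(4):
            img = np.zeros((64, 64, 3), np.uint8)
            samples.append(LabeledImage(img, np.array([[0, .5, .5, .25, .25]])))
        out = mosaic4(samples, size, rng, identity=True)
        # quadrants are exact halves; fit = 64/64 = 1, so each box sits at the
        # centre of its quadrant with side 0.25*64 px
        expected_centres = [(.25, .25), (.75, .25), (.25, .75), (.75, .75)]
        got = sorted((round(b[1], 6), round(b[2], 6)) for b in out.boxes)
        assert got == sorted(expected_centres)
        np.testing.assert_allclose(out.boxes[:, 3], 0.25 * 64 / 128)

    def test_deterministic_under_seed(self):
        base = np.random.default_rng(5)
        samples = [random_labeled_image(base, n_boxes=2) for _ in range(4)]
        a = mosaic4(samples, 64, np.random.default_rng(11))
        b = mosaic4(samples, 64, np.random.default_rng(11))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.boxes, b.boxes)


class TestPhotometricAndFlip:
    def test_zero_amplitude_identity(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        out = photometric_jitter(img, rng, hue=0, saturation=0, value=0,
                                 contrast=0)
        np.testing.assert_array_equal(out, img)

    def test_jitter_stays_uint8(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        out = photometric_jitter(img, rng)
        assert out.dtype == np.uint8 and out.shape == img.shape

    def test_vflip_involution(self, rng):
        s = random_labeled_image(rng, n_boxes=3)
        twice = vflip(vflip(s, p=1.0), p=1.0)
        np.testing.assert_array_equal(twice.image, s.image)
        np.testing.assert_allclose(twice.boxes, s.boxes)

    def test_vflip_maps_cy(self):
        img = np.zeros((16, 16, 3), np.uint8)
        s = LabeledImage(img, np.array([[0, 0.5, 0.2, 0.3, 0.1]]))
        flipped = vflip(s, p=1.0)
        assert flipped.boxes[0, 2] == pytest.approx(0.8)

    def test_vflip_probability_zero_is_noop(self, rng):
        s = random_labeled_image(rng)
        out = vflip(s, p=0.0, rng=rng)
        assert out is s

    def test_thousand_random_augmentations_keep_invariants(self):
        rng = np.random.default_rng(21)
        base = [random_labeled_image(rng, size=48, n_boxes=2)
                for _ in range(8)]
        for i in range(250):
            members = [base[rng.integers(len(base))] for _ in range(4)]
            out = mosaic4(members, 48, rng)
            out = vflip(LabeledImage(
                photometric_jitter(out.image, rng), out.boxes), p=0.5, rng=rng)
            # four augmented products per iteration -> 1000 total
            assert out.image.shape == (48, 48, 3)
            if len(out.boxes):
                assert (out.boxes[:, 0] == 0).all()          # class preserved
                lo = out.boxes[:, 1:3] - out.boxes[:, 3:5] / 2
                hi = out.boxes[:, 1:3] + out.boxes[:, 3:5] / 2
                assert (lo >= -1e-9).all() and (hi <= 1 + 1e-9).all()
                assert (out.boxes[:, 3:5] > 0).all()


class TestSceneGeneration:
    def test_exact_pair_count(self, rng):
        cfg = SceneConfig(canvas=(160, 160), mounting_pairs=(2, 2),
                          n_animals=(2, 3))
        scene = generate_scene(cfg, rng)
        assert len(scene.boxes) == 2

    def test_deterministic(self, tiny_scene_cfg):
        a = generate_scene(tiny_scene_cfg, np.random.default_rng(3))
        b = generate_scene(tiny_scene_cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_allclose(a.boxes, b.boxes)

    def test_labels_match_rendered_silhouettes(self):
        # oracle: recover the pair mask from its distinctive colours and
        # recompute the bounding box from pixels
        cfg = SceneConfig(canvas=(200, 200), mounting_pairs=(1, 1),
                          n_animals=(0, 0), night_prob=0.0)
        rng = np.random.default_rng(9)
        for _ in range(5):
            scene = generate_scene(cfg, rng)
            img = scene.image.astype(int)
            pale = (np.abs(img - [228, 224, 214]).sum(axis=2) < 40)
            dark = (np.abs(img - [34, 30, 30]).sum(axis=2) < 40)
            ys, xs = np.where(pale | dark)
            h, w = img.shape[:2]
            x0, x1 = xs.min() / w, (xs.max() + 1) / w
            y0, y1 = ys.min() / h, (ys.max() + 1) / h
            cls, cx, cy, bw, bh = scene.boxes[0]
            gx0, gx1 = cx - bw / 2, cx + bw / 2
            gy0, gy1 = cy - bh / 2, cy + bh / 2
            inter = (max(0, min(x1, gx1) - max(x0, gx0))
                     * max(0, min(y1, gy1) - max(y0, gy0)))
            union = ((x1 - x0) * (y1 - y0) + (gx1 - gx0) * (gy1 - gy0) - inter)
            assert inter / union >= 0.9

    def test_night_mode_darker(self):
        cfg_day = SceneConfig(canvas=(96, 96), night_prob=0.0)
        cfg_night = SceneConfig(canvas=(96, 96), night_prob=1.0)
        day = generate_scene(cfg_day, np.random.default_rng(4))
        night = generate_scene(cfg_night, np.random.default_rng(4))
        assert night.lighting_tag == "night"
        assert night.image.mean() < 0.6 * day.image.mean()

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(canvas=(32, 32))


class TestGenerateDataset:
    def test_counts_and_manifest(self, tmp_path, tiny_scene_cfg):
        manifest = generate_dataset(tiny_scene_cfg, 10, 5, tmp_path / "ds",
                                    seed=0)
        assert manifest["n_images"] == 50
        assert len(manifest["videos"]) == 10
        imgs = list((tmp_path / "ds" / "images").glob("*.png"))
        lbls = list((tmp_path / "ds" / "labels").glob("*.txt"))
        assert len(imgs) == 50 and len(lbls) == 50
        on_disk = json.loads((tmp_path / "ds" / "manifest.json").read_text())
        assert sum(v["n_frames"] for v in on_disk["videos"].values()) == 50

    def test_existing_dir_needs_overwrite(self, tmp_path, tiny_scene_cfg):
        out = tmp_path / "ds"
        generate_dataset(tiny_scene_cfg, 1, 1, out, seed=0)
        with pytest.raises(FileExistsError):
            generate_dataset(tiny_scene_cfg, 1, 1, out, seed=0)
        generate_dataset(tiny_scene_cfg, 1, 1, out, seed=0, overwrite=True)

    def test_split_compatibility_and_load(self, tmp_path, tiny_scene_cfg):
        generate_dataset(tiny_scene_cfg, 10, 2, tmp_path / "ds", seed=1)
        samples = load_dataset(tmp_path / "ds")
        assert len(samples) == 20
        videos = sorted({s.source_video for s in samples})
        train, test = split_by_video(videos, 0.8)
        assert len(train) == 8 and len(test) == 2

    def test_coco_export(self, tiny_scene_cfg):
        rng = np.random.default_rng(2)
        scenes = [generate_scene(tiny_scene_cfg, rng) for _ in range(3)]
        coco = dataset_to_coco(scenes)
        assert len(coco["images"]) == 3
        assert len(coco["annotations"]) == sum(len(s.boxes) for s in scenes)
        assert coco["categories"][0]["name"] == "mounting"
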