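"""Synthetic scene generator: determinism, label geometry, splits, IO."""

import numpy as np
import pytest

from leafdet.synthdata import (DEFAULT_CLASS_MIX, LabelRecord, SceneConfig,
                               augment, generate_dataset, labels_from_letterbox,
                               labels_to_letterbox, letterbox, read_yolo_labels,
                               render_scene, split_of_index, write_yolo_labels)


class TestDeterminism:
    def test_repeated_generation_byte_identical(self, tmp_path):
        cfg = SceneConfig(n_images=6, image_size=96, seed=11)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for i in range(6):
            stem = f"img{i:06d}"
            la = (tmp_path / "a" / "labels" / f"{stem}.txt").read_bytes()
            lb = (tmp_path / "b" / "labels" / f"{stem}.txt").read_bytes()
            assert la == lb
            ia = (tmp_path / "a" / "images" / f"{stem}.png").read_bytes()
            ib = (tmp_path / "b" / "images" / f"{stem}.png").read_bytes()
            assert ia == ib

    def test_different_seeds_differ(self):
        img1, _ = render_scene(SceneConfig(n_images=1, image_size=64, seed=1), 0)
        img2, _ = render_scene(SceneConfig(n_images=1, image_size=64, seed=2), 0)
        assert not np.array_equal(img1, img2)


class TestLabelGeometry:
    def test_boxes_inside_unit_square(self):
        cfg = SceneConfig(n_images=20, image_size=96, seed=3,
                          lesions_per_image=(1, 4))
        for i in range(20):
            _, recs = render_scene(cfg, i)
            for r in recs:
                assert 0.0 <= r.cx - r.w / 2 + 1e-9
                assert r.cx + r.w / 2 <= 1.0 + 1e-9
                assert 0.0 <= r.cy - r.h / 2 + 1e-9
                assert r.cy + r.h / 2 <= 1.0 + 1e-9

    def test_lesion_pixels_inside_label_box(self):
        """The painted lesion footprint stays inside its label box: pixels
        differing from the re-rendered lesion-free scene lie in some box."""
        cfg = SceneConfig(n_images=1, image_size=96, seed=9,
                          lesions_per_image=(2, 2))
        img, recs = render_scene(cfg, 0)
        clean, _ = render_scene(
            SceneConfig(n_images=1, image_size=96, seed=9,
                        lesions_per_image=(0, 0)), 0)
        diff = np.abs(img.astype(int) - clean.astype(int)).sum(axis=2) > 12
        mask = np.zeros_like(diff)
        s = cfg.image_size
        for r in recs:
            x1 = int(np.floor((r.cx - r.w / 2) * s))
            x2 = int(np.ceil((r.cx + r.w / 2) * s))
            y1 = int(np.floor((r.cy - r.h / 2) * s))
            y2 = int(np.ceil((r.cy + r.h / 2) * s))
            mask[y1:y2, x1:x2] = True
        covered = (diff & mask).sum() / max(diff.sum(), 1)
        assert covered >= 0.9

    def test_class_frequencies_match_mix(self, tmp_path):
        cfg = SceneConfig(n_images=700, image_size=64, seed=17,
                          lesions_per_image=(2, 4))
        counts = np.zeros(3)
        for i in range(cfg.n_images):
            _, recs = render_scene(cfg, i)
            for r in recs:
                counts[r.class_id] += 1
        assert counts.sum() >= 2000
        freq = counts / counts.sum()
        np.testing.assert_allclose(freq, DEFAULT_CLASS_MIX, atol=0.03)

    def test_anisotropy_fraction_shows_up(self):
        cfg = SceneConfig(n_images=150, image_size=64, seed=23,
                          lesions_per_image=(2, 3), anisotropy_fraction=0.5)
        ratios = []
        for i in range(cfg.n_images):
            _, recs = render_scene(cfg, i)
            ratios.extend(max(r.w / r.h, r.h / r.w) for r in recs)
        elongated = np.mean(np.asarray(ratios) > 2.0)
        assert 0.2 < elongated < 0.8


class TestSplits:
    def test_hash_split_stability_and_ratio(self):
        splits = [split_of_index(i) for i in range(1000)]
        assert [split_of_index(i) for i in range(100)] == splits[:100]
        frac_train = splits.count("train") / 1000
        frac_val = splits.count("val") / 1000
        assert 0.74 <= frac_train <= 0.86
        assert 0.06 <= frac_val <= 0.14

    def test_manifest_partitions_all_images(self, tiny_dataset):
        _, cfg, manifest = tiny_dataset
        n = sum(len(v) for v in manifest["splits"].values())
        assert n == cfg.n_images


class TestLabelIO:
    def test_round_trip_at_1e6(self, tmp_path):
        recs = [LabelRecord(1, 0.512345, 0.25, 0.1, 0.098765),
                LabelRecord(0, 0.5, 0.5, 0.333333, 0.2)]
        path = tmp_path / "l.txt"
        write_yolo_labels(path, recs)
        back = read_yolo_labels(path)
        for a, b in zip(recs, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_empty_file_is_valid_negative(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        assert read_yolo_labels(path) == []

    def test_class_range_error_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1 0.1\n3 0.5 0.5 0.1 0.1\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(path, n_classes=3)

    def test_malformed_line_errors(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1\n")
        with pytest.raises(ValueError, match="5 fields"):
            read_yolo_labels(path)
        path.write_text("0 x 0.5 0.1 0.1\n")
        with pytest.raises(ValueError, match="malformed"):
            read_yolo_labels(path)


class TestAugment:
    @pytest.fixture
    def scene(self):
        return render_scene(SceneConfig(n_images=1, image_size=64, seed=2), 0)

    def test_zero_brightness_identity(self, scene):
        img, labels = scene
        out, out_labels = augment(img, labels, {"brightness"}, brightness=0.0)
        np.testing.assert_array_equal(out, img)
        assert out_labels == labels

    def test_photometric_ops_leave_labels(self, scene):
        img, labels = scene
        _, l1 = augment(img, labels, {"hue", "contrast"}, hue_deg=8,
                        contrast=0.2)
        assert l1 == labels

    def test_uniform_rescale_keeps_normalized_labels(self, scene):
        img, labels = scene
        out, l1 = augment(img, labels, {"rescale"}, rescale=1.5)
        assert out.shape[0] == 96
        assert l1 == labels

    def test_unknown_op_rejected(self, scene):
        img, labels = scene
        with pytest.raises(ValueError):
            augment(img, labels, {"mosaic"})

    def test_letterbox_label_round_trip(self, scene):
        img, labels = scene
        rect = img[:48]                       # non-square source
        if not labels:
            labels = [LabelRecord(0, 0.5, 0.4, 0.2, 0.1)]
        boxed, scale, pad = letterbox(rect, 96)
        fwd = labels_to_letterbox(labels, rect.shape, 96, scale, pad)
        back = labels_from_letterbox(fwd, rect.shape, 96, scale, pad)
        for a, b in zip(labels, back):
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)
        assert boxed.shape == (96, 96, 3)


class TestConfigValidation:
    def test_bad_class_mix(self):
        with pytest.raises(ValueError):
            SceneConfig(class_mix=(0.5, 0.5, 0.5))

    def test_bad_lesion_range_and_count(self):
        with pytest.raises(ValueError):
            SceneConfig(lesions_per_image=(3, 1))
        with pytest.raises(ValueError):
            SceneConfig(n_images=0)

    def test_label_record_validation(self):
        with pytest.raises(ValueError):
            LabelRecord(0, 1.5, 0.5, 0.1, 0.1)
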