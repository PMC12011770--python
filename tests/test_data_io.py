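"""Label parsing, letterbox geometry, mosaic and the scene generator."""

from dataclasses import replace

import numpy as np
import pytest

from pdyolo.data_io import (LabeledImage, SceneSpec, generate_synthetic_dataset,
                            generate_synthetic_scene, letterbox, mosaic_augment,
                            parse_label_file, read_yolo_dataset, split_dataset,
                            write_yolo_dataset)


def test_label_line_parsing(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("3 0.5 0.5 0.2 0.1\n")
    boxes = parse_label_file(p)
    assert boxes == [(3, 0.5, 0.5, pytest.approx(0.2), pytest.approx(0.1))]
    p.write_text("")
    assert parse_label_file(p) == []
    p.write_text("1 0.5 0.5 0.2\nnot a line\n0 0.1 0.1 0.05 0.05\n")
    assert len(parse_label_file(p)) == 1          # malformed lines skipped
    p.write_text("0 0.99 0.5 0.2 0.1\n")
    cid, cx, cy, w, h = parse_label_file(p)[0]    # clipped to the unit square
    assert cx + w / 2 <= 1.0 + 1e-9


def test_write_read_roundtrip(tmp_path, rng):
    samples = [LabeledImage(
        image=rng.integers(0, 255, (32, 48, 3), dtype=np.uint8),
        boxes=[(1, 0.5, 0.5, 0.25, 0.125), (0, 0.25, 0.75, 0.1, 0.2)],
        image_id=f"img{i}") for i in range(3)]
    write_yolo_dataset(samples, tmp_path)
    back = read_yolo_dataset(tmp_path)
    assert len(back) == 3
    for orig, rt in zip(samples, back):
        np.testing.assert_array_equal(orig.image, rt.image)
        for a, b in zip(orig.boxes, rt.boxes):
            assert a[0] == b[0]
            np.testing.assert_allclose(a[1:], b[1:], atol=1e-6)


def test_missing_images_dir_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_yolo_dataset(tmp_path / "nothing")


def test_letterbox_geometry():
    img = np.zeros((1080, 1920, 3), dtype=np.uint8)
    out, tf = letterbox(img, (640, 640))
    assert out.shape == (640, 640, 3)
    assert tf.scale == pytest.approx(1 / 3)
    assert tf.pad_y == 140 and tf.pad_x == 0
    # square to square: pure resize, no padding
    _, tf2 = letterbox(np.zeros((320, 320, 3), np.uint8), (640, 640))
    assert tf2.pad_x == tf2.pad_y == 0 and tf2.scale == 2.0
    with pytest.raises(ValueError):
        letterbox(img, (100, 100))


def test_letterbox_transform_invertible(rng):
    _, tf = letterbox(np.zeros((300, 500, 3), np.uint8), (640, 640))
    pts = rng.uniform(0, 300, (7, 2))
    np.testing.assert_allclose(tf.inverse(tf.apply(pts)), pts, atol=1e-9)


def test_mosaic_solid_color_and_determinism():
    solid = LabeledImage(np.full((64, 64, 3), 99, np.uint8),
                         [(0, 0.5, 0.5, 0.5, 0.5)], "s")
    a = mosaic_augment([solid] * 4, 128, seed=5)
    b = mosaic_augment([solid] * 4, 128, seed=5)
    assert np.all(a.image == 99)
    np.testing.assert_array_equal(a.image, b.image)
    assert a.boxes == b.boxes
    assert len(a.boxes) <= 4          # clipping can only drop boxes
    with pytest.raises(ValueError):
        mosaic_augment([solid] * 3, 128)


def test_scene_determinism_and_counts():
    spec = SceneSpec(num_classes=3, image_size=96, objects_per_image=(5, 5),
                     occlusion_prob=0.0, small_target_frac=0.0, seed=11)
    a = generate_synthetic_scene(spec, 0)
    b = generate_synthetic_scene(spec, 0)
    np.testing.assert_array_equal(a.image, b.image)
    assert a.boxes == b.boxes
    # occlusion 0: requested count and pairwise non-overlap (placement discs)
    assert len(a.boxes) == 5
    px = a.boxes_pixels()
    for i in range(len(px)):
        for j in range(i + 1, len(px)):
            x1 = max(px[i, 1], px[j, 1]); y1 = max(px[i, 2], px[j, 2])
            x2 = min(px[i, 3], px[j, 3]); y2 = min(px[i, 4], px[j, 4])
            inter = max(0, x2 - x1) * max(0, y2 - y1)
            area = (px[i, 3] - px[i, 1]) * (px[i, 4] - px[i, 2])
            assert inter <= 0.35 * area  # tight boxes of discs may touch


def test_scene_small_target_fraction():
    spec = SceneSpec(num_classes=2, image_size=128, objects_per_image=(4, 4),
                     occlusion_prob=1.0, small_target_frac=0.5, seed=3)
    boxes = [b for i in range(25) for b in generate_synthetic_scene(spec, i).boxes]
    small = sum(1 for _, _, _, w, h in boxes if w * h < 0.01)
    frac = small / len(boxes)
    assert 0.35 < frac < 0.65         # binomial tolerance around 0.5


def test_generator_label_fidelity():
    """Emitted boxes tightly enclose the rendered plant pixels (<= 1 px)."""
    spec = SceneSpec(num_classes=3, image_size=96, objects_per_image=(1, 1),
                     occlusion_prob=0.0, small_target_frac=0.0, seed=21)
    bg_spec = replace(spec, objects_per_image=(0, 0))
    for i in range(5):
        scene = generate_synthetic_scene(spec, i)
        background = generate_synthetic_scene(bg_spec, i)
        diff = np.any(scene.image != background.image, axis=2)
        ys, xs = np.nonzero(diff)
        assert len(scene.boxes) == 1
        x1, y1, x2, y2 = _corners(scene.boxes[0], 96)
        assert abs(x1 - xs.min()) <= 1 and abs(x2 - (xs.max() + 1)) <= 1
        assert abs(y1 - ys.min()) <= 1 and abs(y2 - (ys.max() + 1)) <= 1


def _corners(box, s):
    _, cx, cy, w, h = box
    return (cx - w / 2) * s, (cy - h / 2) * s, (cx + w / 2) * s, (cy + h / 2) * s


def test_class_color_separability():
    """Nearest-centroid colour classifier on crops exceeds 90% accuracy."""
    spec = SceneSpec(num_classes=3, image_size=64, objects_per_image=(1, 1),
                     scale_range=(0.3, 0.6), occlusion_prob=0.0,
                     small_target_frac=0.0, seed=5)
    scenes = generate_synthetic_dataset(spec, 60)
    feats, labels = [], []
    for sc in scenes:
        if not sc.boxes:
            continue
        x1, y1, x2, y2 = (int(round(v)) for v in _corners(sc.boxes[0], 64))
        crop = sc.image[y1:y2, x1:x2].reshape(-1, 3).astype(np.float64)
        feats.append(crop.mean(axis=0))
        labels.append(sc.boxes[0][0])
    feats, labels = np.array(feats), np.array(labels)
    train, test = slice(0, 40), slice(40, None)
    centroids = {c: feats[train][labels[train] == c].mean(axis=0)
                 for c in np.unique(labels[train])}
    pred = [min(centroids, key=lambda c: np.linalg.norm(f - centroids[c]))
            for f in feats[test]]
    acc = np.mean(np.array(pred) == labels[test])
    assert acc > 0.9


def test_split_ratios_and_determinism():
    samples = [LabeledImage(np.zeros((8, 8, 3), np.uint8), [], f"i{k}")
               for k in range(100)]
    tr, va, te = split_dataset(samples, seed=1)
    assert (len(tr), len(va), len(te)) == (80, 10, 10)
    tr2, _, _ = split_dataset(samples, seed=1)
    assert [s.image_id for s in tr] == [s.image_id for s in tr2]
    tr7, va7, te7 = split_dataset(samples, seed=1, ratios=(0.7, 0.1, 0.2))
    assert (len(tr7), len(va7), len(te7)) == (70, 10, 20)
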