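"""Loss contract, mAP against a brute-force oracle, TIDE taxonomy, training."""

import math

import numpy as np
import pytest

from pdyolo.config import ModelConfig
from pdyolo.data_io import SceneSpec, generate_synthetic_dataset
from pdyolo.model import Detection, box_iou, build_pdyolo
from pdyolo.nn import Tensor
from pdyolo.train_eval import (CLS_WEIGHT, Hyperparams, average_precision,
                               compute_loss, evaluate_map, tide_decompose,
                               train)

# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _raw_outputs(nc=2, reg_max=16, sizes=((8, 8), (4, 4), (2, 2)),
                 strides=(8, 16, 32), fill_box=0.0, fill_cls=0.0):
    outs = []
    for (h, w), s in zip(sizes, strides):
        box = Tensor(np.full((1, 4 * reg_max, h, w), fill_box, np.float32))
        cls = Tensor(np.full((1, nc, h, w), fill_cls, np.float32))
        outs.append((box, cls, s))
    return outs


def test_zero_targets_zero_logits_closed_form():
    """With no ground truth the loss is pure BCE at 0.5 activation."""
    outs = _raw_outputs()
    total, parts = compute_loss(outs, [np.zeros((0, 5), np.float32)])
    n_anchors, nc = 64 + 16 + 4, 2
    expected = CLS_WEIGHT * n_anchors * nc * math.log(2.0)
    assert parts["box"].item() == 0.0 and parts["dfl"].item() == 0.0
    np.testing.assert_allclose(total.item(), expected, rtol=1e-5)


def test_perfect_predictions_minimise_box_and_dfl():
    """Saturated logits exactly on an integer-bin box zero the box terms.

    Box corners sit at half-cell positions (4 and 28 px at stride 8) so
    every anchor-to-edge distance is an exact integer number of cells and
    the distribution-focal target is a single bin.
    """
    reg_max, nc = 16, 2
    h = w = 4
    box = np.full((1, 4, reg_max, h, w), -60.0, np.float32)
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dists = [gx, gy, 3 - gx, 3 - gy]   # integer cell distances to (4,4,28,28)
    for side, d in enumerate(dists):
        for yy in range(h):
            for xx in range(w):
                box[0, side, max(d[yy, xx], 0), yy, xx] = 60.0
    cls = np.full((1, nc, h, w), -12.0, np.float32)
    cls[0, 1] = 12.0
    outs = [(Tensor(box.reshape(1, 4 * reg_max, h, w)), Tensor(cls), 8)]
    gt = np.array([[1, 4.0, 4.0, 28.0, 28.0]], np.float32)
    total, parts = compute_loss(outs, [gt])
    assert parts["box"].item() < 1e-3
    assert parts["dfl"].item() < 1e-2
    assert np.isfinite(total.item())


def test_loss_finite_under_random_model(tiny_config, rng):
    model = build_pdyolo(tiny_config)
    model.train()
    x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
    gts = [np.array([[0, 4.0, 4.0, 40.0, 40.0]], np.float32),
           np.array([[2, 10.0, 10.0, 30.0, 50.0]], np.float32)]
    total, parts = compute_loss(model(x), gts)
    assert np.isfinite(total.item())
    for v in parts.values():
        assert np.isfinite(v.item())


# ---------------------------------------------------------------------------
# mAP: brute-force oracle
# ---------------------------------------------------------------------------

def oracle_ap(dets, gts, iou_thr):
    """Independent PR-curve integration for one class on one image set.

    dets: [(image, box, score)] any order; gts: {image: [boxes]}.
    Walks the ranked list explicitly, recomputing precision/recall at
    every rank, then 101-point interpolates.
    """
    dets = sorted(dets, key=lambda d: -d[2])
    matched = {img: np.zeros(len(b), bool) for img, b in gts.items()}
    n_gt = sum(len(b) for b in gts.values())
    tps = []
    for img, box, _ in dets:
        flag = False
        best_iou, best_j = iou_thr, None
        for j, g in enumerate(gts.get(img, [])):
            iou = box_iou(np.array(box)[None], np.array(g)[None])[0, 0]
            if iou >= best_iou and not matched[img][j]:
                best_iou, best_j = iou, j
        if best_j is not None:
            matched[img][best_j] = True
            flag = True
        tps.append(flag)
    precisions, recalls = [], []
    for k in range(1, len(tps) + 1):
        tp = sum(tps[:k])
        precisions.append(tp / k)
        recalls.append(tp / n_gt if n_gt else 0.0)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        vals = [p for p, rr in zip(precisions, recalls) if rr >= r]
        ap += max(vals) if vals else 0.0
    return ap / 101


def _det(box, score, cid=0):
    return Detection(tuple(map(float, box)), cid, score)


@pytest.mark.parametrize("case", range(6))
def test_map_matches_bruteforce_oracle(case, rng):
    """Random fixtures with <= 6 detections agree with the oracle exactly."""
    rng = np.random.default_rng(100 + case)
    n_img, n_det, n_gt = 2, int(rng.integers(1, 7)), int(rng.integers(1, 4))
    det_lists, gt_lists, oracle_dets, oracle_gts = [], [], [], {}
    for img in range(n_img):
        gts = []
        for _ in range(n_gt):
            x1, y1 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(10, 40, 2)
            gts.append([x1, y1, x1 + w, y1 + h])
        oracle_gts[img] = gts
        gt_lists.append(np.array([[0] + g for g in gts], np.float32))
        dets = []
        for _ in range(n_det):
            base = gts[int(rng.integers(len(gts)))]
            jitter = rng.uniform(-10, 10, 4)
            box = [base[0] + jitter[0], base[1] + jitter[1],
                   max(base[2] + jitter[2], base[0] + jitter[0] + 1),
                   max(base[3] + jitter[3], base[1] + jitter[1] + 1)]
            score = float(rng.uniform(0.1, 1.0))
            dets.append(_det(box, score))
            oracle_dets.append((img, box, score))
        det_lists.append(dets)
    result = evaluate_map(det_lists, gt_lists, iou_grid=np.array([0.5]))
    expected = oracle_ap(oracle_dets, oracle_gts, 0.5)
    np.testing.assert_allclose(result.map50, expected, atol=1e-9)


def test_perfect_detector_scores_one():
    gt = np.array([[0, 10, 10, 50, 50]], np.float32)
    dets = [[_det((10, 10, 50, 50), 0.99)]]
    r = evaluate_map(dets, [gt])
    assert r.precision == r.recall == 1.0
    assert r.map50 == pytest.approx(1.0)
    assert r.map5095 == pytest.approx(1.0)


def test_precision_recall_arithmetic():
    """3 TP + 1 FP -> precision 0.75; 3 TP of 4 GT -> recall 0.75."""
    gt = np.array([[0, 0, 0, 10, 10], [0, 20, 0, 30, 10],
                   [0, 40, 0, 50, 10], [0, 60, 0, 70, 10]], np.float32)
    dets = [[_det((0, 0, 10, 10), 0.9), _det((20, 0, 30, 10), 0.8),
             _det((40, 0, 50, 10), 0.7), _det((100, 100, 110, 110), 0.6)]]
    r = evaluate_map(dets, [gt])
    assert r.precision == pytest.approx(0.75)
    assert r.recall == pytest.approx(0.75)


def test_zero_gt_class_excluded_from_mean():
    gt = np.array([[1, 0, 0, 10, 10]], np.float32)
    dets = [[_det((0, 0, 10, 10), 0.9, cid=1), _det((50, 50, 60, 60), 0.8, cid=0)]]
    r = evaluate_map(dets, [gt])
    assert set(r.ap_per_class) == {1}
    assert r.map50 == pytest.approx(1.0)


def test_map_invariant_to_order_of_equal_scores():
    gt = np.array([[0, 0, 0, 10, 10], [0, 20, 0, 30, 10]], np.float32)
    d1 = [_det((0, 0, 10, 10), 0.5), _det((20, 0, 30, 10), 0.5)]
    r1 = evaluate_map([d1], [gt])
    r2 = evaluate_map([list(reversed(d1))], [gt])
    assert r1.map50 == r2.map50


# ---------------------------------------------------------------------------
# TIDE
# ---------------------------------------------------------------------------

def test_tide_all_eight_categories():
    """Hand-built fixture realising every error type of the taxonomy."""
    gt = np.array([
        [0, 0, 0, 10, 10],      # matched by TP
        [1, 20, 0, 30, 10],     # hit with wrong class -> Cls
        [0, 40, 0, 50, 10],     # loose same-class box -> Loc
        [1, 60, 0, 70, 10],     # loose wrong-class box -> Both
        [0, 80, 0, 90, 10],     # never detected -> Miss
    ], np.float32)
    dets = [
        _det((0, 0, 10, 10), 0.95, cid=0),        # TP
        _det((0, 0, 10, 10), 0.90, cid=0),        # Dupl (same matched GT)
        _det((20, 0, 30, 10), 0.85, cid=0),       # Cls (GT class is 1)
        _det((40, 3, 50, 13), 0.80, cid=0),       # Loc (IoU ~ 0.54 < ... )
        _det((60, 3, 70, 13), 0.75, cid=0),       # Both (wrong class, low IoU)
        _det((200, 200, 210, 210), 0.70, cid=0),  # Bkg
    ]
    rep = tide_decompose([dets], [gt], fg_iou=0.6, bg_iou=0.1)
    n = len(dets)
    assert rep.cls == pytest.approx(100 / n)
    assert rep.loc == pytest.approx(100 / n)
    assert rep.both == pytest.approx(100 / n)
    assert rep.dupl == pytest.approx(100 / n)
    assert rep.bkg == pytest.approx(100 / n)
    assert rep.miss == pytest.approx(100 * 4 / 5)   # only one GT matched
    assert rep.fp == pytest.approx(100 * 5 / n)
    assert rep.fn == rep.miss


def test_tide_partition_property(rng):
    """Every non-TP detection lands in exactly one error category."""
    for trial in range(10):
        r = np.random.default_rng(trial)
        gt = np.array([[int(r.integers(2))] + list(b) for b in
                       [(0, 0, 20, 20), (40, 40, 70, 70)]], np.float32)
        dets = []
        for _ in range(int(r.integers(1, 8))):
            x1, y1 = r.uniform(0, 60, 2)
            dets.append(_det((x1, y1, x1 + r.uniform(5, 30),
                              y1 + r.uniform(5, 30)),
                             float(r.uniform(0.1, 1)), int(r.integers(2))))
        rep = tide_decompose([dets], [gt])
        n = len(dets)
        total_err = (rep.cls + rep.loc + rep.both + rep.dupl + rep.bkg)
        # detection-side categories + TPs account for every detection
        n_tp = n - round(rep.fp * n / 100)
        assert total_err == pytest.approx(rep.fp)
        assert 0 <= n_tp <= n


def test_tide_threshold_validation():
    with pytest.raises(ValueError):
        tide_decompose([[]], [np.zeros((0, 5), np.float32)], 0.1, 0.5)


def test_tide_taxonomy_extremes():
    gt = np.array([[0, 0, 0, 10, 10]], np.float32)
    dets = [_det((90, 90, 99, 99), 0.9, cid=0)]
    rep = tide_decompose([dets], [gt])
    assert rep.bkg == 100.0 and rep.miss == 100.0


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _tiny_dataset(n=4):
    spec = SceneSpec(num_classes=2, image_size=32, objects_per_image=(1, 1),
                     scale_range=(0.4, 0.7), occlusion_prob=0.0,
                     small_target_frac=0.0, seed=9)
    return generate_synthetic_dataset(spec, n)


def test_same_seed_identical_first_epoch_loss(tiny_config):
    data = _tiny_dataset()
    losses = []
    for _ in range(2):
        model = build_pdyolo(ModelConfig(num_classes=2), seed=4)
        hyper = Hyperparams(epochs=1, batch=4, imgsz=32, mosaic_off_epoch=0,
                            seed=11)
        _, hist = train(model, data, hyper, eval_interval=1)
        losses.append(hist[0]["loss"])
    assert losses[0] == losses[1]


def test_mosaic_disabled_when_cutoff_zero(monkeypatch):
    import pdyolo.train_eval as te
    calls = []
    monkeypatch.setattr(te, "mosaic_augment",
                        lambda *a, **k: calls.append(1) or (_ for _ in ()).throw(
                            AssertionError("mosaic sampled")))
    model = build_pdyolo(ModelConfig(num_classes=2), seed=4)
    hyper = Hyperparams(epochs=1, batch=4, imgsz=32, mosaic_off_epoch=0, seed=0)
    train(model, _tiny_dataset(), hyper, eval_interval=1)
    assert calls == []


def test_empty_dataset_rejected():
    model = build_pdyolo(ModelConfig(num_classes=2))
    with pytest.raises(ValueError):
        train(model, [], Hyperparams(epochs=1))


def test_invalid_hyperparams():
    with pytest.raises(ValueError):
        Hyperparams(epochs=10, mosaic_off_epoch=20)
    with pytest.raises(ValueError):
        Hyperparams(lr0=-1)
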