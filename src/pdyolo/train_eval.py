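"""Training loop and evaluation stack.

Loss follows the YOLO-family contract: task-aligned assignment of anchors
to ground truths, binary cross-entropy for classification, complete-IoU
for boxes and a distribution-focal term for the box bins, weighted
0.5 / 7.5 / 1.5.  Evaluation implements precision, recall, mAP via
101-point interpolated precision-recall integration, and the TIDE error
decomposition (classification / localisation / both / duplicate /
background / missed, plus residual FP and FN rates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_io import LabeledImage, mosaic_augment
from .model import PDYOLO, Detection, box_iou, nms, predict
from .nn import Tensor, concat

log = logging.getLogger("pdyolo.train")

CLS_WEIGHT, BOX_WEIGHT, DFL_WEIGHT = 0.5, 7.5, 1.5
TAL_ALPHA, TAL_BETA, TAL_TOPK = 0.5, 6.0, 10


@dataclass
class Hyperparams:
    epochs: int = 100
    lr0: float = 0.01
    weight_decay: float = 5e-4
    momentum: float = 0.937
    mosaic_off_epoch: int = 15
    batch: int = 8
    imgsz: int = 640
    warmup_epochs: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch, self.imgsz) <= 0 or self.lr0 <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.mosaic_off_epoch > self.epochs:
            raise ValueError("mosaic_off_epoch must not exceed epochs")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class APResult:
    precision: float            # TP / (TP + FP) over all detections, IoU 0.5
    recall: float               # TP / n_gt
    ap_per_class: dict
    map50: float
    map5095: float
    precision_f1: float = 0.0   # at the max-F1 confidence point
    recall_f1: float = 0.0


@dataclass
class TIDEReport:
    cls: float = 0.0
    loc: float = 0.0
    both: float = 0.0
    dupl: float = 0.0
    bkg: float = 0.0
    miss: float = 0.0
    fp: float = 0.0
    fn: float = 0.0


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _bce_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy with logits, numerically stable."""
    absx = logits.relu() + (-logits).relu()
    return logits.relu() - logits * targets + ((-absx).exp() + 1.0).log()


def _anchor_grid(shapes, strides):
    """Anchor centres in pixels and per-anchor stride, concatenated levels."""
    centres, astr = [], []
    for (h, w), s in zip(shapes, strides):
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx = (gx.reshape(-1) + 0.5) * s
        cy = (gy.reshape(-1) + 0.5) * s
        centres.append(np.stack([cx, cy], axis=1))
        astr.append(np.full(h * w, s, dtype=np.float32))
    return (np.concatenate(centres).astype(np.float32), np.concatenate(astr))


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between matched box pairs [P, 4] (corner pixels)."""
    tx1, ty1, tx2, ty2 = (target[:, i] for i in range(4))
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    ix1, iy1 = px1.maximum(tx1), py1.maximum(ty1)
    ix2, iy2 = px2.minimum(tx2), py2.minimum(ty2)
    inter = (ix2 - ix1).clip(0, 1e9) * (iy2 - iy1).clip(0, 1e9)
    area_p = (px2 - px1).clip(0, 1e9) * (py2 - py1).clip(0, 1e9)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + 1e-7
    iou = inter / union
    # enclosing-box diagonal and centre distance
    ex1, ey1 = px1.minimum(tx1), py1.minimum(ty1)
    ex2, ey2 = px2.maximum(tx2), py2.maximum(ty2)
    diag = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + 1e-7
    dist = ((px1 + px2) - (tx1 + tx2)) ** 2 + ((py1 + py2) - (ty1 + ty2)) ** 2
    dist = dist * 0.25
    # aspect-ratio consistency
    wt, ht = tx2 - tx1, np.maximum(ty2 - ty1, 1e-7)
    wp, hp = (px2 - px1), (py2 - py1).clip(1e-7, 1e9)
    v = (Tensor(np.arctan(wt / ht)) - (wp / hp).atan()) ** 2 * (4 / math.pi ** 2)
    with nn.no_grad():
        alpha = v.data / (1.0 - iou.data + v.data + 1e-7)
    return iou - dist / diag - v * alpha


def task_aligned_assign(pred_scores: np.ndarray, pred_boxes: np.ndarray,
                        anchors: np.ndarray, gt: np.ndarray):
    """Assign anchors of one image to ground truths.

    ``pred_scores`` [A, nc] sigmoid scores, ``pred_boxes`` [A, 4] decoded
    pixels, ``gt`` [N, 5] (class, x1, y1, x2, y2).  Returns (gt_idx [A],
    target_scores [A], fg mask [A]); alignment metric score^a * IoU^b,
    top-k anchors per GT among those whose centre lies inside the GT.
    """
    a = anchors.shape[0]
    fg = np.zeros(a, dtype=bool)
    gt_idx = np.zeros(a, dtype=np.int64)
    tscore = np.zeros(a, dtype=np.float32)
    if gt.shape[0] == 0:
        return gt_idx, tscore, fg
    ious = box_iou(pred_boxes, gt[:, 1:])                      # [A, N]
    cls_scores = pred_scores[:, gt[:, 0].astype(int)]          # [A, N]
    metric = cls_scores ** TAL_ALPHA * ious ** TAL_BETA
    inside = ((anchors[:, 0:1] > gt[None, :, 1]) & (anchors[:, 0:1] < gt[None, :, 3])
              & (anchors[:, 1:2] > gt[None, :, 2]) & (anchors[:, 1:2] < gt[None, :, 4]))
    metric = np.where(inside, metric, 0.0)
    mask = np.zeros_like(metric, dtype=bool)
    k = min(TAL_TOPK, a)
    top = np.argpartition(-metric, k - 1, axis=0)[:k]
    np.put_along_axis(mask, top, True, axis=0)
    mask &= inside & (metric > 1e-12)
    # an anchor claimed by several GTs goes to the one with highest IoU
    cand = np.where(mask, ious, -1.0)
    best_gt = cand.argmax(axis=1)
    fg = mask[np.arange(a), best_gt]
    gt_idx = best_gt
    # normalise the alignment metric per GT into the target score
    am = np.where(mask, metric, 0.0)
    am_max = am.max(axis=0) + 1e-9
    iou_max = np.where(mask, ious, 0.0).max(axis=0)
    norm = am / am_max * iou_max
    tscore = np.where(fg, norm[np.arange(a), best_gt], 0.0).astype(np.float32)
    return gt_idx, tscore, fg


def compute_loss(outputs, targets: list, reg_max: int = 16):
    """Total detection loss for a batch.

    ``outputs``: list of per-level (box_logits, cls_logits, stride);
    ``targets``: per image [N, 5] arrays (class, x1, y1, x2, y2) pixels.
    Returns (total, parts dict).
    """
    shapes = [bl.shape[2:] for bl, _, _ in outputs]
    strides = [s for _, _, s in outputs]
    anchors, astr = _anchor_grid(shapes, strides)
    bsz = outputs[0][0].shape[0]
    nc = outputs[0][1].shape[1]
    a = anchors.shape[0]

    box_list = [bl.reshape(bsz, 4 * reg_max, -1) for bl, _, _ in outputs]
    cls_list = [cl.reshape(bsz, nc, -1) for _, cl, _ in outputs]
    dist_logits = concat(box_list, axis=2).reshape(bsz, 4, reg_max, a)
    cls_logits = concat(cls_list, axis=2).transpose(0, 2, 1)      # [B, A, nc]

    probs = dist_logits.softmax(axis=2)
    proj = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1)
    dist = (probs * proj).sum(axis=2)                             # [B, 4, A] cells
    cxs, cys = anchors[:, 0], anchors[:, 1]
    px1 = cxs - dist[:, 0] * astr
    py1 = cys - dist[:, 1] * astr
    px2 = cxs + dist[:, 2] * astr
    py2 = cys + dist[:, 3] * astr
    pred_boxes = concat([t.reshape(bsz, 1, a) for t in (px1, py1, px2, py2)],
                        axis=1).transpose(0, 2, 1)                # [B, A, 4]

    with nn.no_grad():
        scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))
    cls_targets = np.zeros((bsz, a, nc), dtype=np.float32)
    fg_all, gts_all, tsc_all, gtidx_all = [], [], [], []
    for i in range(bsz):
        gt = np.asarray(targets[i], dtype=np.float32).reshape(-1, 5)
        gt_idx, tscore, fg = task_aligned_assign(
            scores_np[i], pred_boxes.data[i], anchors, gt)
        if fg.any():
            cls_targets[i, fg, gt[gt_idx[fg], 0].astype(int)] = tscore[fg]
        fg_all.append(fg)
        gts_all.append(gt)
        tsc_all.append(tscore)
        gtidx_all.append(gt_idx)

    ts_sum = max(float(sum(t.sum() for t in tsc_all)), 1.0)
    cls_loss = _bce_logits(cls_logits, cls_targets).sum() * (1.0 / ts_sum)

    # gather positive anchors across the batch
    pos_pairs = [(i, np.nonzero(fg)[0]) for i, fg in enumerate(fg_all)]
    n_pos = sum(len(idx) for _, idx in pos_pairs)
    if n_pos == 0:
        zero = Tensor(np.zeros(()))
        total = cls_loss * CLS_WEIGHT
        return total, {"cls": cls_loss, "box": zero, "dfl": zero}

    flat_idx = np.concatenate([i * a + idx for i, idx in pos_pairs])
    tboxes = np.concatenate([gts_all[i][gtidx_all[i][idx]]
                             for i, idx in pos_pairs])
    weights = np.concatenate([tsc_all[i][idx] for i, idx in pos_pairs])

    pred_pos = pred_boxes.reshape(bsz * a, 4)[flat_idx]
    ciou = _ciou(pred_pos, tboxes[:, 1:])
    box_loss = ((1.0 - ciou) * weights).sum() * (1.0 / ts_sum)

    # distribution-focal targets: distances to the assigned box, in cells
    astr_pos = np.tile(astr, bsz)[flat_idx]
    anc_pos = np.tile(anchors, (bsz, 1))[flat_idx]
    ltrb = np.stack([
        (anc_pos[:, 0] - tboxes[:, 1]) / astr_pos,
        (anc_pos[:, 1] - tboxes[:, 2]) / astr_pos,
        (tboxes[:, 3] - anc_pos[:, 0]) / astr_pos,
        (tboxes[:, 4] - anc_pos[:, 1]) / astr_pos], axis=1)
    ltrb = np.clip(ltrb, 0, reg_max - 1 - 1e-3)
    lo = np.floor(ltrb).astype(np.int64)
    hi = lo + 1
    w_hi = (ltrb - lo).astype(np.float32)
    w_lo = 1.0 - w_hi
    dist_pos = dist_logits.transpose(0, 3, 1, 2).reshape(bsz * a, 4, reg_max)[flat_idx]
    logp = (dist_pos.softmax(axis=2) + 1e-9).log()
    pidx = np.arange(ltrb.shape[0])[:, None]
    side = np.arange(4)[None, :]
    dfl = -(logp[pidx, side, lo] * w_lo + logp[pidx, side, hi] * w_hi)
    dfl_loss = (dfl.mean(axis=1) * weights).sum() * (1.0 / ts_sum)

    total = cls_loss * CLS_WEIGHT + box_loss * BOX_WEIGHT + dfl_loss * DFL_WEIGHT
    return total, {"cls": cls_loss, "box": box_loss, "dfl": dfl_loss}


# ---------------------------------------------------------------------------
# mAP evaluation
# ---------------------------------------------------------------------------

IOU_GRID = np.round(np.arange(0.5, 0.96, 0.05), 2)


def _match_greedy(dets, gts, iou_thr):
    """Greedy score-ordered matching; returns per-det TP flags.

    ``dets``: [(box, score)] sorted by descending score (ties broken by
    box area then class id upstream); ``gts``: [M, 4].
    """
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i, (box, _score) in enumerate(dets):
        if len(gts) == 0:
            break
        ious = box_iou(np.asarray(box)[None], gts)[0]
        ious = np.where(matched, -1.0, ious)
        j = int(ious.argmax())
        if ious[j] >= iou_thr:
            matched[j] = True
            tp[i] = True
    return tp


def _sort_dets(dets: list[Detection]):
    def key(d):
        area = (d.box[2] - d.box[0]) * (d.box[3] - d.box[1])
        return (-d.score, -area, d.class_id)
    return sorted(dets, key=key)


def average_precision(tp: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from score-ranked TP flags."""
    if n_gt == 0:
        return float("nan")
    if tp.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101


def evaluate_map(detections: list[list[Detection]], ground_truths: list[np.ndarray],
                 iou_grid=IOU_GRID) -> APResult:
    """mAP over a dataset; classes with zero ground truths are excluded."""
    gts = [np.asarray(g, dtype=np.float32).reshape(-1, 5) for g in ground_truths]
    classes = sorted({int(c) for g in gts for c in g[:, 0]})
    ap_per_class: dict = {}
    ap5095_per_class: dict = {}
    counts50 = {}
    for c in classes:
        tp_by_thr = {t: [] for t in iou_grid}
        scores = []
        n_gt = 0
        for dets, gt in zip(detections, gts):
            cdets = _sort_dets([d for d in dets if d.class_id == c])
            cgt = gt[gt[:, 0] == c][:, 1:]
            n_gt += len(cgt)
            scores.extend(d.score for d in cdets)
            pairs = [(d.box, d.score) for d in cdets]
            for t in iou_grid:
                tp_by_thr[t].extend(_match_greedy(pairs, cgt, t))
        scores = np.asarray(scores)
        aps = {t: average_precision(np.asarray(tp_by_thr[t], dtype=bool),
                                    scores, n_gt) for t in iou_grid}
        ap_per_class[c] = aps[iou_grid[0]]
        ap5095_per_class[c] = float(np.mean(list(aps.values())))
        counts50[c] = (np.asarray(tp_by_thr[iou_grid[0]], dtype=bool), scores, n_gt)

    map50 = float(np.mean(list(ap_per_class.values()))) if ap_per_class else 0.0
    map5095 = float(np.mean(list(ap5095_per_class.values()))) if ap_per_class else 0.0

    # dataset precision/recall: plain counts over every detection (IoU 0.5),
    # plus the max-F1 confidence operating point
    all_tp = np.concatenate([v[0] for v in counts50.values()]) if counts50 else np.zeros(0, bool)
    all_sc = np.concatenate([v[1] for v in counts50.values()]) if counts50 else np.zeros(0)
    total_gt = sum(v[2] for v in counts50.values())
    n_tp = int(all_tp.sum())
    precision = n_tp / max(len(all_tp), 1)
    recall = n_tp / max(total_gt, 1)
    p_f1, r_f1 = _pr_at_max_f1(all_tp, all_sc, total_gt)
    return APResult(precision=precision, recall=recall, ap_per_class=ap_per_class,
                    map50=map50, map5095=map5095,
                    precision_f1=p_f1, recall_f1=r_f1)


def _pr_at_max_f1(tp, scores, n_gt):
    if tp.size == 0 or n_gt == 0:
        return 0.0, 0.0
    order = np.argsort(-scores, kind="stable")
    cum_tp = np.cumsum(tp[order])
    cum_fp = np.cumsum(~tp[order])
    p = cum_tp / (cum_tp + cum_fp)
    r = cum_tp / n_gt
    f1 = 2 * p * r / np.maximum(p + r, 1e-12)
    i = int(f1.argmax())
    return float(p[i]), float(r[i])


# ---------------------------------------------------------------------------
# TIDE error decomposition
# ---------------------------------------------------------------------------

def tide_decompose(detections: list[list[Detection]],
                   ground_truths: list[np.ndarray],
                   fg_iou: float = 0.5, bg_iou: float = 0.1) -> TIDEReport:
    """Assign every non-TP detection to exactly one error category.

    Categories, checked in order per detection (score-ranked):
    TP; Cls (IoU >= fg to a wrong-class GT); Loc (bg <= IoU < fg, right
    class); Both (bg <= IoU < fg, wrong class); Dupl (IoU >= fg to an
    already-matched right-class GT); Bkg (IoU < bg to every GT).
    Unmatched GTs count as Miss.  Rates are percentages: detection-side
    errors over all detections, Miss/FN over all ground truths.
    """
    if fg_iou <= bg_iou:
        raise ValueError("fg_iou must exceed bg_iou")
    counts = dict(cls=0, loc=0, both=0, dupl=0, bkg=0)
    n_dets = n_gts = n_tp = n_matched_gt = 0
    for dets, gt in zip(detections, ground_truths):
        gt = np.asarray(gt, dtype=np.float32).reshape(-1, 5)
        n_gts += len(gt)
        matched = np.zeros(len(gt), dtype=bool)
        for d in _sort_dets(dets):
            n_dets += 1
            if len(gt) == 0:
                counts["bkg"] += 1
                continue
            ious = box_iou(np.asarray(d.box)[None], gt[:, 1:])[0]
            same = gt[:, 0].astype(int) == d.class_id
            # true positive: best unmatched same-class GT above fg
            cand = np.where(same & ~matched, ious, -1.0)
            j = int(cand.argmax())
            if cand[j] >= fg_iou:
                matched[j] = True
                n_tp += 1
                continue
            if np.any(~same & (ious >= fg_iou)):
                counts["cls"] += 1
            elif np.any(same & (ious >= bg_iou) & (ious < fg_iou)):
                counts["loc"] += 1
            elif np.any(~same & (ious >= bg_iou) & (ious < fg_iou)):
                counts["both"] += 1
            elif np.any(same & matched & (ious >= fg_iou)):
                counts["dupl"] += 1
            else:
                counts["bkg"] += 1
        n_matched_gt += int(matched.sum())
    d = max(n_dets, 1)
    g = max(n_gts, 1)
    pct = lambda n, tot: 100.0 * n / tot
    return TIDEReport(
        cls=pct(counts["cls"], d), loc=pct(counts["loc"], d),
        both=pct(counts["both"], d), dupl=pct(counts["dupl"], d),
        bkg=pct(counts["bkg"], d), miss=pct(n_gts - n_matched_gt, g),
        fp=pct(n_dets - n_tp, d), fn=pct(n_gts - n_matched_gt, g))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _prepare_batch(samples: list[LabeledImage], imgsz: int):
    from .data_io import letterbox
    images, targets = [], []
    for s in samples:
        img, tf = letterbox(s.image, (imgsz, imgsz))
        images.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        px = s.boxes_pixels()
        if len(px):
            corners = px[:, 1:].reshape(-1, 2, 2)
            px[:, 1:] = tf.apply(corners).reshape(-1, 4)
        targets.append(px)
    return Tensor(np.stack(images)), targets


def _lr_at(epoch: int, frac: float, hyper: Hyperparams) -> float:
    t = epoch + frac
    if t < hyper.warmup_epochs:
        return hyper.lr0 * (0.1 + 0.9 * t / hyper.warmup_epochs)
    T = max(hyper.epochs - hyper.warmup_epochs, 1)
    progress = (t - hyper.warmup_epochs) / T
    return hyper.lr0 * (0.01 + 0.99 * 0.5 * (1 + math.cos(math.pi * progress)))


def train(model: PDYOLO, dataset: list[LabeledImage], hyper: Hyperparams,
          val_dataset: list[LabeledImage] | None = None,
          eval_interval: int = 5, target_map50: float | None = None):
    """SGD training; returns (model, per-evaluation metric log).

    Mosaic augmentation is active only while epoch < mosaic_off_epoch.
    When ``target_map50`` is set, training stops early once the metric
    is reached on the evaluation split (the training set by default).
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(hyper.seed)
    opt = nn.SGD(model.named_parameters(), lr=hyper.lr0,
                 momentum=hyper.momentum, weight_decay=hyper.weight_decay)
    history = []
    eval_set = val_dataset if val_dataset is not None else dataset
    steps = max(1, math.ceil(len(dataset) / hyper.batch))
    for epoch in range(hyper.epochs):
        model.train()
        order = rng.permutation(len(dataset))
        use_mosaic = epoch < hyper.mosaic_off_epoch
        epoch_loss = 0.0
        for step in range(steps):
            idx = order[step * hyper.batch:(step + 1) * hyper.batch]
            if idx.size == 0:
                continue
            batch = [dataset[i] for i in idx]
            if use_mosaic:
                batch = [mosaic_augment(
                    [dataset[j] for j in rng.integers(len(dataset), size=4)],
                    hyper.imgsz, seed=int(rng.integers(2 ** 31)))
                    for _ in batch]
            images, targets = _prepare_batch(batch, hyper.imgsz)
            opt.lr = _lr_at(epoch, step / steps, hyper)
            outputs = model(images)
            loss, parts = compute_loss(outputs, targets, model.config.reg_max)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"loss={float(loss.data)} parts="
                    f"{ {k: float(v.data) for k, v in parts.items()} }")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        last_epoch = epoch == hyper.epochs - 1
        if epoch % eval_interval == eval_interval - 1 or last_epoch:
            result = evaluate_model(model, eval_set, imgsz=hyper.imgsz)
            entry = {"epoch": epoch, "loss": epoch_loss / steps,
                     "precision": result.precision, "recall": result.recall,
                     "map50": result.map50, "map5095": result.map5095}
            history.append(entry)
            log.info("epoch %d: loss %.3f mAP50 %.3f", epoch, entry["loss"],
                     entry["map50"])
            if target_map50 is not None and result.map50 >= target_map50:
                break
    return model, history


def evaluate_model(model: PDYOLO, dataset: list[LabeledImage], imgsz: int = 640,
                   conf: float = 0.001, iou: float = 0.7,
                   batch: int = 8) -> APResult:
    """Letterbox, run the detector and score against the labels."""
    dets_all, gts_all = [], []
    for start in range(0, len(dataset), batch):
        chunk = dataset[start:start + batch]
        images, targets = _prepare_batch(chunk, imgsz)
        dets = predict(model, images, conf_threshold=conf, iou_threshold=iou)
        dets_all.extend(dets)
        gts_all.extend(targets)
    return evaluate_map(dets_all, gts_all)


def tide_report(model: PDYOLO, dataset: list[LabeledImage], imgsz: int = 640,
                conf: float = 0.25, iou: float = 0.7) -> TIDEReport:
    dets_all, gts_all = [], []
    for start in range(0, len(dataset), 8):
        chunk = dataset[start:start + 8]
        images, targets = _prepare_batch(chunk, imgsz)
        dets_all.extend(predict(model, images, conf_threshold=conf,
                                iou_threshold=iou))
        gts_all.extend(targets)
    return tide_decompose(dets_all, gts_all)
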