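"""PD-YOLO assembly: backbone + PF-FPN + dynamic head + decoupled detector.

Also provides the budget accountant (exact trainable-parameter counts and
closed-form FLOP estimates, 2 FLOPs per multiply-accumulate) and the
inference path (distribution-focal box decoding, confidence filtering,
class-wise greedy NMS).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .backbone import Backbone, ConvBlock, FeatureMap
from .config import ModelConfig
from .dyhead import DyHead
from .nn import Tensor
from .nn import functional as F
from .pf_fpn import NeckOutputs, build_neck


@dataclass
class Detection:
    """One predicted box, corner pixel coordinates, score in [0, 1]."""
    box: tuple          # (x1, y1, x2, y2)
    class_id: int
    score: float


@dataclass
class BudgetReport:
    params_total: int
    params_by_module: dict
    gflops: float

    def __post_init__(self):
        assert self.params_total == sum(self.params_by_module.values())

    def summary(self) -> str:
        lines = [f"parameters: {self.params_total / 1e6:.2f}M",
                 f"gflops:     {self.gflops:.1f}"]
        for k, v in self.params_by_module.items():
            lines.append(f"  {k:<10s} {v / 1e6:.2f}M")
        return "\n".join(lines)


class Detect(nn.Module):
    """Decoupled per-level classification and box-regression branches."""

    def __init__(self, ch: tuple, num_classes: int, reg_max: int = 16):
        super().__init__()
        self.nc, self.reg_max = num_classes, reg_max
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(num_classes, 100))
        self.box_branches = nn.ModuleList(
            nn.Sequential([ConvBlock(c, c2, 3), ConvBlock(c2, c2, 3),
                           nn.Conv2d(c2, 4 * reg_max, 1)]) for c in ch)
        self.cls_branches = nn.ModuleList(
            nn.Sequential([ConvBlock(c, c3, 3), ConvBlock(c3, c3, 3),
                           nn.Conv2d(c3, num_classes, 1)]) for c in ch)
        for branch in self.box_branches:
            branch[-1].bias.data[...] = 1.0
        for branch in self.cls_branches:
            # ~1% objectness prior keeps the early classification loss sane
            branch[-1].bias.data[...] = -4.6

    def forward(self, levels: list[FeatureMap]):
        out = []
        for f, bb, cb in zip(levels, self.box_branches, self.cls_branches):
            out.append((bb(f.data), cb(f.data), f.stride))
        return out


class PDYOLO(nn.Module):
    """Full detector; ablation switches in the config control each block."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        self.backbone = Backbone(config)
        self.neck = build_neck(config, self.backbone.out_channels)
        neck_ch = self.neck.out_channels
        if config.head.enable_dyhead:
            hc = config.head.channels
            self.head_proj = nn.ModuleList(
                ConvBlock(c, hc, 1) for c in neck_ch)
            self.dyhead = DyHead(hc, config.head.dyhead_blocks)
            det_ch = (hc,) * 3
        else:
            self.head_proj = None
            self.dyhead = None
            det_ch = neck_ch
        self.detect = Detect(det_ch, config.num_classes, config.reg_max)
        self.strides = (8, 16, 32)

    def forward(self, images: Tensor):
        feats = self.backbone(images)
        levels = self.neck(feats).as_list()
        if self.dyhead is not None:
            levels = [FeatureMap(p(f.data), f.stride)
                      for p, f in zip(self.head_proj, levels)]
            levels = self.dyhead(levels)
        return self.detect(levels)


def build_pdyolo(config: ModelConfig, seed: int = 0) -> PDYOLO:
    """Build with a fixed weight-init stream so identical configs match."""
    nn.seed_init(seed)
    return PDYOLO(config)


# ---------------------------------------------------------------------------
# budget accounting
# ---------------------------------------------------------------------------

def count_params(model: PDYOLO) -> int:
    return model.num_params()


def params_by_module(model: PDYOLO) -> dict:
    parts = {"backbone": model.backbone.num_params(),
             "neck": model.neck.num_params(),
             "detect": model.detect.num_params()}
    head_extra = 0
    if model.dyhead is not None:
        head_extra = model.dyhead.num_params() + model.head_proj.num_params()
    parts["dyhead"] = head_extra
    return parts


def count_flops(model: PDYOLO, input_size: tuple | None = None) -> float:
    """GFLOPs at the given input, 2 x multiply-accumulates, conv/linear terms."""
    h, w = input_size or model.config.input_size
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, model.config.in_channels, h, w), dtype=np.float32))
    with nn.no_grad(), F.profile_trace() as trace:
        model(x)
    if was_training:
        model.train()
    macs = sum(m for _, m in trace)
    return 2.0 * macs / 1e9


def budget_report(model: PDYOLO, input_size: tuple | None = None) -> BudgetReport:
    return BudgetReport(
        params_total=count_params(model),
        params_by_module=params_by_module(model),
        gflops=count_flops(model, input_size),
    )


# ---------------------------------------------------------------------------
# decoding and NMS
# ---------------------------------------------------------------------------

def decode_boxes(box_logits: np.ndarray, stride: int, reg_max: int) -> np.ndarray:
    """Distribution-focal decode: [B, 4*reg_max, H, W] -> [B, H*W, 4] pixels."""
    b, _, h, w = box_logits.shape
    logits = box_logits.reshape(b, 4, reg_max, h * w)
    z = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=2, keepdims=True)
    dist = (probs * np.arange(reg_max, dtype=np.float32)[None, None, :, None]).sum(axis=2)
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cx = (gx.reshape(-1) + 0.5)[None]
    cy = (gy.reshape(-1) + 0.5)[None]
    x1 = (cx - dist[:, 0]) * stride
    y1 = (cy - dist[:, 1]) * stride
    x2 = (cx + dist[:, 2]) * stride
    y2 = (cy + dist[:, 3]) * stride
    return np.stack([x1, y1, x2, y2], axis=-1)


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-format boxes [N,4] x [M,4]."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy NMS; returns kept indices sorted by descending score."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou(boxes[i][None], boxes[order[1:]])[0]
        order = order[1:][ious < iou_threshold]
    return np.array(keep, dtype=np.int64)


def predict(model: PDYOLO, images, conf_threshold: float = 0.25,
            iou_threshold: float = 0.45) -> list[list[Detection]]:
    """Run the detector and return per-image detections, sorted by score."""
    model.eval()
    images = images if isinstance(images, Tensor) else Tensor(images)
    with nn.no_grad():
        outputs = model(images)
    b = images.shape[0]
    all_boxes, all_scores, all_cls = [], [], []
    for box_logits, cls_logits, stride in outputs:
        boxes = decode_boxes(box_logits.data, stride, model.config.reg_max)
        scores = 1.0 / (1.0 + np.exp(-cls_logits.data))
        nc = scores.shape[1]
        all_boxes.append(boxes)
        all_scores.append(scores.reshape(b, nc, -1).transpose(0, 2, 1))
    boxes = np.concatenate(all_boxes, axis=1)
    scores = np.concatenate(all_scores, axis=1)

    results = []
    for i in range(b):
        cls_id = scores[i].argmax(axis=1)
        conf = scores[i].max(axis=1)
        m = conf >= conf_threshold
        bx, cf, ci = boxes[i][m], conf[m], cls_id[m]
        dets: list[Detection] = []
        for c in np.unique(ci):
            sel = ci == c
            keep = nms(bx[sel], cf[sel], iou_threshold)
            for j in keep:
                x1, y1, x2, y2 = bx[sel][j]
                if x2 > x1 and y2 > y1:
                    dets.append(Detection((float(x1), float(y1), float(x2),
                                           float(y2)), int(c), float(cf[sel][j])))
        dets.sort(key=lambda d: -d.score)
        results.append(dets)
    return results


# ---------------------------------------------------------------------------
# checkpoints: single-file weights + config
# ---------------------------------------------------------------------------

def save_checkpoint(model: PDYOLO, path):
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        yaml.safe_dump(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> PDYOLO:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    cfg = ModelConfig.from_dict(
        yaml.safe_load(io.BytesIO(data["__config__"].tobytes())))
    model = build_pdyolo(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
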