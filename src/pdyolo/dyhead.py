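"""Dynamic detection head: scale-, spatial- and task-aware attention.

Pyramid levels are projected to a common width, resampled to the middle
(stride-16) grid and stacked into a level-space-channel tensor.  Each
block applies, in order:

* scale attention  -- per-level scalar gate, hard-sigmoid of a linear map
  of the level's global mean;
* spatial attention -- modulated deformable 3x3 sampling (K = 9 points,
  bilinear interpolation, zero padding outside the map) with per-level
  offsets shared from the median level, aggregated over neighbouring
  levels;
* task attention   -- per-channel dynamic piecewise-linear activation
  max(a1*x + b1, a2*x + b2) whose coefficients are emitted by a small
  bottleneck hyper-network, normalised to [-1, 1] (a1 is offset by +1 so
  the initial map is a standard rectifier).

After the configured number of blocks the levels are resampled back to
their original grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import FeatureMap
from .nn import Tensor
from .nn import functional as F

K_POINTS = 9  # 3x3 sampling lattice


@dataclass
class DeformParams:
    """Explicit sampling parameters for the spatial-attention primitive."""
    offsets: np.ndarray   # [B, 2K, H, W] fractional (dy, dx) pairs
    masks: Tensor         # [B, K, H, W] modulation scalars
    k: int = K_POINTS


def deform_conv3x3(x: Tensor, weight: Tensor, offsets: np.ndarray,
                   masks: Tensor) -> Tensor:
    """Deformable 3x3 convolution via bilinear gathering.

    ``weight``: [Cout, Cin, 9]; ``offsets``: [B, 18, H, W] ordered as
    (dy, dx) per sampling point; ``masks``: [B, 9, H, W].  With zero
    offsets and unit masks this equals a dense 3x3 same-padding
    convolution with the same weights.
    """
    b, c, h, w = x.shape
    k = K_POINTS
    base_dy = np.repeat(np.arange(-1, 2), 3).astype(np.float32)
    base_dx = np.tile(np.arange(-1, 2), 3).astype(np.float32)
    gy, gx = np.meshgrid(np.arange(h, dtype=np.float32),
                         np.arange(w, dtype=np.float32), indexing="ij")
    off = offsets.reshape(b, k, 2, h, w)
    ys = gy[None, None] + base_dy[None, :, None, None] + off[:, :, 0]
    xs = gx[None, None] + base_dx[None, :, None, None] + off[:, :, 1]
    sampled = F.bilinear_gather(x, ys.reshape(b, k, h * w),
                                xs.reshape(b, k, h * w))      # [B,C,K,HW]
    modulated = sampled * masks.reshape(b, 1, k, h * w)
    cout = weight.shape[0]
    flat = modulated.reshape(b, c * k, h * w)    # channel-major, then point
    out = weight.reshape(cout, c * k) @ flat                   # [B,Cout,HW]
    F._record("deform_conv", b * cout * c * k * h * w)
    return out.reshape(b, cout, h, w)


class ScaleAttention(nn.Module):
    """Per-level scalar gate: hard-sigmoid(linear(mean over space+channels))."""

    def __init__(self):
        super().__init__()
        self.fc = nn.Linear(1, 1)

    def forward(self, levels: list[Tensor]) -> list[Tensor]:
        out = []
        for f in levels:
            m = f.mean(axis=(1, 2, 3), keepdims=True)          # [B,1,1,1]
            gate = self.fc(m.reshape(m.shape[0], 1)).hardsigmoid()
            out.append(f * gate.reshape(m.shape[0], 1, 1, 1))
        return out


class SpatialAttention(nn.Module):
    """Level-aggregated modulated deformable sampling.

    Offsets and modulation masks are predicted once from the median-level
    feature; each output level averages deformable convolutions of itself
    and its adjacent levels (separate weight banks for the lower / same /
    higher neighbour).
    """

    def __init__(self, channels: int):
        super().__init__()
        self.offset_conv = nn.Conv2d(channels, 3 * K_POINTS, 3, bias=True)
        self.w_low = nn.Conv2d(channels, channels, 3, bias=False)
        self.w_mid = nn.Conv2d(channels, channels, 3, bias=False)
        self.w_high = nn.Conv2d(channels, channels, 3, bias=False)
        groups = 16
        while channels % groups:
            groups //= 2
        self.norm = nn.GroupNorm(groups, channels)

    def predict_params(self, median: Tensor) -> DeformParams:
        pred = self.offset_conv(median)
        off = pred[:, : 2 * K_POINTS]
        masks = pred[:, 2 * K_POINTS:].sigmoid()
        return DeformParams(offsets=off.data, masks=masks)

    def _dcn(self, x: Tensor, bank: nn.Conv2d, p: DeformParams) -> Tensor:
        w = bank.weight.reshape(bank.weight.shape[0], bank.weight.shape[1], 9)
        return deform_conv3x3(x, w, p.offsets, p.masks)

    def forward(self, levels: list[Tensor], params: DeformParams | None = None
                ) -> list[Tensor]:
        if params is None:
            params = self.predict_params(levels[len(levels) // 2])
        out = []
        nl = len(levels)
        for i in range(nl):
            acc = self._dcn(levels[i], self.w_mid, params)
            n = 1
            if i > 0:
                acc = acc + self._dcn(levels[i - 1], self.w_low, params)
                n += 1
            if i < nl - 1:
                acc = acc + self._dcn(levels[i + 1], self.w_high, params)
                n += 1
            out.append(self.norm(acc * (1.0 / n)).relu())
        return out


def dynamic_relu(x: Tensor, a1, a2, b1, b2) -> Tensor:
    """max(a1*x + b1, a2*x + b2) with per-channel coefficients."""
    return (a1 * x + b1).maximum(a2 * x + b2)


class TaskAttention(nn.Module):
    """Per-channel dynamic activation controlled by a bottleneck hyper-net."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        hidden = max(4, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, 4 * channels)
        self.channels = channels

    def coefficients(self, f: Tensor):
        pooled = f.mean(axis=(2, 3))                    # [B, C]
        raw = self.fc2(self.fc1(pooled).relu())
        v = raw.sigmoid() * 2.0 - 1.0                   # normalised to (-1, 1)
        b, c = pooled.shape[0], self.channels
        v = v.reshape(b, 4, c, 1, 1)
        a1 = v[:, 0] + 1.0   # identity-rectifier at the init point
        a2 = v[:, 1]
        b1 = v[:, 2]
        b2 = v[:, 3]
        return a1, a2, b1, b2

    def forward(self, levels: list[Tensor]) -> list[Tensor]:
        return [dynamic_relu(f, *self.coefficients(f)) for f in levels]


class DyHeadBlock(nn.Module):
    def __init__(self, channels: int):
        super().__init__()
        self.scale = ScaleAttention()
        self.spatial = SpatialAttention(channels)
        self.task = TaskAttention(channels)

    def forward(self, levels: list[Tensor]) -> list[Tensor]:
        return self.task(self.spatial(self.scale(levels)))


class DyHead(nn.Module):
    """n_blocks sequential (scale, spatial, task) sandwiches on the stack."""

    def __init__(self, channels: int, n_blocks: int = 2):
        super().__init__()
        self.blocks = nn.ModuleList(DyHeadBlock(channels) for _ in range(n_blocks))

    def forward(self, features: list[FeatureMap]) -> list[FeatureMap]:
        if not self.blocks:
            return list(features)
        shapes = [f.data.shape[2:] for f in features]
        common = shapes[-1]  # coarsest grid keeps the stack compact
        levels = [F.resize_nearest(f.data, common) for f in features]
        for block in self.blocks:
            levels = block(levels)
        return [FeatureMap(F.resize_nearest(lv, s), f.stride)
                for lv, s, f in zip(levels, shapes, features)]


def dyhead_forward(module: DyHead, features: list[FeatureMap]) -> list[FeatureMap]:
    return module(features)
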