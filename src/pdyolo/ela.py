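"""Efficient Local Attention: per-axis strip pooling, gating, outer product.

The input map is average-pooled along each spatial axis to two strip
vectors, each passed through a depthwise 1-D convolution (kernel 7), group
normalisation and a sigmoid; the full attention map is the outer product
of the two axis gates, so every H x W slice has rank <= 1 and all entries
lie strictly in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor
from .nn import functional as F


@dataclass
class StripVectors:
    """Per-row means zh [B,C,H] and per-column means zw [B,C,W]."""
    zh: Tensor
    zw: Tensor


@dataclass
class AttentionMap:
    fh: Tensor       # [B, C, H, 1]
    fw: Tensor       # [B, C, 1, W]
    f_ela: Tensor    # [B, C, H, W] = fh * fw


def strip_pool(x: Tensor) -> StripVectors:
    """Average the map along each axis (true means over the summed axis)."""
    return StripVectors(zh=x.mean(axis=3), zw=x.mean(axis=2))


class ELA(nn.Module):
    """Axis-strip attention gate.

    ``groups`` defaults to 16; when the channel count is smaller it falls
    back to one group per channel so the normalisation stays defined.
    """

    def __init__(self, channels: int, kernel: int = 7, groups: int = 16):
        super().__init__()
        if channels < groups:
            groups = channels
        if channels % groups:
            raise ValueError(
                f"ELA: {channels} channels not divisible by {groups} "
                f"normalisation groups; pass a group count dividing the channels")
        self.channels = channels
        self.kernel = kernel
        # depthwise, bias-free 1-D conv run along the pooled axis;
        # edge-replicate padding keeps constant strips constant
        self.conv_h = nn.Conv2d(channels, channels, (1, kernel), padding=0,
                                groups=channels, bias=False)
        self.conv_w = nn.Conv2d(channels, channels, (1, kernel), padding=0,
                                groups=channels, bias=False)
        self.gn_h = nn.GroupNorm(groups, channels)
        self.gn_w = nn.GroupNorm(groups, channels)

    def _axis_gate(self, z: Tensor, conv: nn.Conv2d, gn: nn.GroupNorm) -> Tensor:
        v = z.reshape(z.shape[0], z.shape[1], 1, z.shape[2])  # [B,C,1,N]
        v = F.pad_replicate2d(v, 0, self.kernel // 2)
        return gn(conv(v)).sigmoid()

    def forward(self, x: Tensor) -> AttentionMap:
        strips = strip_pool(x)
        b, c, h, w = x.shape
        fh = self._axis_gate(strips.zh, self.conv_h, self.gn_h).reshape(b, c, h, 1)
        fw = self._axis_gate(strips.zw, self.conv_w, self.gn_w).reshape(b, c, 1, w)
        return AttentionMap(fh=fh, fw=fw, f_ela=fh * fw)


def ela_weights(module: ELA, x: Tensor) -> AttentionMap:
    """Operation-level wrapper: attention weights for a feature map."""
    return module(x)
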