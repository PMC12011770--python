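"""Hierarchical Adaptive Recalibration Fusion Module.

A shallower feature Xl is projected (3x3 Conv+BN+SiLU, stride 2 when its
grid is twice as fine) to the channel count C2 of the deeper feature X2
and concatenated with it:

    FC   = concat(CBS(Xl), X2)                        # 2*C2 channels
    F1   = ReLU(1x1 conv(FC))                         # 2*C2/r channels
    F2   = ReLU(DW(ReLU(DW(F1))))                     # depthwise 3x3 pair
    F3   = ReLU(1x1 conv(F2))                         # back to 2*C2
    Fout = sigmoid(GN(F3)) * FC + FC                  # residual recalibration

The gate is a bottleneck with reduction ratio r; group normalisation (16
groups) keeps the gate statistics batch-size independent.
"""

from __future__ import annotations

from . import nn
from .backbone import ConvBlock, FeatureMap
from .nn import Tensor, concat
from .nn import functional as F


class RecalibrationGate(nn.Module):
    """sigma(GN(F3)) computed from the concatenated feature FC."""

    def __init__(self, channels: int, r: int = 16, gn_groups: int = 16):
        super().__init__()
        if channels % r:
            raise ValueError(
                f"HARFM: gate channels {channels} not divisible by r={r}")
        cr = channels // r
        self.reduce = nn.Conv2d(channels, cr, 1, bias=True)
        # edge-replicate padding in the depthwise pair keeps a flat FC flat
        self.dw1 = nn.Conv2d(cr, cr, 3, padding=0, groups=cr, bias=True)
        self.dw2 = nn.Conv2d(cr, cr, 3, padding=0, groups=cr, bias=True)
        self.restore = nn.Conv2d(cr, channels, 1, bias=True)
        if channels < gn_groups:
            gn_groups = channels
        self.gn = nn.GroupNorm(gn_groups, channels)

    def forward(self, fc: Tensor) -> Tensor:
        f1 = self.reduce(fc).relu()
        f2 = self.dw1(F.pad_replicate2d(f1, 1, 1)).relu()
        f2 = self.dw2(F.pad_replicate2d(f2, 1, 1)).relu()
        f3 = self.restore(f2).relu()
        return self.gn(f3).sigmoid()


class HARFM(nn.Module):
    def __init__(self, c_low: int, c_high: int, r: int = 16, downsample: bool = True):
        super().__init__()
        self.project = ConvBlock(c_low, c_high, 3, 2 if downsample else 1)
        self.gate = RecalibrationGate(2 * c_high, r)
        self.out_channels = 2 * c_high
        self.downsample = downsample

    def forward(self, xl: FeatureMap, x2: FeatureMap) -> FeatureMap:
        ratio = xl.data.shape[2] // x2.data.shape[2]
        if ratio not in (1, 2) or ratio != (2 if self.downsample else 1):
            raise ValueError(
                f"HARFM: spatial ratio {ratio} does not match the configured "
                f"{'2x' if self.downsample else '1x'} projection")
        fc = concat([self.project(xl.data), x2.data], axis=1)
        gate = self.gate(fc)
        return FeatureMap(gate * fc + fc, x2.stride)


def harfm_forward(module: HARFM, xl: FeatureMap, x2: FeatureMap) -> FeatureMap:
    return module(xl, x2)


def recalibration_gate(module: HARFM, fc: Tensor) -> Tensor:
    """Expose only the sigma(GN(F3)) gate of a built HARFM block."""
    return module.gate(fc)
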