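"""Feature Filtering and Aggregation Module.

Three backbone scales are aligned to the mid (stride-16) grid, gated with
ELA attention, summed, and enriched with a parallel bank of depthwise
convolutions whose kernel sizes follow the rule k_m = (m+1)*2+1, i.e.
[5, 7, 9, 11], fused by a pointwise convolution:

    MS  = ELA(high) * low + high + ELA(mid) * mid        (filtered sum)
    MC  = PW( sum_m DW_km(MS) + MS )                     (multi-kernel context)
    F'  = MS + MC                                        (module output)
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .backbone import ConvBlock, FeatureMap
from .ela import ELA
from .nn import Tensor
from .nn import functional as F


@dataclass
class KernelPlan:
    """Ordered odd kernel sizes of the parallel depthwise branches."""
    kernels: tuple = tuple((m + 1) * 2 + 1 for m in range(1, 5))

    def __post_init__(self):
        assert all(k % 2 == 1 for k in self.kernels)

    @property
    def largest(self) -> int:
        return max(self.kernels)


@dataclass
class AlignedTriple:
    """The three scale branches co-registered on one grid (stride 16)."""
    low: FeatureMap
    mid: FeatureMap
    high: FeatureMap


@dataclass
class FusedMap:
    ms: Tensor
    mc: Tensor
    f_prime: Tensor


class ScaleAlign(nn.Module):
    """Bring (stride-8, stride-16, stride-32) features to the mid grid.

    low: 3x3 stride-2 conv; mid: 3x3 stride-1 conv; high: nearest x2
    upsample followed by a 1x1 conv.
    """

    def __init__(self, c_low: int, c_mid: int, c_high: int, out_channels: int):
        super().__init__()
        self.down_low = ConvBlock(c_low, out_channels, 3, 2)
        self.conv_mid = ConvBlock(c_mid, out_channels, 3, 1)
        self.up_high = ConvBlock(c_high, out_channels, 1, 1)
        self.out_channels = out_channels

    def forward(self, low: FeatureMap, mid: FeatureMap, high: FeatureMap) -> AlignedTriple:
        if not (low.data.shape[0] == mid.data.shape[0] == high.data.shape[0]):
            raise ValueError("align_scales: mismatched batch sizes")
        stride = mid.stride
        return AlignedTriple(
            low=FeatureMap(self.down_low(low.data), stride),
            mid=FeatureMap(self.conv_mid(mid.data), stride),
            high=FeatureMap(self.up_high(F.upsample_nearest(high.data, 2)), stride),
        )


class MultiKernelExtract(nn.Module):
    """Parallel depthwise bank (kernels 5/7/9/11) + identity, fused 1x1."""

    def __init__(self, channels: int, plan: KernelPlan | None = None):
        super().__init__()
        self.plan = plan or KernelPlan()
        self.branches = nn.ModuleList(
            nn.Conv2d(channels, channels, k, groups=channels, bias=False)
            for k in self.plan.kernels)
        # plain 1x1 pointwise fusion (no norm/activation)
        self.pw = nn.Conv2d(channels, channels, 1, bias=True)

    def forward(self, ms: Tensor) -> Tensor:
        acc = ms
        for conv in self.branches:
            acc = acc + conv(ms)
        return self.pw(acc)


class FFAM(nn.Module):
    def __init__(self, c_low: int, c_mid: int, c_high: int, out_channels: int):
        super().__init__()
        self.align = ScaleAlign(c_low, c_mid, c_high, out_channels)
        self.ela_high = ELA(out_channels)
        self.ela_mid = ELA(out_channels)
        self.extract = MultiKernelExtract(out_channels)
        self.out_channels = out_channels

    def filter_fuse(self, aligned: AlignedTriple) -> Tensor:
        """MS = ELA(high)*low + high + ELA(mid)*mid."""
        gate_high = self.ela_high(aligned.high.data).f_ela
        gate_mid = self.ela_mid(aligned.mid.data).f_ela
        return gate_high * aligned.low.data + aligned.high.data \
            + gate_mid * aligned.mid.data

    def forward(self, low: FeatureMap, mid: FeatureMap, high: FeatureMap) -> FusedMap:
        aligned = self.align(low, mid, high)
        ms = self.filter_fuse(aligned)
        mc = self.extract(ms)
        return FusedMap(ms=ms, mc=mc, f_prime=ms + mc)


def ffam_forward(module: FFAM, low: FeatureMap, mid: FeatureMap,
                 high: FeatureMap) -> FeatureMap:
    return FeatureMap(module(low, mid, high).f_prime, mid.stride)
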