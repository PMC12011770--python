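"""Parallel Focusing Feature Pyramid.

Full mode wires one radial FFAM (aggregating {C1, C2, C3} at stride 16,
redistributing to every level through resize + 1x1 channel matching) and
one HARFM per lateral path (each level's backbone feature recalibrated
against the adjacent shallower tap; the stride-8 path uses the backbone's
internal stride-4 feature).  Each level then fuses the concatenated
radial and lateral streams with a C2f block.

With both novel blocks disabled the neck degrades to the classic
top-down/bottom-up lateral C2f pyramid (PA-FPN), which is the baseline
ablation configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .backbone import C2f, ConvBlock, FeatureMap, MultiScaleFeatures
from .config import ModelConfig
from .ffam import FFAM
from .harfm import HARFM
from .nn import concat
from .nn import functional as F


@dataclass
class NeckOutputs:
    """Final pyramid {P1 (stride 8), P2 (stride 16), P3 (stride 32)}."""
    p1: FeatureMap
    p2: FeatureMap
    p3: FeatureMap

    def as_list(self) -> list[FeatureMap]:
        return [self.p1, self.p2, self.p3]


class Redistribute(nn.Module):
    """FFAM output redistributed to one level: resize then 1x1 match conv."""

    def __init__(self, c_in: int, c_out: int, mode: str):
        super().__init__()
        self.mode = mode  # 'up' (to stride 8), 'same', 'down' (to stride 32)
        if mode == "down":
            self.resize = ConvBlock(c_in, c_in, 3, 2)
        else:
            self.resize = nn.Identity()
        self.match = ConvBlock(c_in, c_out, 1)

    def forward(self, x):
        if self.mode == "up":
            # 1x1 conv commutes with nearest upsampling; match first, cheaper
            return F.upsample_nearest(self.match(x), 2)
        return self.match(self.resize(x))


class PAFPNNeck(nn.Module):
    """Baseline lateral neck: top-down then bottom-up C2f paths."""

    def __init__(self, config: ModelConfig, ch: tuple):
        super().__init__()
        _, c1, c2, c3 = ch
        d = config.scaled_depth(3)
        self.td2 = C2f(c3 + c2, c2, d)           # stride 16, top-down
        self.td1 = C2f(c2 + c1, c1, d)           # stride 8
        self.down1 = ConvBlock(c1, c1, 3, 2)
        self.bu2 = C2f(c1 + c2, c2, d)           # stride 16, bottom-up
        self.down2 = ConvBlock(c2, c2, 3, 2)
        self.bu3 = C2f(c2 + c3, c3, d)           # stride 32
        self.out_channels = (c1, c2, c3)

    def forward(self, feats: MultiScaleFeatures) -> NeckOutputs:
        c1, c2, c3 = feats.c1.data, feats.c2.data, feats.c3.data
        t2 = self.td2(concat([F.upsample_nearest(c3, 2), c2], axis=1))
        p1 = self.td1(concat([F.upsample_nearest(t2, 2), c1], axis=1))
        p2 = self.bu2(concat([self.down1(p1), t2], axis=1))
        p3 = self.bu3(concat([self.down2(p2), c3], axis=1))
        return NeckOutputs(FeatureMap(p1, 8), FeatureMap(p2, 16), FeatureMap(p3, 32))


class PFFPN(nn.Module):
    """Parallel-focusing neck; FFAM and HARFM are independently switchable."""

    def __init__(self, config: ModelConfig, ch: tuple):
        super().__init__()
        cs4, c1, c2, c3 = ch
        neck = config.neck
        self.enable_ffam = neck.enable_ffam
        self.enable_harfm = neck.enable_harfm
        d = config.scaled_depth(3)
        lateral = [c1, c2, c3]

        if self.enable_ffam:
            cp = neck.ffam_channels
            self.ffam = FFAM(c1, c2, c3, cp)
            self.redist1 = Redistribute(cp, c1, "up")
            self.redist2 = Redistribute(cp, c2, "same")
            self.redist3 = Redistribute(cp, c3, "down")
        if self.enable_harfm:
            r = neck.harfm_r
            self.harfm1 = HARFM(cs4, c1, r)
            self.harfm2 = HARFM(c1, c2, r)
            self.harfm3 = HARFM(c2, c3, r)
            lateral = [2 * c1, 2 * c2, 2 * c3]

        radial = [c1, c2, c3] if self.enable_ffam else [0, 0, 0]
        self.fuse1 = C2f(radial[0] + lateral[0], c1, d)
        self.fuse2 = C2f(radial[1] + lateral[1], c2, d)
        self.fuse3 = C2f(radial[2] + lateral[2], c3, d)
        self.out_channels = (c1, c2, c3)

    def forward(self, feats: MultiScaleFeatures) -> NeckOutputs:
        if self.enable_harfm:
            lat = [self.harfm1(feats.s4, feats.c1).data,
                   self.harfm2(feats.c1, feats.c2).data,
                   self.harfm3(feats.c2, feats.c3).data]
        else:
            lat = [feats.c1.data, feats.c2.data, feats.c3.data]
        if self.enable_ffam:
            fused = self.ffam(feats.c1, feats.c2, feats.c3).f_prime
            streams = [concat([self.redist1(fused), lat[0]], axis=1),
                       concat([self.redist2(fused), lat[1]], axis=1),
                       concat([self.redist3(fused), lat[2]], axis=1)]
        else:
            streams = lat
        return NeckOutputs(
            FeatureMap(self.fuse1(streams[0]), 8),
            FeatureMap(self.fuse2(streams[1]), 16),
            FeatureMap(self.fuse3(streams[2]), 32),
        )


def build_neck(config: ModelConfig, ch: tuple) -> nn.Module:
    """``ch``: backbone tap channels (stride-4, 8, 16, 32)."""
    if config.neck.enable_ffam or config.neck.enable_harfm:
        return PFFPN(config, ch)
    return PAFPNNeck(config, ch)


def neck_forward(neck: nn.Module, feats: MultiScaleFeatures) -> NeckOutputs:
    return neck(feats)
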