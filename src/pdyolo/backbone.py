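"""CSP backbone producing the three-scale feature triple {C1, C2, C3}.

Layout follows the nano-family convention: 3x3/stride-2 Conv+BN+SiLU stems,
C2f split-bottleneck-concat blocks with depths [1,2,2,1] after depth
scaling, and a terminal SPPF (serial 5x5 max-pool pyramid).  Taps are
exposed at strides 8/16/32 plus the internal stride-4 feature used by the
neck's shallowest lateral path.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .config import ModelConfig
from .nn import Tensor, concat


@dataclass
class FeatureMap:
    """4-D activation [batch, channels, height, width] plus its pixel stride."""
    data: Tensor
    stride: int

    @property
    def shape(self):
        return self.data.shape

    @property
    def channels(self) -> int:
        return self.data.shape[1]


@dataclass
class MultiScaleFeatures:
    """Backbone taps: c1 (stride 8), c2 (stride 16), c3 (stride 32).

    ``s4`` carries the shallower stride-4 feature consumed by the neck's
    first lateral fusion; it is not part of the canonical triple.
    """
    c1: FeatureMap
    c2: FeatureMap
    c3: FeatureMap
    s4: FeatureMap | None = None


class ConvBlock(nn.Module):
    """Conv + BatchNorm + SiLU, the basic stem unit."""

    def __init__(self, cin: int, cout: int, kernel: int = 1, stride: int = 1,
                 groups: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride, groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    def __init__(self, cin: int, cout: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = ConvBlock(cin, cout, 3)
        self.cv2 = ConvBlock(cout, cout, 3)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Split-transform-concatenate block with n bottleneck branches."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = False):
        super().__init__()
        self.c = cout // 2
        self.cv1 = ConvBlock(cin, 2 * self.c, 1)
        self.cv2 = ConvBlock((2 + n) * self.c, cout, 1)
        self.m = nn.ModuleList(Bottleneck(self.c, self.c, shortcut) for _ in range(n))

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(concat(outs, axis=1))


class SPPF(nn.Module):
    """Serial max-pool pyramid (three chained k x k pools, concatenated)."""

    def __init__(self, cin: int, cout: int, kernel: int = 5):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBlock(cin, c_, 1)
        self.cv2 = ConvBlock(c_ * 4, cout, 1)
        self.pool = nn.MaxPool2d(kernel, stride=1, padding=kernel // 2)

    def forward(self, x):
        x = self.cv1(x)
        y1 = self.pool(x)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concat([x, y1, y2, y3], axis=1))


class Backbone(nn.Module):
    """Five-stage CSP backbone; ``channels`` lists the per-stage widths."""

    BASE_CHANNELS = (64, 128, 256, 512, 1024)
    BASE_DEPTHS = (3, 6, 6, 3)

    def __init__(self, config: ModelConfig):
        super().__init__()
        ch = [config.scaled_channels(c) for c in self.BASE_CHANNELS]
        d = [config.scaled_depth(n) for n in self.BASE_DEPTHS]
        self.channels = ch
        self.stem = ConvBlock(config.in_channels, ch[0], 3, 2)      # stride 2
        self.down1 = ConvBlock(ch[0], ch[1], 3, 2)                  # stride 4
        self.stage1 = C2f(ch[1], ch[1], d[0], shortcut=True)
        self.down2 = ConvBlock(ch[1], ch[2], 3, 2)                  # stride 8
        self.stage2 = C2f(ch[2], ch[2], d[1], shortcut=True)
        self.down3 = ConvBlock(ch[2], ch[3], 3, 2)                  # stride 16
        self.stage3 = C2f(ch[3], ch[3], d[2], shortcut=True)
        self.down4 = ConvBlock(ch[3], ch[4], 3, 2)                  # stride 32
        self.stage4 = C2f(ch[4], ch[4], d[3], shortcut=True)
        self.sppf = SPPF(ch[4], ch[4], kernel=5)

    @property
    def out_channels(self):
        """Channel counts of the (s4, C1, C2, C3) taps."""
        ch = self.channels
        return ch[1], ch[2], ch[3], ch[4]

    def forward(self, images: Tensor) -> MultiScaleFeatures:
        h, w = images.shape[2], images.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input {h}x{w} not divisible by 32; pad to "
                f"{-(-h // 32) * 32}x{-(-w // 32) * 32}")
        x = self.stem(images)
        s4 = self.stage1(self.down1(x))
        c1 = self.stage2(self.down2(s4))
        c2 = self.stage3(self.down3(c1))
        c3 = self.sppf(self.stage4(self.down4(c2)))
        return MultiScaleFeatures(
            c1=FeatureMap(c1, 8), c2=FeatureMap(c2, 16), c3=FeatureMap(c3, 32),
            s4=FeatureMap(s4, 4))


def build_backbone(config: ModelConfig) -> Backbone:
    return Backbone(config)
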