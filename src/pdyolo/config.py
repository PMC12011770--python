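"""Model configuration: scaling multipliers, neck/head hyperparameters, YAML I/O.

The canonical configuration is the nano-scale detector (width 0.25, depth
0.33) with all three novel blocks enabled; the free widths below (FFAM
internal width, HARFM reduction ratio, dynamic-head channels and block
count) are the shipped calibration of the published parameter/FLOP budget.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass
class NeckConfig:
    ffam_channels: int = 112     # FFAM internal width C'
    harfm_r: int = 16            # bottleneck reduction ratio of the HARFM gate
    enable_ffam: bool = True
    enable_harfm: bool = True


@dataclass
class HeadConfig:
    dyhead_blocks: int = 2
    channels: int = 80           # common channel width of the dynamic head
    enable_dyhead: bool = True


@dataclass
class ModelConfig:
    num_classes: int = 12
    input_size: tuple = (640, 640)
    width_mult: float = 0.25
    depth_mult: float = 0.33
    in_channels: int = 3
    max_channels: int = 1024
    reg_max: int = 16
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)

    def __post_init__(self):
        if self.width_mult <= 0 or self.depth_mult <= 0:
            raise ValueError("width_mult and depth_mult must be positive")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        self.input_size = tuple(self.input_size)
        if any(s % 32 for s in self.input_size):
            raise ValueError(f"input_size {self.input_size} must be divisible by 32")

    # -- scaling rules --------------------------------------------------
    def scaled_channels(self, c: int) -> int:
        """Width scaling with the conventional divisible-by-8 rounding."""
        c = min(c, self.max_channels)
        return max(8, int(math.ceil(c * self.width_mult / 8) * 8))

    def scaled_depth(self, n: int) -> int:
        return max(1, round(n * self.depth_mult))

    def baseline(self) -> "ModelConfig":
        """Ablation configuration with every novel block disabled."""
        return replace(
            self,
            neck=replace(self.neck, enable_ffam=False, enable_harfm=False),
            head=replace(self.head, enable_dyhead=False),
        )

    # -- YAML ------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "neck" in d and isinstance(d["neck"], dict):
            d["neck"] = NeckConfig(**d["neck"])
        if "head" in d and isinstance(d["head"], dict):
            d["head"] = HeadConfig(**d["head"])
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
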