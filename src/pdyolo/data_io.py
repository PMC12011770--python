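"""YOLO-format dataset I/O, preprocessing, and synthetic weed scenes.

Labels are one ``.txt`` per image with ``class cx cy w h`` lines, centre
format normalised to [0, 1].  The synthetic generator renders soil-
textured backgrounds and procedurally drawn plants (rosette / star /
ellipse silhouettes with class-conditioned colour and shape palettes) and
emits exact bounding boxes from the rendered masks, emulating field
scenes with occlusion, large scale differences and small targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

log = logging.getLogger("pdyolo.data")

IMAGE_EXTS = (".png", ".jpg", ".jpeg", ".bmp")


@dataclass
class LabeledImage:
    image: np.ndarray                    # H x W x 3 uint8 RGB
    boxes: list                         # [(class_id, cx, cy, w, h)] normalised
    image_id: str = ""

    @property
    def size(self):
        return self.image.shape[:2]

    def boxes_pixels(self) -> np.ndarray:
        """Corner-format pixel boxes [N, 5]: class, x1, y1, x2, y2."""
        h, w = self.size
        out = []
        for cid, cx, cy, bw, bh in self.boxes:
            out.append([cid, (cx - bw / 2) * w, (cy - bh / 2) * h,
                        (cx + bw / 2) * w, (cy + bh / 2) * h])
        return np.array(out, dtype=np.float32).reshape(-1, 5)


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------

def _clip_box(cx, cy, w, h):
    x1, y1 = np.clip(cx - w / 2, 0, 1), np.clip(cy - h / 2, 0, 1)
    x2, y2 = np.clip(cx + w / 2, 0, 1), np.clip(cy + h / 2, 0, 1)
    return ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


def parse_label_file(path: Path, num_classes: int | None = None) -> list:
    boxes = []
    if not path.exists():
        log.warning("missing label file %s; treating as empty", path)
        return boxes
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            if len(parts) != 5:
                raise ValueError("expected 5 fields")
            if num_classes is not None and not 0 <= cid < num_classes:
                raise ValueError(f"class {cid} out of range")
        except (ValueError, IndexError) as e:
            log.error("malformed label %s:%d (%r): %s", path, ln, line, e)
            continue
        cx, cy, w, h = _clip_box(cx, cy, w, h)
        boxes.append((cid, cx, cy, w, h))
    return boxes


def read_yolo_dataset(root, num_classes: int | None = None) -> list[LabeledImage]:
    root = Path(root)
    img_dir, lbl_dir = root / "images", root / "labels"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    samples = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_EXTS:
            continue
        try:
            image = np.asarray(Image.open(img_path).convert("RGB"))
        except OSError as e:
            log.error("unreadable image %s: %s; skipped", img_path, e)
            continue
        boxes = parse_label_file(lbl_dir / (img_path.stem + ".txt"), num_classes)
        samples.append(LabeledImage(image, boxes, img_path.stem))
    return samples


def write_yolo_dataset(samples: list[LabeledImage], root):
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(root / "images" / f"{s.image_id}.png")
        lines = [f"{cid} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
                 for cid, cx, cy, w, h in s.boxes]
        (root / "labels" / f"{s.image_id}.txt").write_text("\n".join(lines) + "\n"
                                                           if lines else "")


def write_descriptor(root, num_classes: int, names: list | None = None):
    names = names or [f"class{i}" for i in range(num_classes)]
    # '.' keeps the descriptor relocatable; readers resolve it against the
    # descriptor's own directory
    (Path(root) / "data.yaml").write_text(yaml.safe_dump(
        {"path": ".", "nc": num_classes, "names": names}, sort_keys=False))


def split_dataset(samples: list[LabeledImage], seed: int = 0,
                  ratios=(0.8, 0.1, 0.1)) -> tuple:
    """Seeded shuffle split into (train, val, test) by the given ratios."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    n_train = int(round(ratios[0] * len(samples)))
    n_val = int(round(ratios[1] * len(samples)))
    take = lambda ii: [samples[i] for i in ii]
    return (take(idx[:n_train]), take(idx[n_train:n_train + n_val]),
            take(idx[n_train + n_val:]))


# ---------------------------------------------------------------------------
# letterbox
# ---------------------------------------------------------------------------

@dataclass
class LetterboxTransform:
    scale: float
    pad_x: float
    pad_y: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Source-pixel coords -> padded-image coords."""
        xy = np.asarray(xy, dtype=np.float64)
        out = xy * self.scale
        out[..., 0] += self.pad_x
        out[..., 1] += self.pad_y
        return out

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=np.float64).copy()
        xy[..., 0] -= self.pad_x
        xy[..., 1] -= self.pad_y
        return xy / self.scale


def letterbox(image: np.ndarray, target: tuple, fill: int = 114):
    """Aspect-preserving resize with symmetric grey padding."""
    th, tw = target
    if th % 32 or tw % 32:
        raise ValueError(f"letterbox target {target} must be divisible by 32")
    h, w = image.shape[:2]
    scale = min(th / h, tw / w)
    nh, nw = round(h * scale), round(w * scale)
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    out = np.full((th, tw, 3), fill, dtype=np.uint8)
    py, px = (th - nh) // 2, (tw - nw) // 2
    out[py:py + nh, px:px + nw] = resized
    return out, LetterboxTransform(scale=scale, pad_x=px, pad_y=py)


# ---------------------------------------------------------------------------
# mosaic augmentation
# ---------------------------------------------------------------------------

def mosaic_augment(samples: list[LabeledImage], output_size: int,
                   seed: int = 0) -> LabeledImage:
    """2x2 composite of four samples around a random centre point."""
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 source samples")
    rng = np.random.default_rng(seed)
    s = output_size
    cx = int(rng.uniform(0.3, 0.7) * s)
    cy = int(rng.uniform(0.3, 0.7) * s)
    canvas = np.full((s, s, 3), 114, dtype=np.uint8)
    quads = [(0, 0, cx, cy), (cx, 0, s, cy), (0, cy, cx, s), (cx, cy, s, s)]
    boxes = []
    for sample, (x1, y1, x2, y2) in zip(samples, quads):
        qw, qh = x2 - x1, y2 - y1
        if qw < 1 or qh < 1:
            continue
        img = np.asarray(Image.fromarray(sample.image).resize((qw, qh),
                                                              Image.BILINEAR))
        canvas[y1:y2, x1:x2] = img
        for cid, bcx, bcy, bw, bh in sample.boxes:
            # remap to canvas pixels, then clip to the quadrant
            px1 = x1 + (bcx - bw / 2) * qw
            py1 = y1 + (bcy - bh / 2) * qh
            px2 = x1 + (bcx + bw / 2) * qw
            py2 = y1 + (bcy + bh / 2) * qh
            px1, px2 = np.clip([px1, px2], x1, x2)
            py1, py2 = np.clip([py1, py2], y1, y2)
            if px2 - px1 >= 2 and py2 - py1 >= 2:
                boxes.append((cid, (px1 + px2) / 2 / s, (py1 + py2) / 2 / s,
                              (px2 - px1) / s, (py2 - py1) / s))
    return LabeledImage(canvas, boxes, f"mosaic{seed}")


# ---------------------------------------------------------------------------
# synthetic weed scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    num_classes: int = 3
    image_size: int = 256
    objects_per_image: tuple = (3, 6)
    scale_range: tuple = (0.08, 0.45)     # object diameter as image fraction
    occlusion_prob: float = 0.3
    small_target_frac: float = 0.25       # fraction of objects < 1% image area
    background_roughness: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for p in (self.occlusion_prob, self.small_target_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0 < self.scale_range[0] <= self.scale_range[1] <= 1):
            raise ValueError("scale_range must lie within (0, 1]")


# class-conditioned palettes: well-separated foliage hues + leaf shape per
# class, spanning dark green through yellow-green, red-tinged and glaucous
_BASE_COLORS = [
    (40, 150, 40), (185, 175, 55), (150, 60, 50), (55, 125, 145),
    (95, 205, 95), (25, 85, 30), (205, 125, 45), (130, 170, 170),
    (165, 100, 145), (70, 70, 20), (230, 205, 125), (30, 175, 120),
]


def _class_palette(cid: int):
    color = _BASE_COLORS[cid % len(_BASE_COLORS)]
    shape = ("rosette", "star", "ellipse")[cid % 3]
    n_leaves = 5 + (cid % 4) * 2
    return color, shape, n_leaves


def _soil_background(rng: np.random.Generator, size: int,
                     roughness: float) -> np.ndarray:
    """Multi-octave value noise in soil tones."""
    acc = np.zeros((size, size), dtype=np.float32)
    amp, total = 1.0, 0.0
    for cells in (4, 8, 16, 32):
        coarse = rng.standard_normal((cells + 1, cells + 1)).astype(np.float32)
        img = np.asarray(Image.fromarray(coarse, mode="F").resize(
            (size, size), Image.BILINEAR))
        acc += amp * img
        total += amp
        amp *= 0.55
    noise = acc / total * roughness
    base = np.array([120, 92, 70], dtype=np.float32)
    img = base[None, None] * (1.0 + noise[:, :, None])
    img += rng.normal(0, 4, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _draw_plant(draw: ImageDraw.ImageDraw, cx: float, cy: float, radius: float,
                cid: int, angle: float, jitter: np.ndarray):
    color, shape, n_leaves = _class_palette(cid)
    color = tuple(int(np.clip(c + j, 0, 255)) for c, j in zip(color, jitter))
    if shape == "ellipse":
        draw.ellipse([cx - radius, cy - 0.6 * radius,
                      cx + radius, cy + 0.6 * radius], fill=color + (255,))
        return
    inner = 0.38 if shape == "rosette" else 0.18
    pts = []
    for i in range(2 * n_leaves):
        r = radius if i % 2 == 0 else radius * inner
        a = angle + i * math.pi / n_leaves
        pts.append((cx + r * math.cos(a), cy + r * math.sin(a)))
    draw.polygon(pts, fill=color + (255,))


def generate_synthetic_scene(spec: SceneSpec, index: int = 0) -> LabeledImage:
    """Render one scene; (spec.seed, index) fully determines the output."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, index)))
    s = spec.image_size
    bg = _soil_background(rng, s, spec.background_roughness)
    canvas = Image.fromarray(bg).convert("RGBA")
    n_objects = int(rng.integers(spec.objects_per_image[0],
                                 spec.objects_per_image[1] + 1))
    placed_boxes: list[tuple] = []
    labels = []
    for _ in range(n_objects):
        cid = int(rng.integers(spec.num_classes))
        small = rng.random() < spec.small_target_frac
        ok = False
        for _attempt in range(40):
            if small:
                # tight cap keeps the silhouette's pixel area under 1%
                radius = rng.uniform(0.02, 0.045) * s
            else:
                radius = rng.uniform(*spec.scale_range) * s / 2
            cx = rng.uniform(radius, s - radius)
            cy = rng.uniform(radius, s - radius)
            cand = (cx - radius, cy - radius, cx + radius, cy + radius)
            overlap = any(_boxes_overlap(cand, b) for b in placed_boxes)
            if not overlap or rng.random() < spec.occlusion_prob:
                ok = True
                break
        if not ok:
            log.warning("placement failed after retries; scene has %d/%d objects",
                        len(labels), n_objects)
            continue
        placed_boxes.append(cand)
        overlay = Image.new("RGBA", (s, s), (0, 0, 0, 0))
        _draw_plant(ImageDraw.Draw(overlay), cx, cy, radius, cid,
                    rng.uniform(0, 2 * math.pi), rng.normal(0, 12, 3))
        mask = np.asarray(overlay)[:, :, 3] > 0
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            continue
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        canvas.alpha_composite(overlay)
        labels.append((cid, (x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                       (x2 - x1) / s, (y2 - y1) / s))
    image = np.asarray(canvas.convert("RGB"))
    return LabeledImage(image, labels, f"scene{spec.seed:06d}_{index:05d}")


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def generate_synthetic_dataset(spec: SceneSpec, n: int) -> list[LabeledImage]:
    return [generate_synthetic_scene(spec, i) for i in range(n)]
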