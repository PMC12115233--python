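"""Synthetic root-canal radiograph phantoms with YOLO-format labels.

The generator is a statistical stand-in for a clinical periapical-radiograph
dataset, not an X-ray physics simulator.  Each phantom is a 640×640 (by
default) grayscale image containing:

* a dark tissue background with Perlin-like low-frequency texture,
* one to three bright, curved, elongated bands emulating radiopaque
  root-canal filling material,
* zero to four small dark elliptical *voids* placed fully inside a canal
  band — the detection targets, annotated with tight boxes *before* blur,
* Gaussian blur and additive Gaussian noise applied last.

Void diameters default to 4–28 px at 640², the small-object regime the
detector is built for.  Everything is deterministic given ``(spec, seed)``.

The module also provides YOLO txt label I/O, the 80/20 dataset writer
(612 train / 156 validation at the default 768 images), mosaic augmentation
and letterbox resizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

__all__ = [
    "PhantomSpec",
    "Annotation",
    "LabeledImage",
    "easy_spec",
    "generate_phantom",
    "generate_dataset",
    "write_yolo_labels",
    "read_yolo_labels",
    "mosaic_augment",
    "letterbox_resize",
    "load_manifest",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of the phantom dataset.

    Defaults emulate the clinical-dataset regime: 768 images of 640×640 with
    few-pixel low-contrast voids inside bright canal bands, split 612/156.
    """

    n_images: int = 768
    image_size: int = 640
    canals: tuple = (1, 3)              # inclusive count range per image
    canal_width: tuple = (22.0, 48.0)   # px at image_size
    canal_brightness: tuple = (0.45, 0.62)
    voids: tuple = (0, 4)               # inclusive count range per image
    void_diameter: tuple = (4.0, 28.0)  # px
    void_contrast: tuple = (0.18, 0.4)
    background: float = 0.22
    texture_amp: float = 0.05
    blur_sigma: tuple = (0.6, 1.4)
    noise_sigma: float = 0.02
    train_count: int | None = 612       # split of the emulated clinical set
    val_count: int | None = 156

    def __post_init__(self):
        for name in ("canals", "canal_width", "canal_brightness", "voids",
                     "void_diameter", "void_contrast", "blur_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi or (name != "voids" and lo < 0):
                raise ValueError(f"{name} range must be ordered and positive, got {(lo, hi)}")
        if self.void_diameter[1] >= self.image_size:
            raise ValueError("void diameter must be smaller than the canal length")


def easy_spec(image_size: int = 160, n_images: int = 80) -> PhantomSpec:
    """A high-contrast, low-noise variant for desk-scale learning demos."""
    s = image_size / 640.0
    return PhantomSpec(
        n_images=n_images, image_size=image_size,
        canals=(1, 2), canal_width=(30.0 * 4 * s, 48.0 * 4 * s),
        canal_brightness=(0.55, 0.65),
        voids=(1, 2), void_diameter=(11.0, 24.0),
        void_contrast=(0.45, 0.55), blur_sigma=(0.3, 0.6),
        noise_sigma=0.005, train_count=None, val_count=None)


@dataclass(frozen=True)
class Annotation:
    """YOLO-convention annotation: normalized centre + size, class 0 = void."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError(f"annotation size must lie in (0, 1]: w={self.w}, h={self.h}")
        if not (0 <= self.cx <= 1 and 0 <= self.cy <= 1):
            raise ValueError(f"annotation centre outside the unit square: ({self.cx}, {self.cy})")

    def to_xyxy(self, size: float) -> np.ndarray:
        return np.array([(self.cx - self.w / 2) * size, (self.cy - self.h / 2) * size,
                         (self.cx + self.w / 2) * size, (self.cy + self.h / 2) * size])

    @classmethod
    def from_xyxy(cls, class_id: int, box, size: float) -> "Annotation":
        x1, y1, x2, y2 = (float(v) / size for v in box)
        return cls(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass
class LabeledImage:
    """A grayscale image in [0, 1] plus its annotations."""

    image: np.ndarray
    annotations: list
    identifier: str = ""
    canal_mask: np.ndarray | None = None
    transform: dict | None = None       # letterbox inverse map, when present


# ----------------------------------------------------------------- phantoms

def _low_freq_texture(rng, size: int, amp: float) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (8, 8))
    tex = zoom(coarse, size / 8.0, order=3)[:size, :size]
    return amp * tex / max(np.abs(tex).max(), 1e-9)


def _canal_centerline(rng, size: int) -> np.ndarray:
    """Random gently-curved near-vertical centreline x(y)."""
    x0 = rng.uniform(0.18, 0.82) * size
    tilt = rng.uniform(-0.25, 0.25)
    bend = rng.uniform(-0.35, 0.35)
    y = np.arange(size) / size
    return x0 + tilt * size * (y - 0.5) + bend * size * (y - 0.5) ** 2


def generate_phantom(spec: PhantomSpec, seed: int) -> LabeledImage:
    """Render one phantom; bit-deterministic given ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    size = spec.image_size
    img = np.full((size, size), spec.background, dtype=np.float64)
    img += _low_freq_texture(rng, size, spec.texture_amp)

    cols = np.arange(size, dtype=np.float64)
    n_canals = int(rng.integers(spec.canals[0], spec.canals[1] + 1))
    centerlines, widths = [], []
    canal_mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_canals):
        cl = _canal_centerline(rng, size)
        wdt = rng.uniform(*spec.canal_width)
        bright = rng.uniform(*spec.canal_brightness)
        d = np.abs(cols[None, :] - cl[:, None])      # distance to centreline
        edge = max(2.0, 0.15 * wdt)
        profile = np.clip((wdt / 2 - d) / edge + 0.5, 0.0, 1.0)
        img += bright * profile
        canal_mask |= d < (wdt / 2)
        centerlines.append(cl)
        widths.append(wdt)

    annotations: list[Annotation] = []
    n_voids = int(rng.integers(spec.voids[0], spec.voids[1] + 1))
    placed: list[np.ndarray] = []
    for _ in range(n_voids):
        for _attempt in range(25):
            k = int(rng.integers(0, n_canals))
            cl, wdt = centerlines[k], widths[k]
            dia_x = rng.uniform(*spec.void_diameter)
            dia_y = rng.uniform(*spec.void_diameter)
            # the void must fit inside the canal band laterally
            dia_x = min(dia_x, wdt - 4.0)
            if dia_x < spec.void_diameter[0] * 0.5:
                continue
            margin = int(max(dia_y, 8))
            cy = float(rng.uniform(margin, size - margin))
            cx = float(cl[int(cy)] + rng.uniform(-0.2, 0.2) * (wdt - dia_x))
            box = np.array([cx - dia_x / 2, cy - dia_y / 2,
                            cx + dia_x / 2, cy + dia_y / 2])
            if box[0] < 1 or box[1] < 1 or box[2] > size - 1 or box[3] > size - 1:
                continue
            if any(iou_boxes(box, b) > 0.0 for b in placed):
                continue
            yy, xx = np.mgrid[0:size, 0:size]
            ell = (((xx - cx) / (dia_x / 2)) ** 2 + ((yy - cy) / (dia_y / 2)) ** 2)
            soft = np.clip(1.0 - ell, 0.0, 1.0) ** 0.5
            img -= rng.uniform(*spec.void_contrast) * soft
            placed.append(box)
            annotations.append(Annotation.from_xyxy(0, box, size))
            break

    sigma = rng.uniform(*spec.blur_sigma)
    img = gaussian_filter(img, sigma)
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(image=img, annotations=annotations,
                        identifier=f"phantom_{seed:06d}", canal_mask=canal_mask)


def iou_boxes(a, b) -> float:
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


# ---------------------------------------------------------------- label I/O

def write_yolo_labels(annotations, path) -> None:
    """One ``class cx cy w h`` line per object, 6-decimal fixed format."""
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> list[Annotation]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed label on line {ln}: {line!r}")
        try:
            a = Annotation(int(parts[0]), *map(float, parts[1:]))
        except ValueError as e:
            raise ValueError(f"{path}: invalid label on line {ln}: {e}") from e
        out.append(a)
    return out


# ------------------------------------------------------------ dataset writer

def split_counts(n: int, spec: PhantomSpec | None = None) -> tuple[int, int]:
    """80/20 split; the default 768-image spec uses the published 612/156."""
    if spec is not None and spec.train_count is not None \
            and spec.train_count + (spec.val_count or 0) == n:
        return spec.train_count, spec.val_count
    val = n // 5
    return n - val, val


def generate_dataset(spec: PhantomSpec, out_dir, seed: int = 0) -> dict:
    """Write PNG images + YOLO labels in train/val subtrees and a YAML
    manifest; the split is image-level random under ``seed``."""
    out_dir = Path(out_dir)
    for sub in ("train/images", "train/labels", "val/images", "val/labels"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    n = spec.n_images
    n_train, n_val = split_counts(n, spec)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = set(perm[:n_train].tolist())
    counts = {"train": 0, "val": 0}
    for i in range(n):
        item = generate_phantom(spec, seed=seed * 1_000_003 % (2 ** 31) + i)
        sub = "train" if i in train_ids else "val"
        stem = f"{item.identifier}"
        Image.fromarray((item.image * 255).astype(np.uint8), mode="L").save(
            out_dir / sub / "images" / f"{stem}.png")
        write_yolo_labels(item.annotations, out_dir / sub / "labels" / f"{stem}.txt")
        counts[sub] += 1
    manifest = {
        "path": ".",
        "train": "train/images",
        "val": "val/images",
        "names": {0: "void"},
        "image_size": spec.image_size,
        "counts": counts,
        "split_seed": seed,
    }
    with open(out_dir / "dataset.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return manifest


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "dataset.yaml"
    with open(path) as f:
        manifest = yaml.safe_load(f)
    manifest["_root"] = str(path.parent)
    return manifest


def load_split(manifest: dict, split: str) -> list[LabeledImage]:
    """Read one split's images + labels back into memory."""
    root = Path(manifest["_root"])
    img_dir = root / manifest[split]
    items = []
    for img_path in sorted(img_dir.glob("*.png")):
        lab_path = img_dir.parent / "labels" / (img_path.stem + ".txt")
        img = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
        anns = read_yolo_labels(lab_path) if lab_path.exists() else []
        items.append(LabeledImage(image=img, annotations=anns,
                                  identifier=img_path.stem))
    return items


# ------------------------------------------------------------- augmentation

def mosaic_augment(items, out_size: int, seed: int = 0,
                   jitter: float = 0.2) -> LabeledImage:
    """Combine four labelled images around a jittered centre point.

    Each source image is resized (non-aspect-preserving) to its quadrant;
    annotations are remapped by the same affine map, clipped to the canvas,
    and dropped if their remapped area falls below 1 px².
    """
    if len(items) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(items)}")
    rng = np.random.default_rng(seed)
    cx = int(round(out_size * (0.5 + rng.uniform(-jitter, jitter))))
    cy = int(round(out_size * (0.5 + rng.uniform(-jitter, jitter))))
    cx = min(max(cx, 1), out_size - 1)
    cy = min(max(cy, 1), out_size - 1)
    quads = [(0, 0, cx, cy), (cx, 0, out_size - cx, cy),
             (0, cy, cx, out_size - cy), (cx, cy, out_size - cx, out_size - cy)]
    canvas = np.full((out_size, out_size), 0.5, dtype=np.float64)
    anns: list[Annotation] = []
    for item, (qx, qy, qw, qh) in zip(items, quads):
        h, w = item.image.shape[:2]
        pil = Image.fromarray(item.image.astype(np.float32), mode="F")
        patch = np.asarray(pil.resize((qw, qh), Image.BILINEAR), dtype=np.float64)
        canvas[qy:qy + qh, qx:qx + qw] = patch
        sx, sy = qw / w, qh / h
        for a in item.annotations:
            box = a.to_xyxy(1.0)      # normalized corners
            x1 = box[0] * w * sx + qx
            y1 = box[1] * h * sy + qy
            x2 = box[2] * w * sx + qx
            y2 = box[3] * h * sy + qy
            x1, x2 = max(x1, qx), min(x2, qx + qw)
            y1, y2 = max(y1, qy), min(y2, qy + qh)
            if (x2 - x1) * (y2 - y1) < 1.0:
                continue
            anns.append(Annotation.from_xyxy(a.class_id, (x1, y1, x2, y2), out_size))
    return LabeledImage(image=canvas, annotations=anns,
                        identifier="mosaic_" + "_".join(i.identifier for i in items))


def letterbox_resize(item: LabeledImage, target: int,
                     pad_value: float = 0.5) -> LabeledImage:
    """Aspect-preserving resize + symmetric gray padding to target×target.

    The affine map is recorded in ``transform`` as
    ``{"scale": s, "pad_x": px, "pad_y": py}``; a pixel (x, y) of the source
    maps to ``(x·s + px, y·s + py)``.
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    h, w = item.image.shape[:2]
    s = target / max(h, w)
    nh, nw = int(round(h * s)), int(round(w * s))
    pil = Image.fromarray(item.image.astype(np.float32), mode="F")
    resized = np.asarray(pil.resize((nw, nh), Image.BILINEAR), dtype=np.float64)
    py, px = (target - nh) // 2, (target - nw) // 2
    canvas = np.full((target, target), pad_value, dtype=np.float64)
    canvas[py:py + nh, px:px + nw] = resized
    anns = []
    for a in item.annotations:
        x1, y1, x2, y2 = a.to_xyxy(1.0)
        box = (x1 * w * (nw / w) + px, y1 * h * (nh / h) + py,
               x2 * w * (nw / w) + px, y2 * h * (nh / h) + py)
        anns.append(Annotation.from_xyxy(a.class_id, box, target))
    return LabeledImage(image=canvas, annotations=anns,
                        identifier=item.identifier,
                        transform={"scale_x": nw / w, "scale_y": nh / h,
                                   "pad_x": px, "pad_y": py})
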