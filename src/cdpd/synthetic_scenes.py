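"""Seeded synthetic pest scenes with boxes, masks, and weather corruptions.

Scenes emulate multi-object pest photographs at desk scale: K object
classes drawn as filled ellipses or convex polygons (class determines
colour and shape family) on a textured background, with pixel-accurate
bounding boxes and an integer instance/class mask.  A separate family of
parameterized photometric corruptions emulates deployment-time weather
and lighting shifts: brightness (BR), darkness (DA), Gaussian noise
(GN), fog (FO), rain streaks (RA), snow blobs (SN) and salt-and-pepper
noise (SP).  Corruptions never move pixels, so labels are invariant.

Boxes are 0-based, half-open ``(x_min, y_min, x_max, y_max)`` in pixel
units; the YOLO normalized centre format appears only at the file
boundary.  Generated images are quantized to the 8-bit grid (multiples
of 1/255) so a PNG write/read round-trip is bit-exact.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

__all__ = [
    "SceneSpec", "LabeledScene", "CorruptionSpec", "CORRUPTION_KINDS",
    "SEVERITY_MAPS", "SceneSizingError", "generate_scene", "generate_dataset",
    "read_dataset", "read_yolo_labels", "write_yolo_labels", "apply_corruption",
    "class_color",
]

# The seven-domain corruption sequence used in the continual experiment,
# in stream order: brightness, darkness, Gaussian noise, fog, rain, snow,
# salt-and-pepper.
CORRUPTION_KINDS = ("BR", "DA", "GN", "FO", "RA", "SN", "SP")

# Severity -> physical parameter maps.  Severity s is in [0,1]; every map
# is the identity at s=0.  Fixed constants (the corruption benchmark is
# defined BY these choices):
#   BR: multiplicative gain 1 + 0.8 s
#   DA: multiplicative gain 1 - 0.7 s
#   GN: additive Gaussian noise, sigma = 32 s on the 0-255 scale
#   FO: alpha-blend with a smooth white haze field, peak alpha 0.8 s
#   RA: round(40 s) bright diagonal streaks
#   SN: round(60 s) white blobs
#   SP: per-pixel flip probability 0.2 s (half salt, half pepper)
SEVERITY_MAPS = {
    "BR": lambda s: 1.0 + 0.8 * s,
    "DA": lambda s: 1.0 - 0.7 * s,
    "GN": lambda s: 32.0 * s / 255.0,
    "FO": lambda s: 0.8 * s,
    "RA": lambda s: int(round(40 * s)),
    "SN": lambda s: int(round(60 * s)),
    "SP": lambda s: 0.2 * s,
}


class SceneSizingError(ValueError):
    """Requested objects cannot fit into the image geometry."""


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a family of synthetic scenes (deterministic given seed)."""

    image_height: int = 48
    image_width: int = 48
    num_classes: int = 3
    objects_per_image: tuple[int, int] = (1, 3)
    object_scale: tuple[float, float] = (0.12, 0.25)
    background_texture: str = "speckle"
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        lo, hi = self.objects_per_image
        if lo < 0 or hi < lo:
            raise ValueError("objects_per_image must satisfy 0 <= lo <= hi")
        slo, shi = self.object_scale
        if not (0 < slo <= shi):
            raise ValueError("object_scale must be positive and ordered")
        if shi >= 0.5:
            raise SceneSizingError(
                f"object_scale upper bound {shi} does not fit in the image "
                "(diameter would reach or exceed the image side)")
        if self.background_texture not in ("flat", "gradient", "speckle"):
            raise ValueError(f"unknown background_texture {self.background_texture!r}")
        if min(self.image_height, self.image_width) < 8:
            raise SceneSizingError("image must be at least 8x8 pixels")


@dataclass
class LabeledScene:
    """One image with its boxes, class ids and pixel mask."""

    image: np.ndarray                       # (H, W, 3) float64 in [0, 1]
    boxes: np.ndarray                       # (M, 4) float64 half-open pixel boxes
    class_ids: np.ndarray                   # (M,) int
    mask: np.ndarray                        # (H, W) int, 0 background, c+1 object

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64).reshape(-1)
        self.mask = np.asarray(self.mask, dtype=np.int64)
        h, w = self.mask.shape
        if self.image.shape != (h, w, 3):
            raise ValueError("image and mask shapes disagree")
        if len(self.boxes) != len(self.class_ids):
            raise ValueError("boxes and class_ids length mismatch")
        for (x0, y0, x1, y1) in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"invalid box ({x0},{y0},{x1},{y1}) for {w}x{h}")

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    def copy_with_image(self, image: np.ndarray) -> "LabeledScene":
        return LabeledScene(image=image, boxes=self.boxes.copy(),
                            class_ids=self.class_ids.copy(), mask=self.mask.copy())


@dataclass(frozen=True)
class CorruptionSpec:
    kind: str
    severity: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind {self.kind!r}; "
                             f"expected one of {CORRUPTION_KINDS}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def class_color(class_id: int, num_classes: int) -> np.ndarray:
    """Evenly hue-spaced, saturated colour for a class."""
    hue = (class_id / num_classes) % 1.0
    return np.asarray(colorsys.hsv_to_rgb(hue, 0.85, 0.75))


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_height, spec.image_width
    base = rng.uniform(0.55, 0.8, size=3)  # light vegetation-ish tone
    if spec.background_texture == "flat":
        img = np.broadcast_to(base, (h, w, 3)).copy()
    elif spec.background_texture == "gradient":
        other = rng.uniform(0.35, 0.6, size=3)
        t = np.linspace(0.0, 1.0, h)[:, None, None]
        img = (1 - t) * base + t * other
        img = np.broadcast_to(img, (h, w, 3)).copy()
    else:  # speckle
        img = base + rng.normal(0.0, 0.04, size=(h, w, 3))
    return np.clip(img, 0.0, 1.0)


def _draw_object(img, mask, class_id, cx, cy, rx, ry, num_classes, rng):
    """Fill an ellipse (even class) or convex polygon (odd class); return box."""
    h, w = mask.shape
    if class_id % 2 == 0:
        rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(h, w))
    else:
        n_vertices = 5 + class_id % 3
        # evenly spaced angles with bounded jitter: guarantees a fat,
        # simply connected star polygon (no slivers)
        base = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        angles = base + rng.uniform(-0.35, 0.35, n_vertices) * (2 * np.pi / n_vertices)
        radii = rng.uniform(0.7, 1.0, n_vertices)
        ys = cy + radii * ry * np.sin(angles)
        xs = cx + radii * rx * np.cos(angles)
        rr, cc = skdraw.polygon(ys, xs, shape=(h, w))
    if rr.size == 0:
        return None
    color = class_color(class_id, num_classes)
    shade = 1.0 + rng.normal(0.0, 0.05, size=rr.size)
    img[rr, cc] = np.clip(color[None, :] * shade[:, None], 0.0, 1.0)
    mask[rr, cc] = class_id + 1
    # tight box from the actually drawn pixels (half-open)
    return (float(cc.min()), float(rr.min()), float(cc.max() + 1), float(rr.max() + 1))


def generate_scene(spec: SceneSpec, index: int) -> LabeledScene:
    """Deterministically generate scene ``index`` of the family ``spec``.

    Objects are placed without overlap (a 2-px guard band) so each object
    is one connected mask component and every mask pixel lies inside its
    own box.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(int(index),)))
    h, w = spec.image_height, spec.image_width
    img = _background(spec, rng)
    mask = np.zeros((h, w), dtype=np.int64)

    n_objects = int(rng.integers(spec.objects_per_image[0],
                                 spec.objects_per_image[1] + 1))
    side = min(h, w)
    slo, shi = spec.object_scale
    boxes, class_ids = [], []
    # whole-scene restarts: a large early object can block later ones, so
    # on retry redraw everything, biasing scales toward the lower bound
    for restart in range(12):
        img_try = img.copy()
        mask_try = np.zeros((h, w), dtype=np.int64)
        boxes, class_ids = [], []
        occupied: list[tuple[float, float, float, float]] = []
        hi = shi if restart < 4 else slo + (shi - slo) * 0.5 ** (restart - 3)
        ok = True
        for _ in range(n_objects):
            placed = False
            for _attempt in range(200):
                scale = rng.uniform(slo, hi)
                rx = max(2.0, scale * side)
                ry = max(2.0, scale * side * rng.uniform(0.6, 1.0))
                if 2 * rx + 4 >= w or 2 * ry + 4 >= h:
                    continue
                cx = rng.uniform(rx + 1, w - rx - 2)
                cy = rng.uniform(ry + 1, h - ry - 2)
                cand = (cx - rx - 2, cy - ry - 2, cx + rx + 2, cy + ry + 2)
                if any(cand[0] < o[2] and o[0] < cand[2] and
                       cand[1] < o[3] and o[1] < cand[3] for o in occupied):
                    continue
                class_id = int(rng.integers(0, spec.num_classes))
                box = _draw_object(img_try, mask_try, class_id, cx, cy, rx, ry,
                                   spec.num_classes, rng)
                if box is None:
                    continue
                boxes.append(box)
                class_ids.append(class_id)
                occupied.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            img, mask = img_try, mask_try
            break
    else:
        raise SceneSizingError(
            f"could not place {n_objects} non-overlapping objects of scale "
            f"{spec.object_scale} in a {w}x{h} image")

    img = np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0  # 8-bit grid
    return LabeledScene(image=img,
                        boxes=np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
                        class_ids=np.asarray(class_ids, dtype=np.int64),
                        mask=mask)


# ---------------------------------------------------------------------------
# dataset I/O: PNG images + masks, YOLO-txt and COCO-style JSON labels
# ---------------------------------------------------------------------------

def _box_to_yolo(box, w, h):
    x0, y0, x1, y1 = box
    return ((x0 + x1) / 2 / w, (y0 + y1) / 2 / h, (x1 - x0) / w, (y1 - y0) / h)


def _yolo_to_box(cx, cy, bw, bh, w, h):
    return ((cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h)


def write_yolo_labels(path, scene: LabeledScene):
    lines = []
    for box, cid in zip(scene.boxes, scene.class_ids):
        cx, cy, bw, bh = _box_to_yolo(box, scene.width, scene.height)
        lines.append(f"{int(cid)} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, width: int, height: int):
    """Read YOLO-format labels back into pixel boxes and class ids."""
    boxes, class_ids = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        class_ids.append(int(parts[0]))
        cx, cy, bw, bh = map(float, parts[1:5])
        boxes.append(_yolo_to_box(cx, cy, bw, bh, width, height))
    return (np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
            np.asarray(class_ids, dtype=np.int64))


def generate_dataset(spec: SceneSpec, n: int, out_dir) -> list[LabeledScene]:
    """Generate ``n`` scenes and write PNG images, YOLO-txt labels,
    a COCO-style JSON, and mask PNGs under ``out_dir``."""
    from pathlib import Path

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    for sub in ("images", "labels", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    scenes = [generate_scene(spec, i) for i in range(n)]
    coco = {"images": [], "annotations": [],
            "categories": [{"id": c, "name": f"pest_{c}"}
                           for c in range(spec.num_classes)]}
    ann_id = 0
    for i, scene in enumerate(scenes):
        stem = f"scene_{i:05d}"
        iio.imwrite(out / "images" / f"{stem}.png",
                    np.round(scene.image * 255.0).astype(np.uint8))
        iio.imwrite(out / "masks" / f"{stem}.png",
                    scene.mask.astype(np.uint8))
        write_yolo_labels(out / "labels" / f"{stem}.txt", scene)
        coco["images"].append({"id": i, "file_name": f"images/{stem}.png",
                               "height": scene.height, "width": scene.width})
        for box, cid in zip(scene.boxes, scene.class_ids):
            x0, y0, x1, y1 = box
            coco["annotations"].append({
                "id": ann_id, "image_id": i, "category_id": int(cid),
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0})
            ann_id += 1
    (out / "coco.json").write_text(json.dumps(coco, indent=1))
    manifest = {"n_scenes": n, "num_classes": spec.num_classes,
                "image_height": spec.image_height, "image_width": spec.image_width,
                "seed": spec.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return scenes


def read_dataset(out_dir) -> list[LabeledScene]:
    """Read a dataset written by :func:`generate_dataset` (COCO boxes, exact)."""
    from pathlib import Path

    out = Path(out_dir)
    coco = json.loads((out / "coco.json").read_text())
    by_image: dict[int, list] = {img["id"]: [] for img in coco["images"]}
    for ann in coco["annotations"]:
        by_image[ann["image_id"]].append(ann)
    scenes = []
    for img_info in sorted(coco["images"], key=lambda d: d["id"]):
        image = iio.imread(out / img_info["file_name"]).astype(np.float64) / 255.0
        stem = Path(img_info["file_name"]).stem
        mask = iio.imread(out / "masks" / f"{stem}.png").astype(np.int64)
        anns = by_image[img_info["id"]]
        boxes = np.asarray([[a["bbox"][0], a["bbox"][1],
                             a["bbox"][0] + a["bbox"][2],
                             a["bbox"][1] + a["bbox"][3]] for a in anns],
                           dtype=np.float64).reshape(-1, 4)
        class_ids = np.asarray([a["category_id"] for a in anns], dtype=np.int64)
        scenes.append(LabeledScene(image=image, boxes=boxes,
                                   class_ids=class_ids, mask=mask))
    return scenes


# ---------------------------------------------------------------------------
# photometric corruptions
# ---------------------------------------------------------------------------

def _haze_field(h, w, rng) -> np.ndarray:
    """Smooth random field in [0, 1] (low-res noise, bilinear upsample)."""
    coarse = rng.uniform(0.0, 1.0, size=(6, 6))
    field = ndimage.zoom(coarse, (h / 6, w / 6), order=1, grid_mode=True,
                         mode="nearest")
    field = field[:h, :w]
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo) if hi > lo else np.full((h, w), 0.5)


def apply_corruption(scene: LabeledScene, c: CorruptionSpec) -> LabeledScene:
    """Photometric corruption of the image; boxes, class ids and mask are
    returned unchanged.  Deterministic in (scene, spec)."""
    img = scene.image
    h, w = scene.height, scene.width
    if c.severity == 0.0:
        return scene.copy_with_image(img.copy())
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=c.seed, spawn_key=(CORRUPTION_KINDS.index(c.kind),)))

    if c.kind == "BR":
        out = img * SEVERITY_MAPS["BR"](c.severity)
    elif c.kind == "DA":
        out = img * SEVERITY_MAPS["DA"](c.severity)
    elif c.kind == "GN":
        sigma = SEVERITY_MAPS["GN"](c.severity)
        out = img + rng.normal(0.0, sigma, size=img.shape)
    elif c.kind == "FO":
        alpha = SEVERITY_MAPS["FO"](c.severity) * _haze_field(h, w, rng)
        out = (1.0 - alpha[..., None]) * img + alpha[..., None]
    elif c.kind == "RA":
        out = img.copy()
        for _ in range(SEVERITY_MAPS["RA"](c.severity)):
            x0 = rng.integers(0, w)
            y0 = rng.integers(0, h)
            length = int(rng.integers(h // 4, h))
            dx = int(round(length * 0.35))
            rr, cc = skdraw.line(int(y0), int(x0),
                                 min(int(y0) + length, h - 1),
                                 min(int(x0) + dx, w - 1))
            out[rr, cc] = 0.35 * out[rr, cc] + 0.65
    elif c.kind == "SN":
        out = img.copy()
        for _ in range(SEVERITY_MAPS["SN"](c.severity)):
            cy = rng.integers(0, h)
            cx = rng.integers(0, w)
            r = int(rng.integers(1, 3))
            rr, cc = skdraw.disk((int(cy), int(cx)), r, shape=(h, w))
            out[rr, cc] = 0.2 * out[rr, cc] + 0.8
    elif c.kind == "SP":
        p = SEVERITY_MAPS["SP"](c.severity)
        out = img.copy()
        u = rng.uniform(size=(h, w))
        out[u < p / 2] = 0.0
        out[u > 1.0 - p / 2] = 1.0
    else:  # pragma: no cover - guarded by CorruptionSpec
        raise ValueError(f"unknown corruption kind {c.kind!r}")

    return scene.copy_with_image(np.clip(out, 0.0, 1.0))
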