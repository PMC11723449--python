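"""COCO-format detection I/O and the training-time image geometry:
letterboxing, mosaic composition, and random zoom/translation.

Boxes are kept as 0-based half-open pixel (x0, y0, x1, y1) arrays inside the
package; the COCO xywh convention is converted at this boundary only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

PAD_VALUE = 114  # conventional letterbox grey


class CocoFormatError(ValueError):
    pass


@dataclass
class AnnotatedImage:
    image_id: int
    size: tuple[int, int]                 # (h, w)
    boxes: np.ndarray                     # (n, 4) xyxy float32
    categories: np.ndarray                # (n,) contiguous ids in [0, C)
    pixels: np.ndarray | None = None      # (h, w, 3) uint8, may be lazy
    file_name: str | None = None

    def load_pixels(self, root: Path | None = None) -> np.ndarray:
        if self.pixels is None:
            if self.file_name is None:
                raise ValueError(f"image {self.image_id} has no pixels or file")
            path = Path(root or ".") / self.file_name
            self.pixels = np.asarray(Image.open(path).convert("RGB"))
        return self.pixels

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)


@dataclass
class Dataset:
    images: list[AnnotatedImage]
    category_names: list[str]
    category_id_map: dict[int, int] = field(default_factory=dict)  # original -> contiguous
    root: Path | None = None

    def __len__(self):
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def annotations(self):
        """Iterate (category, box_w, box_h) over every annotation — the input
        the class pixel statistics are accumulated from."""
        for img in self.images:
            for cat, (x0, y0, x1, y1) in zip(img.categories, img.boxes):
                yield int(cat), float(x1 - x0), float(y1 - y0)


def load_coco(json_path, images_root=None) -> Dataset:
    """Load a COCO detection JSON.  Category ids are remapped to a contiguous
    [0, C) range (ordered by original id); every annotation is linked to its
    image and malformed records raise `CocoFormatError` naming the record."""
    json_path = Path(json_path)
    with open(json_path) as f:
        doc = json.load(f)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise CocoFormatError(f"missing top-level key {key!r}")
    cats = sorted(doc["categories"], key=lambda c: c["id"])
    id_map = {c["id"]: i for i, c in enumerate(cats)}
    names = [str(c.get("name", c["id"])) for c in cats]
    by_image: dict[int, list] = {}
    images: dict[int, AnnotatedImage] = {}
    for rec in doc["images"]:
        try:
            images[rec["id"]] = AnnotatedImage(
                image_id=rec["id"], size=(rec["height"], rec["width"]),
                boxes=np.zeros((0, 4), np.float32),
                categories=np.zeros(0, np.int64),
                file_name=rec.get("file_name"))
        except KeyError as e:
            raise CocoFormatError(f"image record {rec.get('id')} missing {e}") from e
        by_image[rec["id"]] = []
    for ann in doc["annotations"]:
        img_id = ann.get("image_id")
        if img_id not in images:
            raise CocoFormatError(f"annotation {ann.get('id')} references "
                                  f"unknown image {img_id}")
        if ann.get("category_id") not in id_map:
            raise CocoFormatError(f"annotation {ann.get('id')} references "
                                  f"unknown category {ann.get('category_id')}")
        x, y, w, h = ann["bbox"]
        by_image[img_id].append((id_map[ann["category_id"]], (x, y, x + w, y + h)))
    for img_id, anns in by_image.items():
        if anns:
            images[img_id].categories = np.array([a[0] for a in anns], np.int64)
            images[img_id].boxes = np.array([a[1] for a in anns], np.float32)
    root = Path(images_root) if images_root else json_path.parent
    return Dataset(images=list(images.values()), category_names=names,
                   category_id_map=id_map, root=root)


def save_coco(dataset: Dataset, json_path) -> None:
    """Write a dataset back to COCO detection JSON (inverse of `load_coco`)."""
    inv = {v: k for k, v in dataset.category_id_map.items()} or \
        {i: i for i in range(dataset.n_categories)}
    doc = {"images": [], "annotations": [], "categories": [
        {"id": inv[i], "name": n} for i, n in enumerate(dataset.category_names)]}
    ann_id = 1
    for img in dataset.images:
        doc["images"].append({"id": img.image_id, "height": img.size[0],
                              "width": img.size[1], "file_name": img.file_name})
        for cat, (x0, y0, x1, y1) in zip(img.categories, img.boxes):
            doc["annotations"].append({
                "id": ann_id, "image_id": img.image_id,
                "category_id": inv[int(cat)],
                "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                "area": float((x1 - x0) * (y1 - y0)), "iscrowd": 0})
            ann_id += 1
    with open(json_path, "w") as f:
        json.dump(doc, f)


def save_results(detections_per_image, image_ids, category_id_map, path) -> None:
    """Write predictions as COCO results JSON (image_id, category_id, xywh, score)."""
    inv = {v: k for k, v in category_id_map.items()}
    out = []
    for img_id, dets in zip(image_ids, detections_per_image):
        for d in dets:
            x0, y0, x1, y1 = d.box
            out.append({"image_id": img_id,
                        "category_id": inv.get(d.category, d.category),
                        "bbox": [x0, y0, x1 - x0, y1 - y0],
                        "score": d.confidence})
    with open(path, "w") as f:
        json.dump(out, f)


def load_results(path, category_id_map) -> dict:
    """COCO results JSON -> {image_id: [(category, score, xyxy box), ...]}."""
    with open(path) as f:
        rows = json.load(f)
    per_image: dict = {}
    for r in rows:
        x, y, w, h = r["bbox"]
        per_image.setdefault(r["image_id"], []).append(
            (category_id_map[r["category_id"]], r["score"], (x, y, x + w, y + h)))
    return per_image


# -- geometry -------------------------------------------------------------

@dataclass(frozen=True)
class LetterboxRecord:
    scale: float
    pad_x: int
    pad_y: int
    original_size: tuple[int, int]  # (h, w)


def letterbox(image: np.ndarray, boxes: np.ndarray, target: tuple[int, int]):
    """Aspect-preserving resize with symmetric grey padding to `target` (h, w).

    Returns (image, boxes, record); `inverse_letterbox` undoes the box
    transform to within 0.5 px.
    """
    th, tw = target
    if th < 32 or tw < 32:
        raise ValueError("target dims must be >= 32")
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("zero-sized image")
    scale = min(th / h, tw / w)
    nh, nw = round(h * scale), round(w * scale)
    resized = np.asarray(
        Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    pad_y, pad_x = (th - nh) // 2, (tw - nw) // 2
    out = np.full((th, tw, 3), PAD_VALUE, dtype=image.dtype)
    out[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    new_boxes = boxes.astype(np.float32).copy()
    if len(new_boxes):
        new_boxes[:, [0, 2]] = new_boxes[:, [0, 2]] * scale + pad_x
        new_boxes[:, [1, 3]] = new_boxes[:, [1, 3]] * scale + pad_y
    return out, new_boxes, LetterboxRecord(scale, pad_x, pad_y, (h, w))


def inverse_letterbox(boxes: np.ndarray, record: LetterboxRecord) -> np.ndarray:
    out = np.asarray(boxes, np.float32).copy()
    if len(out):
        out[:, [0, 2]] = (out[:, [0, 2]] - record.pad_x) / record.scale
        out[:, [1, 3]] = (out[:, [1, 3]] - record.pad_y) / record.scale
    return out


def _clip_boxes(boxes, cats, h, w, min_area=1.0):
    if len(boxes) == 0:
        return boxes.reshape(0, 4), cats
    boxes = boxes.copy()
    boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, w)
    boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, h)
    area = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    keep = area >= min_area
    return boxes[keep], cats[keep]


def mosaic_augment(images, rng_seed: int | np.random.Generator,
                   out_size: tuple[int, int] | None = None) -> AnnotatedImage:
    """Compose four annotated images into one 2x2 mosaic around a random
    centre; boxes are shifted, clipped, and dropped below 1 px^2."""
    images = list(images)
    if len(images) != 4:
        raise ValueError(f"mosaic requires exactly 4 images, got {len(images)}")
    rng = rng_seed if hasattr(rng_seed, "uniform") else np.random.default_rng(rng_seed)
    base_h, base_w = images[0].size if out_size is None else out_size
    H, W = base_h * 2, base_w * 2
    canvas = np.full((H, W, 3), PAD_VALUE, dtype=np.uint8)
    xc = int(rng.uniform(0.5 * base_w, 1.5 * base_w))
    yc = int(rng.uniform(0.5 * base_h, 1.5 * base_h))
    all_boxes, all_cats = [], []
    corners = [(0, 0, xc, yc), (xc, 0, W, yc), (0, yc, xc, H), (xc, yc, W, H)]
    for img, (x0, y0, x1, y1) in zip(images, corners):
        px = img.load_pixels()
        h, w = px.shape[:2]
        cw, ch = x1 - x0, y1 - y0
        sx, sy = max(w - cw, 0), max(h - ch, 0)  # crop from bottom-right anchor
        crop = px[sy:sy + ch, sx:sx + cw]
        canvas[y1 - crop.shape[0]:y1, x1 - crop.shape[1]:x1] = crop
        dx, dy = x1 - crop.shape[1] - sx, y1 - crop.shape[0] - sy
        if img.n_boxes:
            b = img.boxes.copy()
            b[:, [0, 2]] += dx
            b[:, [1, 3]] += dy
            all_boxes.append(b)
            all_cats.append(img.categories)
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4), np.float32)
    cats = np.concatenate(all_cats) if all_cats else np.zeros(0, np.int64)
    boxes, cats = _clip_boxes(boxes, cats, H, W)
    return AnnotatedImage(image_id=-1, size=(H, W), boxes=boxes,
                          categories=cats, pixels=canvas)


def random_affine(image: np.ndarray, boxes: np.ndarray,
                  zoom_range=(0.5, 1.5), translate_range=0.1,
                  rng_seed: int | np.random.Generator = 0,
                  categories: np.ndarray | None = None):
    """Random zoom about the image centre plus random panning; boxes follow
    the same affine map as the pixels and degenerate boxes are dropped."""
    lo, hi = zoom_range
    if not (0 < lo <= hi):
        raise ValueError("zoom_range must be within (0, inf) with lo <= hi")
    if not 0 <= translate_range < 1:
        raise ValueError("translate_range must lie in [0, 1)")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    h, w = image.shape[:2]
    s = rng.uniform(lo, hi)
    tx = rng.uniform(-translate_range, translate_range) * w
    ty = rng.uniform(-translate_range, translate_range) * h
    # forward map: p' = s * (p - c) + c + t
    cx, cy = w / 2, h / 2
    a, b0 = 1 / s, cx - (cx + tx) / s
    d, e0 = 1 / s, cy - (cy + ty) / s
    warped = np.asarray(Image.fromarray(image).transform(
        (w, h), Image.AFFINE, (a, 0.0, b0, 0.0, d, e0),
        resample=Image.BILINEAR, fillcolor=(PAD_VALUE,) * 3))
    nb = np.asarray(boxes, np.float32).copy()
    cats = (np.asarray(categories) if categories is not None
            else np.zeros(len(nb), np.int64))
    if len(nb):
        nb[:, [0, 2]] = s * (nb[:, [0, 2]] - cx) + cx + tx
        nb[:, [1, 3]] = s * (nb[:, [1, 3]] - cy) + cy + ty
        nb, cats = _clip_boxes(nb, cats, h, w)
    if categories is None:
        return warped, nb
    return warped, nb, cats
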