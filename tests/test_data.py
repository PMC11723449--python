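"""COCO I/O, letterbox geometry, mosaic and affine augmentation."""

import json

import numpy as np
import pytest

from bsdnet.data import (AnnotatedImage, CocoFormatError, inverse_letterbox,
                         letterbox, load_coco, mosaic_augment, random_affine,
                         save_coco)


def coco_doc():
    return {
        "images": [
            {"id": 10, "height": 48, "width": 64, "file_name": "a.png"},
            {"id": 11, "height": 48, "width": 64, "file_name": "b.png"},
        ],
        "annotations": [
            {"id": 1, "image_id": 10, "category_id": 7, "bbox": [2, 3, 10, 8]},
            {"id": 2, "image_id": 10, "category_id": 3, "bbox": [20, 5, 6, 6]},
            {"id": 3, "image_id": 11, "category_id": 7, "bbox": [1, 1, 30, 20]},
        ],
        "categories": [{"id": 7, "name": "crane"}, {"id": 3, "name": "egret"}],
    }


def test_load_coco_counts_and_remapping(tmp_path):
    p = tmp_path / "ann.json"
    p.write_text(json.dumps(coco_doc()))
    ds = load_coco(p)
    assert len(ds) == 2 and ds.n_categories == 2
    assert sum(img.n_boxes for img in ds) == 3
    # ids remapped to contiguous [0, C) ordered by original id: 3 -> 0, 7 -> 1
    assert ds.category_id_map == {3: 0, 7: 1}
    assert ds.images[0].categories.tolist() == [1, 0]
    # xywh converted to xyxy
    assert ds.images[0].boxes[0].tolist() == [2, 3, 12, 11]


def test_load_coco_rejects_malformed_documents(tmp_path):
    doc = coco_doc()
    del doc["categories"]
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(CocoFormatError):
        load_coco(p)
    doc = coco_doc()
    doc["annotations"][0]["image_id"] = 999
    p.write_text(json.dumps(doc))
    with pytest.raises(CocoFormatError, match="999"):
        load_coco(p)


def test_coco_round_trip_is_identity_on_boxes_and_labels(tmp_path):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    p1.write_text(json.dumps(coco_doc()))
    ds1 = load_coco(p1)
    save_coco(ds1, p2)
    ds2 = load_coco(p2)
    for i1, i2 in zip(ds1.images, ds2.images):
        assert np.allclose(i1.boxes, i2.boxes)
        assert np.array_equal(i1.categories, i2.categories)
    assert ds1.category_id_map == ds2.category_id_map


def test_letterbox_geometry_oracle():
    """1280x720 -> 640x640: scale 0.5, resized 640x360, pad 140 top/bottom;
    box [0,0,100,100] maps to [0,140,50,190]."""
    img = np.zeros((720, 1280, 3), np.uint8)
    boxes = np.array([[0, 0, 100, 100]], np.float32)
    out, nb, rec = letterbox(img, boxes, (640, 640))
    assert out.shape == (640, 640, 3)
    assert rec.scale == 0.5 and rec.pad_x == 0 and rec.pad_y == 140
    assert nb[0].tolist() == [0, 140, 50, 190]
    back = inverse_letterbox(nb, rec)
    assert np.abs(back - boxes).max() <= 0.5


def test_letterbox_identity_on_square_target_size():
    img = np.full((64, 64, 3), 9, np.uint8)
    boxes = np.array([[4, 4, 20, 20]], np.float32)
    out, nb, rec = letterbox(img, boxes, (64, 64))
    assert rec.scale == 1.0 and rec.pad_x == 0 and rec.pad_y == 0
    assert np.array_equal(out, img) and np.array_equal(nb, boxes)
    with pytest.raises(ValueError):
        letterbox(np.zeros((0, 10, 3), np.uint8), boxes, (64, 64))


class _MidpointRng:
    """Stub generator whose uniform() returns the interval midpoint."""

    def uniform(self, lo, hi, *a, **k):
        return (lo + hi) / 2


def single_box_image(i=0):
    px = np.full((32, 32, 3), 50, np.uint8)
    px[8:16, 8:24] = 200
    return AnnotatedImage(image_id=i, size=(32, 32),
                          boxes=np.array([[8, 8, 24, 16]], np.float32),
                          categories=np.array([0]), pixels=px)


def test_mosaic_with_centre_at_midpoint_keeps_one_box_per_quadrant():
    imgs = [single_box_image(i) for i in range(4)]
    out = mosaic_augment(imgs, _MidpointRng())
    assert out.size == (64, 64)
    assert out.n_boxes == 4
    quadrants = set()
    for x0, y0, x1, y1 in out.boxes:
        quadrants.add((x0 >= 32, y0 >= 32))
    assert len(quadrants) == 4
    with pytest.raises(ValueError):
        mosaic_augment(imgs[:3], 0)


def test_mosaic_clipping_only_removes_boxes_and_is_seeded():
    rng = np.random.default_rng(0)
    imgs = [single_box_image(i) for i in range(4)]
    for seed in range(5):
        out = mosaic_augment(imgs, seed)
        assert out.n_boxes <= sum(i.n_boxes for i in imgs)
        again = mosaic_augment(imgs, seed)
        assert np.array_equal(out.pixels, again.pixels)
        assert np.array_equal(out.boxes, again.boxes)


def test_affine_identity_and_zoom():
    img = single_box_image().pixels
    boxes = np.array([[8, 8, 24, 16]], np.float32)
    out, nb = random_affine(img, boxes, zoom_range=(1.0, 1.0),
                            translate_range=0.0, rng_seed=0)
    assert np.array_equal(nb, boxes)
    # zoom 2 about the centre doubles side lengths (before clipping)
    _, nb2 = random_affine(img, np.array([[12, 12, 20, 18]], np.float32),
                           zoom_range=(2.0, 2.0), translate_range=0.0,
                           rng_seed=0)
    assert np.allclose(nb2[0, 2] - nb2[0, 0], 16)
    assert np.allclose(nb2[0, 3] - nb2[0, 1], 12)
    with pytest.raises(ValueError):
        random_affine(img, boxes, zoom_range=(0, 1), rng_seed=0)
    with pytest.raises(ValueError):
        random_affine(img, boxes, translate_range=1.5, rng_seed=0)


def test_affine_is_reproducible_bitwise():
    img = single_box_image().pixels
    boxes = np.array([[8, 8, 24, 16]], np.float32)
    a_img, a_b = random_affine(img, boxes, rng_seed=9)
    b_img, b_b = random_affine(img, boxes, rng_seed=9)
    assert np.array_equal(a_img, b_img) and np.array_equal(a_b, b_b)


def test_fuzzed_augmentations_emit_valid_boxes():
    rng = np.random.default_rng(123)
    imgs = [single_box_image(i) for i in range(4)]
    for trial in range(200):
        if trial % 2:
            out = mosaic_augment(imgs, int(rng.integers(0, 2 ** 31)))
            boxes, (h, w) = out.boxes, out.size
        else:
            _, boxes = random_affine(imgs[0].pixels, imgs[0].boxes,
                                     rng_seed=int(rng.integers(0, 2 ** 31)))
            h = w = 32
        for x0, y0, x1, y1 in boxes:
            assert x1 > x0 and y1 > y0
            assert 0 <= x0 and x1 <= w and 0 <= y0 and y1 <= h
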