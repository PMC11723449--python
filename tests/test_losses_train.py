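"""Target assignment, the composite loss, and the training loop."""

import math

import numpy as np
import pytest

from bsdnet import pbm as pbm_module
from bsdnet.autograd import Tensor
from bsdnet.losses import assign_targets, compute_loss
from bsdnet.model import (REG_MAX, ModelConfig, PbmConfig, build_model,
                          predict)
from bsdnet.pbm import compute_class_pixel_stats, sample_variation
from bsdnet.train import TrainConfig, fit, validation_map50

GRIDS = [(8, 8), (4, 4), (2, 2)]
STRIDES = (8, 16, 32)


def test_single_centred_box_gets_a_positive_cell():
    gt = (np.array([[24.0, 24.0, 40.0, 40.0]]), np.array([1]))
    a = assign_targets([gt], GRIDS, STRIDES, 3)
    assert a.n_pos == 1
    sa = a.scales[0]  # 16 px box fits the stride-8 range
    assert sa.pos_cells.tolist() == [4 * 8 + 4]
    assert sa.target_cat.tolist() == [1]
    # the box centre (32, 32) falls in the cell spanning [32, 40): cell
    # centre 36, so distances are (36-24, 36-24, 40-36, 40-36) / 8
    assert np.allclose(sa.target_ltrb, [[1.5, 1.5, 0.5, 0.5]])


def test_empty_ground_truth_is_classification_only():
    a = assign_targets([(np.zeros((0, 4)), np.zeros(0, int))], GRIDS, STRIDES, 3)
    assert a.n_pos == 0
    rng = np.random.default_rng(0)
    outputs = [(Tensor(rng.normal(size=(1, 3, h, w)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 4 * REG_MAX, h, w)).astype(np.float32)))
               for h, w in GRIDS]
    loss, comps = compute_loss(outputs, a)
    assert comps["box"] == 0.0 and comps["dfl"] == 0.0 and comps["cls"] > 0
    assert math.isfinite(comps["total"])


@pytest.mark.parametrize("trial", range(20))
def test_assignment_is_invariant_to_ground_truth_order(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(2, 6))
    boxes = []
    for _ in range(n):
        w, h = rng.uniform(6, 40, 2)
        x0 = rng.uniform(0, 64 - w)
        y0 = rng.uniform(0, 64 - h)
        boxes.append([x0, y0, x0 + w, y0 + h])
    boxes = np.array(boxes, np.float32)
    cats = rng.integers(0, 3, n)
    a = assign_targets([(boxes, cats)], GRIDS, STRIDES, 3)
    perm = rng.permutation(n)
    b = assign_targets([(boxes[perm], cats[perm])], GRIDS, STRIDES, 3)
    for sa, sb in zip(a.scales, b.scales):
        assert np.array_equal(sa.pos_cells, sb.pos_cells)
        assert np.array_equal(sa.target_cat, sb.target_cat)
        assert np.allclose(sa.target_ltrb, sb.target_ltrb)


def test_disabled_pbm_equals_sigma_zero_bitwise():
    rng = np.random.default_rng(1)
    gt = (np.array([[10.0, 10.0, 30.0, 30.0]]), np.array([0]))
    a = assign_targets([gt], GRIDS, STRIDES, 2)
    outputs = [(Tensor(rng.normal(size=(1, 2, h, w)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 64, h, w)).astype(np.float32)))
               for h, w in GRIDS]
    stats = compute_class_pixel_stats([(0, 10, 10), (1, 5, 5)], 2)
    zero = sample_variation(stats, 0.0, 0)
    l_off, _ = compute_loss(outputs, a, pbm_state=None)
    l_zero, _ = compute_loss(outputs, a, pbm_state=zero)
    assert l_off.data == l_zero.data


def test_perturbation_is_dropped_outside_training():
    rng = np.random.default_rng(2)
    gt = (np.array([[10.0, 10.0, 30.0, 30.0]]), np.array([0]))
    a = assign_targets([gt], GRIDS, STRIDES, 2)
    outputs = [(Tensor(rng.normal(size=(1, 2, h, w)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 64, h, w)).astype(np.float32)))
               for h, w in GRIDS]
    stats = compute_class_pixel_stats([(0, 100, 100), (1, 2, 2)], 2)
    var = sample_variation(stats, 4.0, 3)
    l_train, _ = compute_loss(outputs, a, pbm_state=var, training=True)
    l_eval, _ = compute_loss(outputs, a, pbm_state=var, training=False)
    l_none, _ = compute_loss(outputs, a, pbm_state=None, training=True)
    assert l_eval.data == l_none.data
    assert l_train.data != l_none.data


def test_perfect_box_predictions_have_near_zero_box_loss():
    """Concentrate the bin logits on integral target distances: decoded
    boxes coincide with the ground truth, so the CIoU loss vanishes."""
    # centre (36, 36) sits exactly on the stride-8 cell centre: ltrb = 1 cell
    gt = (np.array([[28.0, 28.0, 44.0, 44.0]]), np.array([0]))
    a = assign_targets([gt], GRIDS, STRIDES, 1)
    outputs = []
    for h, w in GRIDS:
        reg = np.zeros((1, 4, REG_MAX, h, w), np.float32)
        reg[:, :, 1] = 40.0  # all mass on bin 1 (= the target distance)
        outputs.append((Tensor(np.full((1, 1, h, w), -10.0, np.float32)),
                        Tensor(reg.reshape(1, 4 * REG_MAX, h, w))))
    _, comps = compute_loss(outputs, a)
    assert comps["box"] < 1e-4


def test_logit_perturbation_scale_follows_the_frequency_ratio():
    """Two categories, head p=10000 / tail p=10: over many iterations the
    tail perturbation std is ~ sigma and the head's is scaled by
    Pix_head / Pix_tail."""
    stats = compute_class_pixel_stats([(0, 100, 100), (1, 5, 2)], 2)
    sigma = 4.0
    draws = np.stack([sample_variation(stats, sigma, s).variation
                      for s in range(10_000)])
    stds = draws.std(axis=0)
    ratio = stats.frequency[0] / stats.frequency[1]
    assert abs(stds[1] - sigma) / sigma < 0.05
    assert abs(stds[0] - sigma * ratio) / (sigma * ratio) < 0.05


def test_loss_is_finite_for_random_inputs():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(0, 4))
        boxes = []
        for _ in range(n):
            w, h = rng.uniform(4, 50, 2)
            x0 = rng.uniform(0, 64 - w)
            y0 = rng.uniform(0, 64 - h)
            boxes.append([x0, y0, x0 + w, y0 + h])
        gt = (np.array(boxes, np.float32).reshape(-1, 4), rng.integers(0, 3, n))
        a = assign_targets([gt], GRIDS, STRIDES, 3)
        outputs = [(Tensor(rng.normal(0, 5, (1, 3, h, w)).astype(np.float32)),
                    Tensor(rng.normal(0, 5, (1, 64, h, w)).astype(np.float32)))
                   for h, w in GRIDS]
        loss, comps = compute_loss(outputs, a)
        assert math.isfinite(comps["total"]) and comps["total"] >= 0


def test_fit_is_reproducible_given_a_seed(tiny_dataset):
    dataset, _ = tiny_dataset
    cfg = ModelConfig(n_categories=3, scale="tiny", input_size=(64, 64))
    losses = []
    for _ in range(2):
        model = build_model(cfg, seed=4)
        _, hist = fit(model, dataset, TrainConfig(
            epochs=5, batch_size=8, augment=False, mosaic_off_last=0, seed=11))
        losses.append([h["total"] for h in hist])
    assert losses[0] == losses[1]


def test_mosaic_disabled_for_the_final_epochs(tiny_dataset):
    dataset, _ = tiny_dataset
    cfg = ModelConfig(n_categories=3, scale="tiny", input_size=(64, 64),
                      pbm=PbmConfig(enabled=False))
    model = build_model(cfg, seed=5)
    _, hist = fit(model, dataset, TrainConfig(
        epochs=12, batch_size=8, augment=True, mosaic_off_last=4, seed=0))
    flags = [h["mosaic"] for h in hist]
    assert flags == [True] * 8 + [False] * 4
    calls = [h["mosaic_calls"] for h in hist]
    assert calls[7] > 0 and calls[-1] == calls[7]  # counter frozen afterwards


def test_inference_path_never_samples_perturbations(monkeypatch, overfit_run):
    model, _, dataset = overfit_run
    calls = {"n": 0}
    orig = pbm_module.sample_variation

    def counting(*a, **k):
        calls["n"] += 1
        return orig(*a, **k)

    monkeypatch.setattr(pbm_module, "sample_variation", counting)
    img = dataset.images[0]
    chw = img.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0
    predict(model, chw, conf_threshold=0.25)
    validation_map50(model, dataset, (64, 64))
    assert calls["n"] == 0


def test_detections_identical_with_pbm_enabled_or_disabled(overfit_run):
    model, _, dataset = overfit_run
    img = dataset.images[1]
    chw = img.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0
    model.config.pbm = PbmConfig(enabled=True)
    a = predict(model, chw, conf_threshold=0.1)
    model.config.pbm = PbmConfig(enabled=False)
    b = predict(model, chw, conf_threshold=0.1)
    assert a == b


def test_default_recipe_configuration():
    cfg = TrainConfig()
    assert (cfg.epochs, cfg.batch_size) == (100, 16)
    assert (cfg.lr0, cfg.momentum) == (0.01, 0.937)
    assert cfg.mosaic_off_last == 10 and cfg.optimizer == "sgd"
    with pytest.raises(ValueError):
        TrainConfig(epochs=5, mosaic_off_last=6)
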