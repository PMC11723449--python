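"""Training loop: SGD with momentum, linear warmup + cosine decay, mosaic /
zoom / panning augmentation with the mosaic switched off for the final
epochs, and the prediction balance module injected into the classification
loss path (training only).

Defaults mirror the published recipe: 100 epochs, batch 16, initial
learning rate 0.01, momentum 0.937, mosaic disabled for the last 10 epochs,
no pretrained weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import pbm as pbm_module
from .autograd import Tensor
from .data import Dataset, letterbox, mosaic_augment, random_affine
from .losses import assign_targets, compute_loss
from .metrics import evaluate
from .model import BSDNet, PbmConfig, predict, save_checkpoint


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr0: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    optimizer: str = "sgd"
    warmup_epochs: int = 3
    final_lr_fraction: float = 0.01
    mosaic_off_last: int = 10
    input_size: tuple[int, int] | None = None   # falls back to the model config
    augment: bool = True
    zoom_range: tuple[float, float] = (0.5, 1.5)
    translate_range: float = 0.1
    pbm: PbmConfig | None = None                # falls back to the model config
    seed: int = 0
    max_iterations: int | None = None
    validate: bool = False
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mosaic_off_last > self.epochs:
            raise ValueError("mosaic_off_last cannot exceed epochs")
        if self.optimizer != "sgd":
            raise ValueError("only SGD is supported")


class _SGD:
    """SGD with momentum; weight decay on convolution kernels only."""

    def __init__(self, params, momentum, weight_decay):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim == 4:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v


def _lr_at(it, total_iters, warmup_iters, lr0, final_frac):
    if it < warmup_iters:
        return lr0 * (it + 1) / warmup_iters
    span = max(total_iters - warmup_iters, 1)
    t = (it - warmup_iters) / span
    return lr0 * (final_frac + (1 - final_frac) * 0.5 * (1 + math.cos(math.pi * t)))


def _prepare_image(img, input_size, mosaic_pool, use_mosaic, cfg, rng):
    """One training sample -> (chw float image, boxes, categories)."""
    if use_mosaic:
        extra = [mosaic_pool[i] for i in rng.choice(len(mosaic_pool), 3)]
        img = mosaic_augment([img] + list(extra), rng)
    px = img.load_pixels()
    boxes, cats = img.boxes, img.categories
    if cfg.augment:
        px, boxes, cats = random_affine(px, boxes, cfg.zoom_range,
                                        cfg.translate_range, rng, categories=cats)
    px, boxes, _ = letterbox(px, boxes, input_size)
    chw = px.astype(np.float32).transpose(2, 0, 1) / 255.0
    return chw, boxes, cats


def fit(model: BSDNet, dataset: Dataset, config: TrainConfig,
        val_dataset: Dataset | None = None):
    """Train the model in place; returns (model, history).

    History holds one record per epoch (mean loss components, learning
    rate, optional validation mAP50).  Training aborts on divergence (NaN
    loss), restoring the last finite weights.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    input_size = config.input_size or model.config.input_size
    nc = model.config.n_categories
    pbm_cfg = config.pbm if config.pbm is not None else model.config.pbm
    stats = None
    if pbm_cfg.enabled:
        # class pixel statistics from original-resolution boxes, pre-augmentation
        stats = pbm_module.compute_class_pixel_stats(dataset.annotations(), nc)
    opt = _SGD(model.parameters(), config.momentum, config.weight_decay)
    n_batches = max(1, math.ceil(len(dataset) / config.batch_size))
    total_iters = config.epochs * n_batches
    if config.max_iterations is not None:
        total_iters = min(total_iters, config.max_iterations)
    warmup = min(config.warmup_epochs * n_batches, max(total_iters // 10, 1))
    history = []
    best = {"map50": -1.0, "state": None}
    last_good = None
    it = 0
    stop = False
    mosaic_calls = 0
    for epoch in range(config.epochs):
        if stop:
            break
        model.train()
        mosaic_on = (config.augment and len(dataset) >= 4
                     and epoch < config.epochs - config.mosaic_off_last)
        order = rng.permutation(len(dataset))
        sums: dict = {}
        seen = 0
        for b in range(n_batches):
            if config.max_iterations is not None and it >= config.max_iterations:
                stop = True
                break
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            imgs, gts = [], []
            for i in idx:
                if mosaic_on:
                    mosaic_calls += 1
                chw, boxes, cats = _prepare_image(
                    dataset.images[i], input_size, dataset.images,
                    mosaic_on, config, rng)
                imgs.append(chw)
                gts.append((boxes, cats))
            batch = Tensor(np.stack(imgs))
            outputs = model(batch)
            shapes = [(o[0].shape[2], o[0].shape[3]) for o in outputs]
            assignments = assign_targets(gts, shapes, model.strides, nc)
            variation = None
            if stats is not None:
                variation = pbm_module.sample_variation(
                    stats, pbm_cfg.sigma,
                    np.random.default_rng((pbm_cfg.seed + it) % (2 ** 31)))
            try:
                loss, comps = compute_loss(outputs, assignments, variation,
                                           training=True)
            except FloatingPointError:
                comps = {"total": float("nan")}
                loss = None
            if loss is None or not math.isfinite(comps["total"]):
                if last_good is not None:
                    model.load_state_dict(last_good)
                history.append({"epoch": epoch, "diverged": True})
                return model, history
            model.zero_grad()
            loss.backward()
            opt.step(_lr_at(it, total_iters, warmup, config.lr0,
                            config.final_lr_fraction))
            for k, v in comps.items():
                sums[k] = sums.get(k, 0.0) + v * len(idx)
            seen += len(idx)
            it += 1
            if it % 50 == 0:
                last_good = {k: v.copy() for k, v in model.state_dict().items()}
        rec = {"epoch": epoch, "lr": _lr_at(max(it - 1, 0), total_iters, warmup,
                                            config.lr0, config.final_lr_fraction),
               "mosaic": bool(mosaic_on), "mosaic_calls": mosaic_calls}
        rec.update({k: v / max(seen, 1) for k, v in sums.items()})
        if config.validate and val_dataset is not None:
            rec["map50"] = validation_map50(model, val_dataset, input_size)
            if rec["map50"] > best["map50"]:
                best = {"map50": rec["map50"],
                        "state": {k: v.copy() for k, v in model.state_dict().items()}}
                if config.checkpoint_dir:
                    Path(config.checkpoint_dir).mkdir(parents=True, exist_ok=True)
                    save_checkpoint(model, Path(config.checkpoint_dir) / "best.npz",
                                    extra={"epoch": epoch, "map50": rec["map50"]})
            model.train()
        history.append(rec)
    if config.validate and best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return model, history


def validation_map50(model: BSDNet, dataset: Dataset, input_size,
                     conf_threshold: float = 0.05) -> float:
    """mAP50 over a dataset, evaluated with the balance module inert (the
    perturbation exists only inside the training loss path)."""
    model.eval()
    dets_per_img, gts_per_img = [], []
    for img in dataset.images:
        px, boxes, _ = letterbox(img.load_pixels(), img.boxes, input_size)
        chw = px.astype(np.float32).transpose(2, 0, 1) / 255.0
        dets = predict(model, chw, conf_threshold=conf_threshold, iou_nms=0.7)
        dets_per_img.append([(d.category, d.confidence, d.box) for d in dets])
        gts_per_img.append([(int(c), tuple(b)) for c, b in
                            zip(img.categories, boxes)])
    report = evaluate(dets_per_img, gts_per_img, iou_thresholds=(0.5,))
    return report.ap[0.5] and float(np.mean(list(report.ap[0.5].values()))) or 0.0
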