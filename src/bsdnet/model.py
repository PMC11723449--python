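"""BSD-Net assembly: stem, three downsampling stages (dual-branch feature
mixers, or Conv+C2F for the ablation baseline), SPPF, PAFPN neck, and a
decoupled anchor-free head with a distribution-focal box representation.

The medium scale follows the YOLO-family schedule (depth 0.67, width 0.75,
max width 768); the baseline variant is therefore a YOLOv8m-shaped network.
The mixer stages use a calibrated per-stage width schedule expressed as
fractions of the stage widths (see `DBFM_LOCAL_FRACS` / `DBFM_OUT_FRACS`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import C2F, SPPF, ConvBNSiLU
from .dbfm import DbfmSpec, DualBranchFeatureMixer
from .nn import Conv2d, Module, ModuleList, Upsample2x

REG_MAX = 16  # bins of the distribution-focal box representation, per side

SCALES = {
    # depth_multiple, width_multiple, max_width
    "nano": (0.33, 0.25, 1024),
    "small": (0.33, 0.50, 1024),
    "medium": (0.67, 0.75, 768),
    "tiny": (0.33, 0.125, 768),  # reduced-width scale for desk-size experiments
}

# Mixer stage schedule (fractions of the stage in/out widths), calibrated so
# the medium-scale model meets the published parameter/FLOP budget.
DBFM_LOCAL_REPEATS = (1, 1, 1)
DBFM_LOCAL_FRACS = (Fraction(5, 12), Fraction(7, 12), Fraction(1, 2))
DBFM_OUT_FRACS = (Fraction(1, 2), Fraction(1, 2), Fraction(35, 48))


@dataclass
class PbmConfig:
    enabled: bool = True
    sigma: float = 4.0
    seed: int = 0


@dataclass
class ModelConfig:
    n_categories: int = 200
    scale: str = "medium"
    input_size: tuple[int, int] = (640, 640)
    use_dbfm: bool = True
    width_multiple: float | None = None
    depth_multiple: float | None = None
    stem_channels: int | None = None  # C1; derived from the scale if None
    pbm: PbmConfig = field(default_factory=PbmConfig)

    def __post_init__(self):
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size must be divisible by 32, got {self.input_size}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; options: {sorted(SCALES)}")

    def resolve(self):
        """(channels per level, repeats per stage) after applying multipliers."""
        d0, w0, maxw = SCALES[self.scale]
        d = self.depth_multiple if self.depth_multiple is not None else d0
        w = self.width_multiple if self.width_multiple is not None else w0
        ch = [_make_divisible(min(c, maxw) * w) for c in (64, 128, 256, 512, 1024)]
        if self.stem_channels is not None:
            ch[1] = self.stem_channels
        dep = [max(round(n * d), 1) for n in (3, 6, 6, 3)]
        return ch, dep

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["input_size"] = tuple(d.get("input_size", (640, 640)))
        if isinstance(d.get("pbm"), dict):
            d["pbm"] = PbmConfig(**d["pbm"])
        return cls(**d)


@dataclass(frozen=True)
class DetectionBox:
    """One prediction or ground-truth box: 0-based half-open pixel coords."""
    category: int
    confidence: float
    box: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


def _make_divisible(x: float, div: int = 8) -> int:
    return int(math.ceil(x / div) * div)


class ConvC2fStage(Module):
    """Baseline downsampling stage: stride-2 conv then a C2F block."""

    def __init__(self, c_in, c_out, n, rng=None):
        super().__init__()
        self.down = ConvBNSiLU(c_in, c_out, 3, stride=2, rng=rng)
        self.c2f = C2F(c_out, c_out, n=n, shortcut=True, rng=rng)

    def forward(self, x):
        return self.c2f(self.down(x))

    def profile(self, h, w):
        f1, (h, w) = self.down.profile(h, w)
        f2, _ = self.c2f.profile(h, w)
        return f1 + f2, (h, w)


class Backbone(Module):
    def __init__(self, ch, dep, use_dbfm, rng=None):
        super().__init__()
        self.stem1 = ConvBNSiLU(3, ch[0], 3, stride=2, rng=rng)
        self.stem2 = ConvBNSiLU(ch[0], ch[1], 3, stride=2, rng=rng)
        self.c2f_p2 = C2F(ch[1], ch[1], n=dep[0], shortcut=True, rng=rng)
        stages = []
        for i, (c1, c2, n) in enumerate(
            [(ch[1], ch[2], dep[1]), (ch[2], ch[3], dep[2]), (ch[3], ch[4], dep[3])]
        ):
            if use_dbfm:
                spec = DbfmSpec(
                    in_channels=c1, out_channels=c2,
                    local_repeats=DBFM_LOCAL_REPEATS[i],
                    local_hidden=int(round(c1 * DBFM_LOCAL_FRACS[i])),
                    out_repeats=n,
                    out_hidden=int(round(c2 * DBFM_OUT_FRACS[i])),
                )
                stages.append(DualBranchFeatureMixer(spec, rng=rng))
            else:
                stages.append(ConvC2fStage(c1, c2, n, rng=rng))
        self.stages = ModuleList(stages)
        self.sppf = SPPF(ch[4], ch[4], pool_kernel=5, rng=rng)

    def forward(self, x):
        x = self.c2f_p2(self.stem2(self.stem1(x)))
        p3 = self.stages[0](x)
        p4 = self.stages[1](p3)
        p5 = self.sppf(self.stages[2](p4))
        return p3, p4, p5

    def profile(self, h, w):
        f = 0
        for m in (self.stem1, self.stem2, self.c2f_p2):
            fm, (h, w) = m.profile(h, w)
            f += fm
        for st in self.stages:
            fm, (h, w) = st.profile(h, w)
            f += fm
        f += self.sppf.profile(h, w)[0]
        return f


class Neck(Module):
    """Path-aggregation FPN over P3/P4/P5 with C2F fusion blocks."""

    def __init__(self, ch, dep, rng=None):
        super().__init__()
        n = dep[3]
        self.up = Upsample2x()
        self.td1 = C2F(ch[4] + ch[3], ch[3], n=n, shortcut=False, rng=rng)
        self.td2 = C2F(ch[3] + ch[2], ch[2], n=n, shortcut=False, rng=rng)
        self.down1 = ConvBNSiLU(ch[2], ch[2], 3, stride=2, rng=rng)
        self.bu1 = C2F(ch[2] + ch[3], ch[3], n=n, shortcut=False, rng=rng)
        self.down2 = ConvBNSiLU(ch[3], ch[3], 3, stride=2, rng=rng)
        self.bu2 = C2F(ch[3] + ch[4], ch[4], n=n, shortcut=False, rng=rng)

    def forward(self, p3, p4, p5):
        t4 = self.td1(ag.concat([self.up(p5), p4], axis=1))
        n3 = self.td2(ag.concat([self.up(t4), p3], axis=1))
        n4 = self.bu1(ag.concat([self.down1(n3), t4], axis=1))
        n5 = self.bu2(ag.concat([self.down2(n4), p5], axis=1))
        return n3, n4, n5

    def profile(self, h3, w3):
        h4, w4, h5, w5 = h3 // 2, w3 // 2, h3 // 4, w3 // 4
        f = self.td1.profile(h4, w4)[0] + self.td2.profile(h3, w3)[0]
        f += self.down1.profile(h3, w3)[0] + self.bu1.profile(h4, w4)[0]
        f += self.down2.profile(h4, w4)[0] + self.bu2.profile(h5, w5)[0]
        return f


class Head(Module):
    """Decoupled classification / box-regression head at three scales.

    Box branch emits 4 * REG_MAX distribution-focal logits per cell; the
    classification branch emits one logit per category.
    """

    def __init__(self, ch3, nc, rng=None):
        super().__init__()
        self.nc = nc
        c2 = max(16, ch3[0] // 4, 4 * REG_MAX)
        c3 = max(ch3[0], min(nc, 100))
        self.reg = ModuleList()
        self.cls = ModuleList()
        for c in ch3:
            self.reg.append(_Branch(c, c2, 4 * REG_MAX, rng=rng))
            self.cls.append(_Branch(c, c3, nc, bias_init=-math.log(99.0), rng=rng))

    def forward(self, feats):
        out = []
        for f, rb, cb in zip(feats, self.reg, self.cls):
            out.append((cb(f), rb(f)))
        return out

    def profile(self, shapes):
        f = 0
        for (h, w), rb, cb in zip(shapes, self.reg, self.cls):
            f += rb.profile(h, w)[0] + cb.profile(h, w)[0]
        return f


class _Branch(Module):
    def __init__(self, c_in, c_mid, c_out, bias_init=0.0, rng=None):
        super().__init__()
        self.cv1 = ConvBNSiLU(c_in, c_mid, 3, rng=rng)
        self.cv2 = ConvBNSiLU(c_mid, c_mid, 3, rng=rng)
        self.out = Conv2d(c_mid, c_out, 1, bias=True, rng=rng)
        self.out.bias.data[:] = bias_init

    def forward(self, x):
        return self.out(self.cv2(self.cv1(x)))

    def profile(self, h, w):
        return (self.cv1.profile(h, w)[0] + self.cv2.profile(h, w)[0]
                + self.out.profile(h, w)[0]), (h, w)


class BSDNet(Module):
    strides = (8, 16, 32)

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        ch, dep = config.resolve()
        self.config = config
        self.backbone = Backbone(ch, dep, config.use_dbfm, rng=rng)
        self.neck = Neck(ch, dep, rng=rng)
        self.head = Head((ch[2], ch[3], ch[4]), config.n_categories, rng=rng)

    def forward(self, x: Tensor):
        """x: (N, 3, H, W) with H, W divisible by 32.  Returns a list of
        (cls_logits, reg_logits) pairs at strides 8, 16, 32."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial dims must be divisible by 32")
        return self.head(self.neck(*self.backbone(x)))

    def profile_flops(self, input_size=None) -> int:
        """Analytic forward FLOPs (conv/linear, MAC = 2) at batch 1."""
        h, w = input_size or self.config.input_size
        f = self.backbone.profile(h, w)
        f += self.neck.profile(h // 8, w // 8)
        f += self.head.profile([(h // s, w // s) for s in self.strides])
        return f


# -- public API -----------------------------------------------------------

def build_model(config: ModelConfig, seed: int = 0) -> BSDNet:
    return BSDNet(config, seed=seed)


def count_parameters(model: BSDNet) -> int:
    return model.num_parameters()


def count_flops(model: BSDNet, input_size=None) -> float:
    """Forward-pass cost in GFLOPs (1 MAC = 2 FLOPs, batch 1, convolutions
    and linear maps only) at the given (h, w)."""
    return model.profile_flops(input_size) / 1e9


def make_anchors(shapes, strides):
    """Cell-centre coordinates (in input pixels) and stride per flattened cell."""
    pts, sts = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
        sts.append(np.full(h * w, s, dtype=np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(sts)


def dfl_expectation(reg: np.ndarray) -> np.ndarray:
    """(N, 4*REG_MAX, H, W) logits -> (N, 4, H, W) expected l,t,r,b distances
    in stride units (softmax expectation over the bin distribution)."""
    n, _, h, w = reg.shape
    r = reg.reshape(n, 4, REG_MAX, h, w)
    r = r - r.max(axis=2, keepdims=True)
    e = np.exp(r)
    p = e / e.sum(axis=2, keepdims=True)
    bins = np.arange(REG_MAX, dtype=np.float32).reshape(1, 1, REG_MAX, 1, 1)
    return (p * bins).sum(axis=2)


def decode_predictions(outputs, strides=BSDNet.strides):
    """Raw head outputs -> (boxes_xyxy (M,4), scores (M,nc)) in input pixels."""
    boxes, scores = [], []
    for (cls, reg), s in zip(outputs, strides):
        cl, rg = cls.data, reg.data
        n, nc, h, w = cl.shape
        dist = dfl_expectation(rg) * s
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx, cy = (xs + 0.5) * s, (ys + 0.5) * s
        x0 = cx[None] - dist[:, 0]
        y0 = cy[None] - dist[:, 1]
        x1 = cx[None] + dist[:, 2]
        y1 = cy[None] + dist[:, 3]
        boxes.append(np.stack([x0, y0, x1, y1], axis=-1).reshape(n, -1, 4))
        scores.append(1.0 / (1.0 + np.exp(-cl.transpose(0, 2, 3, 1).reshape(n, -1, nc))))
    return np.concatenate(boxes, axis=1), np.concatenate(scores, axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float):
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        others = order[~suppressed[order]]
        xx0 = np.maximum(boxes[i, 0], boxes[others, 0])
        yy0 = np.maximum(boxes[i, 1], boxes[others, 1])
        xx1 = np.minimum(boxes[i, 2], boxes[others, 2])
        yy1 = np.minimum(boxes[i, 3], boxes[others, 3])
        inter = np.clip(xx1 - xx0, 0, None) * np.clip(yy1 - yy0, 0, None)
        iou = inter / (areas[i] + areas[others] - inter + 1e-12)
        suppressed[others[iou > iou_threshold]] = True
        suppressed[i] = True
    return keep


def predict(model: BSDNet, image: np.ndarray, conf_threshold: float = 0.25,
            iou_nms: float = 0.7, max_det: int = 300):
    """Run inference on one image (3, H, W float in [0, 1]) and return a
    confidence-sorted list of `DetectionBox` after per-category NMS."""
    if not (0 < conf_threshold <= 1 and 0 < iou_nms < 1):
        raise ValueError("thresholds must lie in (0, 1]")
    model.eval()
    with ag.no_grad():
        outputs = model(Tensor(image[None]))
    boxes, scores = decode_predictions(outputs)
    boxes, scores = boxes[0], scores[0]
    h_img = image.shape[1]
    w_img = image.shape[2]
    dets: list[DetectionBox] = []
    for k in range(scores.shape[1]):
        sel = np.flatnonzero(scores[:, k] >= conf_threshold)
        if sel.size == 0:
            continue
        kept = nms(boxes[sel], scores[sel, k], iou_nms)
        for i in kept:
            x0, y0, x1, y1 = boxes[sel[i]]
            x0, x1 = np.clip([x0, x1], 0, w_img)
            y0, y1 = np.clip([y0, y1], 0, h_img)
            if x1 > x0 and y1 > y0:
                dets.append(DetectionBox(k, float(scores[sel[i], k]),
                                         (float(x0), float(y0), float(x1), float(y1))))
    dets.sort(key=lambda d: -d.confidence)
    return dets[:max_det]


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: BSDNet, path, extra: dict | None = None) -> None:
    """Persist weights + config (config embedded as JSON)."""
    state = model.state_dict()
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> BSDNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model
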