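# Methods

## Model

BSD-Net is a single-stage, anchor-free detector in the YOLOv8 family. A
two-convolution stem (both stride 2, Conv–BN–SiLU) takes the RGB input to
H/4×W/4 at width C1, followed by a C2F block. Three downsampling stages
then produce the P3/P4/P5 pyramid (strides 8/16/32); an SPPF block (1×1
squeeze, three cascaded 5×5 stride-1 max-pools, concat, 1×1 fuse) sits on
P5. A PAFPN neck fuses the three levels top-down and bottom-up with C2F
blocks, and a decoupled head emits, per cell and scale, `nc` category
logits and 4×16 distribution-focal bin logits (box sides as softmax
expectations over 16 integer bins, in stride units).

Scales follow the conventional depth/width multiplier schedule; `medium`
is (0.67, 0.75, max width 768), which makes the mixer-free baseline
(`use_dbfm=False`, each stage a stride-2 Conv + C2F) a YOLOv8m-shaped
network. A `tiny` scale (0.33, 0.125) exists for desk-scale experiments.

### Dual-branch feature mixer

Each downsampling stage of the full model is a mixer that operates at the
stage input resolution and width C:

1. **Local branch**: a C2F block (C→C).
2. **Global branch**: 1×1 conv expands C→2C (BN+SiLU), split into F1 and
   F2; a depthwise 3×3 over (F1 + input) is gated by an exact-erf GELU,
   multiplied elementwise by F2, projected back C→C by a 1×1 conv, and
   added residually to the input. The expansion must produce an even
   channel count, hence `in_channels` is required even.
3. **Fusion**: `SiLU(BN(Conv1x1(concat(LD, GI))))` at width C (so the fused
   map can be added back to the input pathway without projection).
4. **Downsampling**: the fused-plus-input map is rearranged into its four
   strided sub-grids at offsets (0,0), (1,0), (0,1), (1,1) — a lossless
   bijection C×H×W → 4C×H/2×W/2 — then 1×1-mixed to the output width and
   passed through a trailing channel-mixing C2F.

Design points that were genuinely open and how they were resolved:

- **Channel arithmetic of the split.** The branch split only type-checks
  with the residual additions if F1 and F2 each carry C channels, so the
  leading 1×1 conv expands C→2C before splitting. This is the only reading
  under which every addition in the global branch is well-formed.
- **Sub-region selection.** Strided even/odd slices (the established
  space-to-depth idiom) rather than quadrant crops: both give identical
  channel counts, but only the strided form keeps each output pixel's 4
  channels spatially co-located, which is the point of replacing a stride-2
  kernel with a rearrangement.
- **Second channel mixing.** After the four sub-grids are stacked, the
  channels are mixed twice: a 1×1 conv to the stage output width and a
  trailing C2F at that width. The trailing C2F plays the role the
  stand-alone C2F plays in the baseline stage; the mixer replaces the whole
  Conv+C2F pair.
- **One residual.** The fused map is added once to the input pathway
  (inside step 4's input); no second residual around the whole mixer is
  applied. The local branch consumes the stage input directly.
- **GELU** uses the exact erf formulation; the tanh approximation differs
  at the 1e-3 level and would blur the hand-computed scalar oracles in the
  test-suite.
- **Internal widths.** The hidden widths of the two C2F blocks are the
  mixer's free capacity knobs. The medium-scale schedule — local hidden
  (40, 112, 192), trailing hidden (96, 192, 420), local depth 1, trailing
  depth (4, 4, 2), expressed in code as per-stage fractions of the stage
  widths — was calibrated once so the full medium model meets the
  published budget of +4.7 M parameters / +17 GFLOPs over the baseline
  (realised: +4.652 M / +16.99 G; totals 30.62 M / 96.32 G vs the
  baseline's 25.97 M / 79.32 G). At other scales the hidden widths default
  to the same fractions of the (smaller) stage widths.

A note on "global": within a single block the gated depthwise path has a
3×3 spatial footprint; map-wide coupling arises through the normalisation
statistics (in training), the elementwise gating, and the stacking of three
such stages with downsampling. The receptive-field probe in the tests
asserts the coupling beyond the local footprint in training mode.

### Prediction balance module

Per-category pixel masses `p_k` are accumulated once before training from
the *original-resolution* annotation boxes (sum of w·h per category,
pre-augmentation); categories absent from the training set are clamped to
1 px² with a warning. The frequency vector is `Pix_k = log(Σ p_i / p_k)`;
with a single category, or a perfectly uniform set (max Pix = 0), the
perturbation is zero by convention.

Each training iteration draws one `Variation_k = Pix_k / max Pix · δ_k`
with `δ_k ~ N(0, σ²)` i.i.d. per category, and adds it to the raw
classification logits (broadcast over all cells of the batch) before the
classification loss. Decisions on points the formulation leaves open:

- σ is treated as the **standard deviation** of the draw. The ablation
  grid σ ∈ {3,4,5,6} behaves as a scale knob either way; σ = 4 is the
  default (the best ablation setting). The variance reading would simply
  re-index the same knob as σ².
- Perturbation target: **logits**, not post-sigmoid probabilities — keeps
  the binary cross-entropy well-defined and unbiased in expectation.
- Sampling frequency: **one vector per iteration (batch)**, shared across
  locations; per-anchor or per-epoch resampling are noted alternatives.

The module has no parameters and contributes no FLOPs; it exists only in
the training loss path. `sample_variation` is never invoked from the
inference code, so detections with the module enabled or disabled are
bitwise identical.

## Training recipe

SGD with momentum 0.937 and weight decay 5e-4 on convolution kernels only;
initial learning rate 0.01, 3-epoch linear warmup then cosine decay to 1%
of lr0; 100 epochs, batch 16, no pretrained weights. Augmentation: mosaic
(2×2 composite around a random centre, boxes clipped, sub-pixel boxes
dropped) followed by random zoom (0.5–1.5) and translation (±10%) —
magnitudes are the conventional defaults since only the augmentation
family is prescribed — with mosaic disabled for the last 10 epochs.
Letterboxing pads with grey 114 and records the transform for exact
inversion.

Target assignment is deliberately simple and deterministic: each ground
truth goes to the cell containing its centre at the finest stride whose
16-bin distribution-focal range can represent the box; when two boxes
claim a cell the smaller wins, ties broken by coordinates, making the
assignment invariant to annotation order. The loss is
`7.5·CIoU + 0.5·BCE + 1.5·DFL` with the BCE summed over all cells and
normalised by the positive count. Validation and checkpoint selection
(best mAP50) run perturbation-free.

## Synthetic scenes

The generator emulates the three properties of real wetland survey data
that the detector's two additions target: a long-tailed category
distribution (category k drawn with probability ∝ (k+1)^−e, default
e = 1.5), widely varying object scales (sprite side 16–48 px in a 160×160
scene by default), and shared local appearance — every sprite is the same
ellipse body + triangular beak, and only a wing patch whose salience
scales with (1 − motif_overlap) identifies the category (default overlap
0.5). Backgrounds are low-frequency blue-green noise so objects are not
trivially separable. Boxes are exact tight boxes around sprite pixels
(integers by construction), and the emitted ledger of per-category pixel
sums equals the balance module's `p_k` exactly, giving an end-to-end
integer consistency check.

What the generator does **not** emulate: occlusion between birds, pose
articulation, lighting/weather variation, camera blur, background clutter
that mimics bird shapes, and label noise. Passing tests on these scenes
therefore validate mechanism (shapes, statistics, optimisation dynamics,
metric arithmetic), not field accuracy; the published benchmark accuracies
require the real datasets and GPU-scale training, which are out of scope.

## Numerical choices

- All computation is float32 on numpy; convolution via im2col + BLAS
  matmul; inference runs with graph construction disabled.
- BatchNorm uses eps 1e-3, momentum 0.03 (YOLO-family convention); the
  test-suite uses an explicit `identity_()` helper (running stats 0 and
  1−eps) where a hand-traced oracle needs BN bypassed exactly.
- FLOPs are counted analytically over convolutions and linear maps with
  one MAC = 2 FLOPs at batch 1 (normalisation, pooling, activations
  excluded) — the convention under which single-stage detector budgets
  are conventionally quoted. A runtime recorder inside the conv ops lets
  the tests assert that the analytic walker matches the executed work
  exactly. Profile figures are reported truncated to one decimal, the
  convention of the budget tables this package reproduces (the baseline's
  25.97 M prints as 25.9).
- Greedy NMS per category with IoU ties broken by order of confidence;
  matching in the evaluator is greedy in confidence with highest-IoU
  choice and lower-index tie-break; max-pool gradients flow to every tied
  maximum.
- AP is the literal rank summation (no interpolation); a COCO-style
  101-point variant exists behind a flag for cross-checks only. Categories
  without ground truth are excluded from mAP means; a ground-truth-free
  evaluation reports mAP as undefined rather than zero. Single-number P/R
  are reported at the F1-optimal confidence and labelled with it.

## Desk-scale problem sizes

The test-suite and examples use the `tiny` scale (≈0.8 M parameters) at
64×64 inputs, 8-image overfit runs of 200 iterations, 1e5-draw Monte-Carlo
checks of the perturbation statistics, and 200-scene metric comparisons
against a brute-force oracle — sizes chosen so the full suite runs in a
few minutes on one CPU core while still exercising every code path of the
full-scale model (which itself is built and profiled, not trained, in the
tests).

## Known limitations

- Task-aligned (IoU-quality-weighted) assignment and EMA weights, used by
  modern YOLO trainers, are not implemented; the centre-cell assigner is
  sufficient for desk-scale convergence but less forgiving on crowded
  scenes.
- numpy execution is single-threaded BLAS-bound; medium-scale training is
  out of reach (inference at 640×640 takes seconds per image).
- The directional claim that balancing narrows the head/tail AP gap is a
  statistical property of full-scale training; at 8-image overfit scale
  both configurations reach perfect training mAP and the effect is not
  measurable.
- COCO I/O covers the detection schema (images/annotations/categories,
  xywh boxes); crowd/segmentation fields are ignored.
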