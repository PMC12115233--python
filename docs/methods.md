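# Methods

## Problem setting

Post-treatment assessment of root-canal fillings looks for *voids*: small
dark gaps inside the bright, elongated canal filling visible on periapical
radiographs. As a detection task this is single-class, small-object
(targets of a few to ~30 px at 640×640), low-contrast, and set against
structured background texture. The package implements a complete detection
pipeline for this regime and validates every component against independent
oracles.

## Model

### Detector topology

An anchor-free, one-to-many YOLO-style detector:

* **Backbone** — five stride-2 ResConv stages with C2f fusion blocks after
  stages 1–4; taps at strides 8/16/32 (P3/P4/P5).
* **Neck** — FPN top-down fusion (upsample + concat + C2f) followed by PAN
  bottom-up fusion. The stride-8 path ends in a **C2fCS** block (C2f with
  tokenized attention appended) immediately before the stride-8 head: the
  highest-resolution head carries the small objects, so that is where the
  extra local focusing is spent.
* **Heads** — per scale, a 3×3 conv then a 1×1 conv to `4 + 1 + n_classes`
  channels: FCOS-style box distances (softplus(l,t,r,b)·stride around the
  cell centre), an objectness logit (bias-initialised to −4 so the initial
  objectness prior is low), and class logits. Inference decodes cells above
  a confidence threshold and applies greedy class-aware NMS.

### ResConv

`y = Conv₃ₓ₃,stride(x)`, `out = SiLU(BN(y + DWConv₃ₓ₃(y)))`. The wiring is
simultaneously serial (the depthwise conv consumes the standard conv's
output) and parallel (the additive skip carries `y` past it), and the skip
is shape-compatible at any stride without projections. The depthwise kernel
is zero-initialised, so each block starts as a plain convolution and the
depthwise branch grows in as training demands it.

### Tokenized attention (TokAtt)

The input `(H, W, C)` map is LayerNorm-ed over channels, linearly embedded
(C→C), partitioned into `S²` equal non-overlapping spatial tokens, and
scaled dot-product self-attention (`softmax(QKᵀ/√C)V`, single-head by
default; the head count is a config knob) runs inside each token with
projections shared across tokens. Tokens are then fused back in row-major
grid order — an exact inverse of the tokenization — and passed through an
output linear map. An outer residual skip (`x + block(x)`) is on by
default: the output projection is zero-initialised, so the block starts as
the identity and cannot destroy signal at initialisation. By construction
no information crosses token boundaries before the output map; the test
suite asserts this by perturbation.

Choices left open by the mechanism's description and fixed here: the
attention scale is `√C` (the ViT convention) rather than `C`; the linear
embedding preserves the channel count; `S = 4` by default (the stride-8
grid must be divisible by `S`, which the config validates at build time).

### CMIoU box loss

For predicted box `p` and ground truth `g` in corner coordinates with image
frame `(H, W)`:

```
L_CMIoU(p, g) = 1 − IoU + (d₁² + d₂²)/(H² + W²) + ρ²/c² + α·v
v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))²,  α = v/((1 − IoU) + v)
```

`d₁², d₂²` are squared distances between corresponding top-left and
bottom-right corners; `ρ²` is the squared centre distance and `c²` the
squared diagonal of the tightest enclosing box. Numerical conventions:

* aspect ratios clamp the denominator at 1e−7 px so degenerate predictions
  stay finite and keep gradients;
* `α` is a stop-gradient weight during backpropagation (the CIoU-literature
  convention);
* the corner normaliser uses the training input frame (default 640×640),
  not the enclosing box;
* the MPDIoU quantity `IoU − (d₁²+d₂²)/(H²+W²)` is exposed verbatim as a
  similarity score (it can be negative; higher is better); the trainable
  objective is exclusively `L_CMIoU`.

The total training loss is `w_cls·L_cls + w_box·L_box + w_obj·L_obj` with
default weights (0.5, 5.0, 1.0): binary cross-entropy on class and
objectness logits (objectness balanced 4.0/1.0/0.4 across the three scales,
reflecting where the positives live), and CMIoU (or CIoU, selectable)
averaged over assigned cells. A distribution-focal localization term is
deliberately not included.

### Target assignment

Each ground truth is routed to one scale by √area thresholds (≤32 px →
stride 8, ≤96 px → stride 16, else stride 32) and matched to its containing
cell plus the two nearest neighbour cells chosen by the sub-cell offset
(≤3 positive cells per object; a contested cell keeps its first object).
This replaces the dual one-to-one/one-to-many head scheme of full-scale
YOLOv10-class detectors — inherited machinery orthogonal to the blocks this
package is about — with a single one-to-many head per scale and NMS at
inference.

## Numerics

The network runs on an in-package reverse-mode autodiff engine over numpy
arrays (im2col convolutions, shifted-add depthwise convolutions, batch/layer
norm with explicit backward formulas, softmax attention). Gradients of
every operation are verified against central differences; the network runs
in float32, the scalar loss API in float64. Training is AdamW with
decoupled weight decay applied to rank-≥2 parameters only. All parameter
initialisation (Kaiming-uniform convolutions, Xavier linear maps,
zero-initialised residual-branch output projections) is driven by a single
seeded generator in construction order, so builds, runs and evaluations are
bit-reproducible on one machine.

## Synthetic phantoms

The generator models the *appearance statistics* of obturation radiographs,
not dental anatomy or X-ray physics: a dark textured background (low-
frequency noise), 1–3 bright gently-curved near-vertical bands (the filled
canals, width 22–48 px at 640), 0–4 darker soft-edged ellipses placed fully
inside a canal band (the voids, 4–28 px diameter, contrast 0.18–0.40),
then Gaussian blur (σ 0.6–1.4) and additive noise (σ 0.02). Boxes are
recorded tightly around each void **before** blur; at the default σ the
apparent edge shift is under ~2 px and is accepted as label noise mirroring
clinical annotation uncertainty. The default dataset is 768 images split
612/156 train/val — the split of the clinical dataset this generator
stands in for (768·0.2 is 153.6, so the printed 612/156 counts
are carried explicitly; any other n splits as val = ⌊n/5⌋).

An `easy` preset (default 160×160, one or two 11–24 px voids at contrast
0.45–0.55, minimal blur/noise, wide canals) defines the desk-scale
demonstrations. What passing tests on phantoms shows: the architecture can
learn and localise small low-contrast inclusions inside bright elongated
structures, end to end, under the stated training procedure. What it does
not show: clinical performance — real radiographs have anatomy, occlusion,
exposure variation and annotation ambiguity the phantom does not model.

## Training defaults

`TrainConfig` defaults follow the YOLO-family convention: AdamW, lr 0.01,
batch 16, β₁ = 0.937 (the "momentum" parameter mapped to AdamW's first
moment; β₂ = 0.999), weight decay 5e−4. No warmup; a cosine decay and
mosaic augmentation (4-image composition with jittered centre) are
available behind flags. Early stopping is off to keep runs deterministic.

Two canonical desk-scale runs are defined in `voidnet.train`:

* **overfit sanity** — one 160×160 easy phantom, 200 epochs, lr 5e−3,
  batch 1: train loss must fall ≥90% and the image must be recovered at
  mAP50 = 1.0;
* **learning demo** — 64 easy phantoms (16 held out), 50 epochs at the
  default lr 0.01 with cosine decay, mosaic off (on tiny easy sets the
  mosaic crops destroy most of the few positives). Reaches val mAP50 ≈
  0.7–0.8 across seeds.

The nano configuration used by both (stage widths 8/16/32/48/64, ~230k
parameters, 160×160 inputs) keeps the full topology at reduced capacity so
the whole suite trains on one CPU in minutes; the topology, not the
capacity, is the contract.

## Evaluation

Greedy score-ordered matching (each prediction takes the unmatched
same-class GT of highest IoU if ≥ threshold; ties in score broken by
insertion order), cumulative precision/recall, 101-point interpolated AP
(COCO convention — the integral-under-the-PR-curve definition admits many
discretisations; the 101-point one makes numbers comparable to common
practice), mAP50 and mAP50-95 over IoU 0.50:0.05:0.95. Scalar
precision/recall are reported at the F1-maximising confidence threshold of
the evaluation set, since an operating point has to be chosen somewhere.
Everything is cross-checked against an independent brute-force reference
implementation in the tests.

## Known limitations

* The phantom's void-size and contrast distributions are assumptions, not
  estimates from clinical data; they are spec parameters and documented as
  such.
* The engine is CPU-only and single-threaded beyond BLAS; it is sized for
  the nano configuration, not for full-scale training.
* Single-head attention by default; multi-head is available but untuned.
* Boxes are axis-aligned; rotated boxes and mask losses are out of scope,
  as are GIoU/DIoU/SIoU variants and NMS-free dual-assignment training.
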