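# Methods

## Problem setting

A whole-slide image (WSI) is far too large to classify directly, and in
routine archives its only label is the slide-level diagnosis. The method
implemented here treats the slide as a bag of square tiles: every tissue
tile inherits the slide's binary label during training (weak supervision),
and the slide's prediction at inference is the **maximum** tile
probability. Max aggregation encodes the clinical asymmetry — a single
convincing carcinoma focus makes the slide malignant, whereas a benign
slide must contain *no* such focus.

## Pipeline

### Tissue detection

Tissue is separated from the near-white scanner background by Otsu's
method on the 8-bit grayscale image (BT.601 luminance weights
0.299/0.587/0.114 for RGB input). The implementation evaluates all 255
candidate thresholds of the 256-bin histogram and maximizes the
between-class variance `w0·w1·(μ0−μ1)²`, breaking ties toward the lowest
threshold; tissue is the class strictly below the threshold. A constant
image has no valid split and raises. Tiles are enumerated row-major at
origins `(i·stride, j·stride)`, fully inside the image; a tile is kept
when its tissue fraction is at least `min_tissue_frac` (default 0.1;
drops mostly-background edge tiles). Default stride equals the tile size
(non-overlapping). When `(W−T)` and `(H−T)` are multiples of the stride —
true for every configuration used here — the grid at
`min_tissue_frac = 0` covers every tissue pixel.

### Balanced sampling

Training slides enter a per-epoch shuffled queue that alternates labels.
When one label's list is exhausted first, further draws of that label are
uniform with replacement from its full list (oversampling), so alternation
— and hence exact 16/16 label balance at batch size 32 — continues until
the longer list is spent, and every slide contributes tiles each epoch.
From each drawn slide, `batch_size / num_labels` tiles are sampled
uniformly from its tile pool, without replacement when the pool is large
enough and with replacement otherwise. An epoch is one alternation pass
over the longer label list; the notion of "epoch" is otherwise undefined
under queue sampling, and this choice makes epoch length proportional to
cohort size.

### Hard-example mining

Phase 2 begins once the running-minimum validation loss has not strictly
improved (tolerance 0) within the last 2 epochs, and the transition is
one-way. The loop then alternates inference and training: slides are
visited in queue order; the model — weights frozen, batch-norm in
running-statistics mode — scores the slide's full tile grid; the k = 8
tiles most inconsistent with the slide label (highest positive probability
on benign slides, lowest on adenocarcinoma slides) are appended to a FIFO
pool; whenever the pool holds N = 256 tiles, exactly those 256 are
released in arrival order and trained on in batches of 32, as released
(release is defined purely by count, so mined batches are not re-balanced).
Ties in the top-/bottom-k selection break by row-major tile order (y, then
x) for determinism. One slide per inference step bounds memory; the pool
is JSON-checkpointable for resumable runs.

### Optimization

Adam with β₁ = 0.9, β₂ = 0.999, initial learning rate 10⁻³, decayed by
0.95 every 2 epochs (`lr(e) = 10⁻³·0.95^⌊e/2⌋`, e 0-based), binary
cross-entropy on a single logistic logit (equivalent to a two-column
softmax; one logit is simpler). No gradient clipping. Early stopping ends
training after 10 epochs without a new validation-loss minimum, capped at
`max_epochs` (default 100), and the lowest-validation-loss checkpoint is
returned. The validation loss is the mean tile BCE over a fixed, seeded
subsample of up to 64 tiles per validation slide — fixed across epochs so
the early-stopping signal is not resampling noise; probabilities are
clipped to `[1e−7, 1−1e−7]` inside the loss.

**Partial fine-tuning.** With a pretrained backbone only the
normalization layers' scale/shift and the final classifier's weight/bias
are trainable; convolutions stay bit-identical for the whole run (verified
by test). Full training is a config switch and is the mode used for the
synthetic experiments, since no pretrained weights ship with the package.
Batch-norm running statistics are buffers, not parameters, and continue to
update in training mode in either case.

### Backbone

No deep-learning framework is assumed: the bundled backbone is a numpy
CNN — three stride-2 3×3 conv/batch-norm/ReLU blocks (8/16/32 channels),
global average pooling, and a one-logit linear head — with hand-written
backpropagation validated against central finite differences, He
initialization, and batch-norm eps 10⁻⁵ / momentum 0.1. Evaluation mode
uses running statistics, making inference independent of batch
composition (asserted to 10⁻⁶). The backbone contract is only "named,
kind-tagged parameters + forward/backward", so a framework-backed
EfficientNet-class network can be substituted without touching the loop;
tests exercise the tiny CNN.

### Evaluation

A slide is called positive at threshold t iff `score ≥ t` (ties positive).
The ROC sweeps all distinct scores plus sentinels (above-max → (0,0)
corner; 0 → (1,1)); TPR = TP/(TP+FN), FPR = FP/(FP+TN); AUC by the
trapezoidal rule, which equals the Mann–Whitney pairwise statistic
(ties counted half) — asserted to 10⁻⁹ against that oracle. The sweep is
implemented as one pass over the score-sorted cohort; a unit test pins it
to explicit per-threshold confusion counting. 95% CIs are percentile
bootstrap over 1000 resamples of *slides* (the metrics are slide-level, so
slides are the exchangeable unit); degenerate resamples missing a label
are redrawn so the bootstrap distribution always holds 1000 values.
Threshold-dependent metrics (accuracy, sensitivity, specificity, F1)
default to t = 0.5, exposed as a flag.

## Synthetic slides

The generator emulates exactly the properties the pipeline depends on:

- **Background** at gray 232 with σ = 1 sensor noise, separable by Otsu.
- **Tissue geometry**: `needle` cores are long thin rotated rectangles
  (aspect 8–12:1, mimicking biopsy cores); `blob` cores are unions of
  overlapping discs (TUR-P-like chips). Default 4 cores per slide.
- **Texture**: benign tissue is Gaussian-smoothed unit-variance noise
  (correlation length σ = 3 px) scaled to 18 gray levels around mean 152;
  lesion texture uses the same construction with σ = 1.2 px around mean
  `152 − texture_contrast` (default contrast 15). Pixel histograms of the
  two textures overlap heavily, so a per-pixel threshold cannot separate
  them reliably, while a CNN seeing a tile's spatial statistics can — the
  pipeline must learn texture, not a gray-level shortcut.
- **Lesion**: a connected region grown nearest-first from a random seed
  pixel within one core (spilling into further cores only when one core is
  too small), with a pixel count equal to `lesion_fraction` × tissue area
  by construction. Ground-truth lesion and tissue masks are written
  alongside the image but are read only by evaluation code; the sampling
  and training stages consume manifests without ever opening them.
- **Magnification** is nominal metadata: "10×" cohorts render at half the
  linear resolution of "20×", mirroring the two standard tiling configs
  (20×/512 px and 10×/224 px tiles; synthetic tests use 128 px tiles on
  1024 px slides, the same 8× ratio of slide to tile as a small clinical
  core at 20×).

All randomness flows from one master seed through named substreams
(CRC-keyed `SeedSequence`), so identical parameters give bit-identical
PNGs.

What the generator does **not** model: staining variation, pen ink, blur,
scanner artifacts, cautery, tissue folds, nuclear morphology. Passing
tests therefore establish that the pipeline's logic is correct and that it
can recover discriminative texture from weak labels — not that any
particular clinical performance would be achieved.

## Study conditions and observed behavior

The end-to-end tests and `scripts/acceptance.py` use a 70-slide cohort
(40 train / 10 validation / 20 test, balanced labels), 1024 px slides,
128 px tiles, lesion fraction 0.3 — sizes chosen so a full run (generation,
two-phase training, scoring, 1000-iteration bootstraps) completes in a few
minutes on one CPU while leaving tile statistics non-trivial (≈25 tissue
tiles per slide, most tiles of a positive slide benign).

Two behaviors of the method are worth stating because they are properties
of max-pooling weak supervision, not bugs:

- Tiles of benign texture inside *positive* slides carry positive labels
  during training, so the model's benign-texture probability settles near
  the benign-tile label mean (≈0.5) rather than 0. Benign slides' max
  scores then cluster just above 0.5 while positive slides reach ~0.95+:
  ranking is excellent (AUC 1.0 in the shipped run) but the default 0.5
  operating threshold yields low specificity. The threshold is a flag, and
  AUC/log-loss are the threshold-free headline numbers.
- Hard mining on positive slides selects the *lowest*-probability tiles,
  which on this generator are usually genuinely benign tissue; the
  min-validation-loss checkpoint rule is what keeps this phase from
  degrading the final model when the mined labels are noisy.

## Numerical and degenerate-input choices

- Otsu on a constant image, an all-white slide, an empty tile grid, a
  single-label cohort or queue, an empty probability map, and zero
  TPR/FPR denominators all raise informative errors rather than returning
  sentinel values.
- "Improvement" for both stopping rules means a strictly lower running
  minimum (epsilon 0).
- Probability clipping: 10⁻⁷ in the training/validation loss, 10⁻¹⁵
  default in the slide-level log loss.
- Coordinates are 0-based, half-open, x right / y down, everywhere.

## Limitations

Single-resolution TIFF/PNG input only (no pyramidal SVS/JPEG2000); binary
labels only (the queue generalizes to more labels but only the binary case
is exercised); the numpy backbone is deliberately small — it demonstrates
and tests the training contract, not state-of-the-art accuracy; no
stain normalization or color deconvolution.
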