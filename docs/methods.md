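# Methods

## Overview

`mfscnet` is a toolkit for benign/malignant (and eight-subtype)
classification of H&E-stained histopathology patches. It combines four
pieces that are usually glued together ad hoc in this literature: a
manifest layer for BreakHis-style directory trees with balanced subsetting
and stratified 7:1:2 splitting; sparse-NMF stain normalization; exact-pixel
rotation/flip augmentation of the training split; and a densely connected
convolutional backbone whose channels are re-weighted by
squeeze-and-excitation (SE) attention blocks inserted at one of three
alternative sites. A seeded synthetic H&E generator stands in for external
data so that every stage is testable end to end.

## Network model

The backbone is the standard 121-layer densely connected network:

* stem: 7×7 convolution, stride 2, 2k channels, then 3×3 max pooling,
  stride 2;
* four dense blocks of (6, 12, 24, 16) layers at growth rate k = 32; each
  layer maps the concatenation of all previous feature maps through
  BN → ReLU → 1×1 conv (4k channels) → BN → ReLU → 3×3 conv (k channels),
  so block output width is `C_in + n_layers·k`;
* transition layers between blocks: BN → ReLU → 1×1 convolution at
  compression 0.5, then 2×2 average pooling, stride 2;
* head: BN → ReLU → global average pooling → linear classifier (optionally
  with an intermediate fully connected layer, `head_width`).

Convolutions are bias-free and batch normalization contributes two
trainable parameters per channel (running statistics are buffers). With
the native 1000-way classifier this reproduces the published reference
total of 7,978,856 trainable parameters exactly, which the test suite
asserts as an external oracle for the parameter-accounting code.

### Squeeze-and-excitation attention

The plain SE squeeze is global average pooling (one scalar per channel).
The optimized squeeze used here concatenates three per-channel statistics:

* global mean over the spatial map;
* local-pool max: the maximum of the 2×2, stride-2 average-pooled map
  (maps smaller than the window fall back to the plain spatial maximum);
* spatial variance (population convention, divisor H·W).

Excitation is the usual bottleneck, `FC(3C → C/r) → ReLU → FC(C/r → C) →
sigmoid`, with reduction r = 16 by default (configurable; a bottleneck
below one unit is clamped to one with a warning), and the resulting gates
rescale channels multiplicatively. The three statistics are concatenated
rather than summed or pooled further because concatenation is the minimal
combination that leaves the excitation free to learn how to weigh them.

### Variants

Three attention variants differ only in where SE blocks sit:

* **C** — after each of the four dense-block outputs (widths 256, 512,
  1024, 1024 at defaults);
* **B** — after each of the three transition outputs (128, 256, 512);
* **A** — at all seven positions (the union of B and C).

Because SE blocks are self-contained add-ons, two structural identities
hold exactly for *every* configuration, and are enforced by tests: the
parameter overhead of A over the baseline equals the sum of B's and C's
overheads, and no overhead depends on the class count. These identities,
rather than any absolute parameter total, are the binding architecture
checks: the published per-variant totals for this family assume a
classifier-head configuration that is not reconstructible (they imply a
penultimate width inconsistent with the backbone's 1024 features), so the
`head_width` knob is exposed but defaults to the native head.

## Stain normalization

Under the Beer-Lambert law, optical density is linear in dye
concentration: `OD ≈ W c`, with `W` the 3×2 stain matrix (columns:
hematoxylin-like and eosin-like RGB absorption directions, unit norm) and
`c ≥ 0` the per-pixel concentrations. The OD transform used is
`OD = −log10((I+1)/256)`, chosen so that the integer round trip
`od_to_rgb(rgb_to_od(x)) = x` is exact.

`estimate_stain_model` fits `W` by non-negative matrix factorization with
an L1 penalty (weight `sparsity`, default 0.1) on the concentrations, over
foreground pixels only (maximum-channel OD > `od_threshold`, default
0.15). The factorization minimizes
`0.5‖OD − C Wᵀ‖² + sparsity·‖C‖₁` via multiplicative updates and is
initialized from the canonical H&E absorption directions with
concentrations from an exact two-variable NNLS; the deterministic,
per-pixel-independent initialization makes the fit invariant to pixel
order. Columns are unit-normalized and ordered hematoxylin-first (the
larger red-channel coefficient).

The per-stain concentration scale is the 99th percentile of the
concentrations over **all** pixels, not only the foreground.
Normalization maps each stain's scale onto the target's
(`c′ = c · target_scale / source_scale`, re-rendered through the target
matrix), so the full-image percentile makes renormalization of an
already-normalized image a near-fixpoint regardless of how much
background glass the image contains. Two properties and their limits:

* *Idempotence.* An already-normalized image carries the target's stain
  model by construction; re-applying normalization with that model changes
  mean concentration per stain by well under 1% (re-projection and 8-bit
  rounding only). Re-*estimating* the model from the normalized pixels
  instead incurs a 1–3° basis wobble which the decomposition amplifies —
  H&E absorption directions are strongly correlated (cosine ≈ 0.76), so
  NNLS redistributes concentration mass between stains — and idempotence
  then holds only to within roughly ±10%. This is intrinsic to
  percentile-matched stain transfer, not an implementation artifact.
* *Structure preservation.* Each stain's concentration map is multiplied
  by one positive constant, so concentration ranks are preserved wherever
  the stain is materially present (c > 0.05); near-zero pixels are
  dominated by 8-bit quantization noise. The rank of the *sum* of the two
  concentrations is not preserved when the two scale factors differ —
  that is a property of the mapping, not an error.

## Synthetic data generator

The generator emulates exactly the physics the stain module inverts:
nucleus centers from a homogeneous Poisson process at a class-specific
density (defaults 8 vs 20 nuclei per 10⁴ px² for the two-class task, a
6–24 ladder for eight classes), soft-edged disks of radius 3–6 px
(modestly larger for denser classes) carrying hematoxylin-like
concentration 0.8–1.2, a diffuse eosin-like background at 0.30 of which
80% is displaced inside nuclei (nuclei exclude cytoplasm; this also keeps
near-pure pixels of both stains present, without which the stain matrix
would not be identifiable from the image), Gaussian concentration noise
(σ = 0.02, clipped at zero), and rendering through the exact inverse of
the OD transform. Class identity is carried by nucleus density and radius
only.

What passing tests on this generator do **not** show: robustness to the
texture, magnification-dependent appearance, compression artifacts,
out-of-focus regions, pen marks, or patient-level variation of real
histopathology. The generator exists to verify the machinery (stain
recovery to cosine ≥ 0.99, learnable class signal, exact bookkeeping), not
to calibrate clinical performance.

## Training protocol

Defaults follow the tuned full-scale protocol: Adam, learning rate 1e-4,
batch size 32, 224×224 inputs, cross-entropy loss, bilinear resizing,
intensities scaled to [0, 1], no early stopping, final-epoch weights.
Training is fully seeded (weight initialization and batch order), so
identically configured runs reproduce bit-for-bit. After the last epoch a
precise-BN pass re-estimates every batch-normalization layer's statistics
under the final weights (cumulative average of batch moments over the
training set): during training each batch is normalized by its own
statistics while the running averages trail the moving weights, and on
small datasets that gap is large enough to corrupt inference.

The learnability smoke test trains a reduced variant A (growth rate 8,
blocks (2, 2, 2, 2), r = 8) on 200 synthetic 64 px two-class patches for
up to 50 epochs at learning rate 1e-3 (the practitioner default for a
network this small; 1e-4 is tuned for the full-scale model) and requires
≥ 95% training accuracy plus exact reproduction under the same seed.
Problem sizes throughout the test suite (patch sizes 32–128 px, tens to
hundreds of images, reduced block configurations) are chosen so the whole
suite runs on one CPU core in minutes.

Splits are stratified by the task's class label with largest-remainder
rounding, which makes the 7:1:2 contract exact (4,000 records →
2,800/400/800). Patient identity is not modeled: records are split
independently, so on real multi-patch-per-patient data the protocol
leaks patient-level information between splits — a known caveat of this
experimental design. The stain-normalization target defaults to the first
training image in manifest order, and augmentation (default
{rot90, rot180, rot270, hflip, vflip}; right angles only, so labels and
pixels are exact) is applied to the train split only.

## Evaluation

Accuracy, precision, recall and F1 come from the per-class confusion
tallies, with zero-denominator cases defined as 0 (logged, not raised —
small runs can produce empty prediction classes). The AUC is the
Mann-Whitney pair statistic with half-credit ties, computed from midranks;
tests verify it against exhaustive pair enumeration and an independent
library implementation. Multiclass summaries are macro averages (accuracy
is the overall fraction correct), and multiclass AUC is macro one-vs-rest
over classes present in the truth labels (absent classes are excluded with
a warning).

## Numerical engine

The networks run on a small reverse-mode automatic-differentiation engine
over numpy arrays written for this package: broadcast arithmetic, matmul,
ReLU/sigmoid, reductions, concatenation, 2-D convolution (im2col + BLAS),
average/max pooling, and a fused softmax cross-entropy. Convolution caches
its column matrix only while gradients are enabled; `backward()` releases
closures and parent links after propagation so per-step memory is flat.
Gradients of every layer are verified against central finite differences.
Determinism holds to bit level for fixed seeds on a fixed BLAS; summation
order in the NMF means stain models are reproducible to ~1e-14 under
pixel permutation rather than bitwise.

## Known limitations

* No patient-aware splitting (see above).
* Stain estimation assumes exactly two stains and breaks on images with
  < 100 foreground pixels (raised as an error with advice).
* Mapping a weakly stained image onto a much more strongly stained
  target can saturate nucleus cores (intensity clipped at 0), degrading
  any subsequent re-estimation of its stain model.
* The pruning that is sometimes applied to dense networks is out of
  scope, as are competing backbone families.
* CPU-only: full-scale 224 px training of the default architecture is
  orders of magnitude slower than on accelerator hardware; the package
  targets correctness and small-scale experiments.
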