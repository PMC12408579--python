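# Methods

This note records what the package implements, the conventions behind the
numbers it prints, and the limits of what the included experiments can show.

## Problem setting

Given an RGB image containing many very small, roughly elliptical dark
objects (a few pixels across) on a textured background, the task is to
predict a per-pixel probability that the pixel belongs to an object, and to
derive object detections and a count from that map by thresholding and
connected-component analysis. Supervision comes from bounding boxes only:
the training loss needs one center pixel and the box outline per object,
never a full segmentation mask.

## Model

The network is fully convolutional and processes one image at a time
(batch size 1). Feature maps are unbatched `(C, H, W)` float32 arrays.

**Backbone (PartialNeXt).** A ConvNeXtV2-style hierarchy: a 4×4/stride-4
stem with channel layer normalization, four stages with depths
`(2, 2, 8, 2)` and widths `(80, 160, 320, 640)` at full scale, and 2×2
stride-2 downsampling between stages. Each block is a 7×7 spatial mixer →
LayerNorm → pointwise expansion (4×) → GELU → global response
normalization (GRN) → pointwise projection, with a residual connection.
The spatial mixer is the switchable element: either a depthwise 7×7
convolution, or a *partial* convolution that applies a dense 7×7
convolution to the first quarter of the channels and passes the rest
through unchanged. The partial variant increases parameters and MACs
(quantified by `tcdnet profile` and the acceptance script) while touching
only a quarter of the channels per block.

**Hybrid attention.** Each backbone output level passes through
`SA(CA(f)) + f`. Channel attention pools the map both globally and to an
`ls×ls` grid (`ls` = 32/16/8/4 for C2…C5), runs a shared 3-tap 1-D
convolution along the channel axis on both pooled maps, adds them, and
gates with one sigmoid. Spatial attention concatenates the channel-wise
mean and maximum and reduces them with a 3×3 convolution to one sigmoid
gate. Each attention instance has 23 parameters; the whole mechanism is
effectively free in the parameter budget.

**Feature pyramid with adaptive fusion.** Lateral 1×1 convolutions bring
C2…C5 to a common width (256 at full scale; no 3×3 smoothing
convolutions). Top-down merging at P4/P3/P2 uses an adaptive feature
mixer: a spatial branch (1×1 conv to a hidden width, 1×1 back) plus a
broadcast channel branch (two-layer FFN on the pooled vector) produce a
sigmoid weight map `W`, and the levels blend as
`f_lateral · W + f_topdown · (1 − W)`. Each mixer has 66,176 parameters at
width 256.

**Heads and output.** Four 1×1 convolutions map P2…P5 to one channel
each; the four maps are bilinearly upsampled to the input size and summed
into a single logit map; a sigmoid yields the probability map.

## Loss

With logits `z`, probabilities `P = σ(z)`, center matrix `T_L` (one pixel
per box, at `floor` of the box midpoint) and boundary matrix `T_B`
(1-pixel box outlines; outline pixels falling inside another box's
interior are dropped):

- **Localization** `L_L = λ_L · Σ_{T_L} softplus(−z)` with `λ_L = ΣT_L`
  (the object count): every center must be foreground.
- **Boundary** `L_B = λ_B · Σ_{T_B} softplus(z)` with `λ_B = max(n−1, 0)`:
  outlines must be background, which separates touching objects; a single
  object needs no separation, hence the `n−1` weighting (an
  `inverse_count` variant is available as a configuration switch).
- **False positive** `L_F = Σ softplus(z)` over pixels of thresholded
  components (at 0.5) that contain no ground-truth center. The component
  mining is done on detached probabilities; gradients flow only through
  the penalized logits.

All three use `softplus` via `log1p`/`logaddexp` for numerical stability.
Training uses Adam (weight decay added to the gradient), random
horizontal/vertical flips applied jointly to image and supervision, and
keeps the checkpoint with the best validation F1. The small-scale recipe
uses lr 3e-4 with cosine decay to a 5% floor; the full-scale default is lr
1e-5, constant.

## Post-processing and metrics

Inference thresholds the probability map at 0.5 (inclusive), labels
4-connected components (`scipy.ndimage.label`, relabeled to row-major
first-pixel order so results are convention-independent), and reports one
detection per component with its pixel-mean centroid, area, and mean
probability as confidence. A detection is a true positive when its
centroid lies in an unclaimed ground-truth box; matching is one-to-one,
greedy in descending confidence, nearest box center on ties. Precision,
recall and F1 are micro-averaged over the dataset; counting quality is
MAE, RMSE, the standard R² (`1 − SS_res/SS_tot`) and, for comparability
with reports that use it, the variance-ratio form
`Σ(pred − mean_gt)² / Σ(gt − mean_gt)²`, which can exceed 1.

## Numerical conventions

- float32 parameters and activations; losses and metrics accumulate in
  float64.
- Convolution via im2col + GEMM (1×1 convolutions as plain matrix
  products); bilinear resize and adaptive average pooling as separable
  cached matrix pairs using the half-pixel (`align_corners=False`)
  convention; LayerNorm over channels with eps 1e-6.
- MAC profiling counts convolution/linear multiplies only (norms,
  activations, pooling, resampling excluded), and one MAC is reported as
  one FLOP — the convention under which the printed budgets of the
  reference architecture reconcile.
- Boxes are half-open `[x_min, x_max) × [y_min, y_max)` in pixel units;
  the center pixel is `floor((lo + hi − 1) / 2)` per axis.

## Synthetic scene generator

Real trap imagery is not required anywhere. The generator emulates its
statistics: a green background with a low-frequency gradient and smoothed
noise texture, a truncated-Poisson object count (mean 8.5 by default),
and rotated dark ellipses with axes 2–9 px, anti-aliased by 4×
supersampling, placed with a minimum center separation. The annotation
box of each object is the tight box of pixels with coverage ≥ 0.1, so
boxes follow the rendered shape, not the nominal ellipse. Everything is
reproducible from one integer seed.

## Benchmark problem sizes

The end-to-end training benchmark (`tcdnet.bench`) is sized for minutes
on a single CPU core, since the package carries its own NumPy autodiff
rather than a compiled framework: width-reduced model (widths
40/80/160/320, depths 2/2/4/2, pyramid width 128) on 128×128 scenes with
at most 12 objects, bilinearly upsampled 2× to 256×256 before training,
32 training and 12 validation images, 40 epochs. The upsampling step
exists because error analysis showed misses concentrate entirely on the
smallest objects (≈3×3 boxes), whose single interior pixel sits below
the effective resolution of the stride-4 heads; doubling the input
resolution relative to the object size is the training-time counterpart
of running large native inputs, and raised recall without touching the
detection threshold or the generator. Loss-ablation runs reuse the
pipeline at 12/6 images: 20 epochs for the full-loss vs. no-`L_F`
false-positive comparison, 4 epochs for the `L_L`-only degeneracy check.
The acceptance script (`scripts/acceptance.py`) recomputes all reported
quantities from a single command-line seed.

## Limitations

- Single-image batches only; no GPU path; full-scale (1280²) training is
  out of reach for the bundled NumPy engine, which is intended for
  correctness and small-scale experiments, not throughput.
- The synthetic generator covers the tiny-dark-object regime only; it is
  not a stand-in for real trap imagery (occlusion, debris, specular
  lighting are absent), so benchmark scores are an internal sanity
  surface, not a claim about field performance.
- Profiling counts conv/linear MACs only; memory traffic and
  normalization costs are not modeled.
- The greedy confidence-ordered matcher is not a maximum-cardinality
  matcher; with overlapping boxes it can differ from the optimum by a
  small amount (the test suite bounds this on random problems).
- On these distractor-free synthetic scenes, removing the false-positive
  loss term does not measurably increase false positives: both loss
  variants converge to near-zero FP counts (the benchmark reports both).
  The term's documented benefit presupposes FP-prone background
  structure — debris, dirt, non-target objects — which the generator
  deliberately does not model; demonstrating that degeneracy would
  require distractor-bearing scenes.
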