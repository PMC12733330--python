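# Methods

## Problem setting

Six-way classification of corn-kernel images (normal plus five defect
classes), under a data regime of ~1000 images per class, 224×224 RGB.
Two components address the scarcity: a gradient-penalty Wasserstein GAN
that widens the training distribution with synthetic kernels, and a
compact multi-scale classifier.  This note records the models as
implemented, the parameters that matter, and the choices made where the
design was genuinely open.

## Tensor engine

All networks run on `grainforge.nn`, a reverse-mode autodiff engine over
numpy arrays.  Design points:

- Every primitive's vector–Jacobian products are themselves built from
  primitives, so `grad(..., create_graph=True)` yields differentiable
  gradients.  The critic objective differentiates an input-gradient norm
  with respect to the critic weights; this double backward traverses
  `conv2d` ↔ `conv_transpose2d` (each is the other's input-vjp) and
  terminal weight-correlation primitives.  Third-order derivatives are
  not supported and not needed.
- Convolutions are im2col/col2im with grouped matmuls; float32 for
  training, float64 in gradient-check tests (central differences are
  unreliable in float32).
- Correctness is established by finite-difference oracles for conv,
  transposed conv, normalisation layers, max-pooling and the
  double-backward composition itself.

## Generator and critic

Generator: 100-d standard-normal latent → dense projection to a
7×7×512 map → five stride-2 transposed-conv stages
(512→256→128→64→32→3), ReLU hidden activations, tanh output in [−1,1].
The 28→56 and 56→112 stages are *GSCSA blocks*:
`y = ReLU(BN(ConvT(x + SCSA(x))))` — attention inside an identity skip,
then upsampling.  Which stages to replace is an open choice; mid-ladder
positions act on maps small enough for attention to be cheap but large
enough to carry spatial structure.  Transposed convs use kernel 4,
stride 2, padding 1 (the exact-doubling configuration).

SCSA composes two gates serially.  The spatial half (SMSA) pools the map
along each axis, splits channels into 4 groups, applies one depthwise
1-D conv per group (kernel sizes 3/5/7/9, shared between the H- and
W-pooled sequences), group-normalises, and sigmoid-gates both axes.  The
channel half (PCSA) average-pools to a p×p grid (p = 7, reduced to the
largest divisor of the map size when needed), forms depthwise Q/K/V over
the flattened grid, applies single-head channel-by-channel softmax
attention scaled by 1/√p², pools to one pixel and sigmoid-gates each
channel.  Both halves only attenuate (gates in (0,1)); with zeroed
weights the module multiplies its input by exactly 0.25 · 0.5 = 0.125, a
property the tests pin down.

Critic: six 3×3 stride-2 convolutions (LeakyReLU 0.2), a 3×3
convolutional scoring head and a spatial mean — no dense layers, scores
unbounded.  Batch normalisation after stages 2–6 is the default, with a
config switch to instance norm or none.

## Losses and training

Duality-form Wasserstein losses with gradient penalty λ = 10 (the
canonical value; the source configuration names only optimizers and
epochs), interpolation coefficient drawn once per sample, gradient norm
over all input coordinates.  `‖∇‖` is floored at 1e-12 before the square
root so an exactly-vanishing gradient cannot produce infinities in the
backward pass.  Critic:generator update ratio 5:1; Adam betas
(0.5, 0.999), fixed learning rates 1e-4 (G) / 2e-4 (D), batch 64,
checkpoints every 10 epochs scored by FID against the training
distribution under the configured embedder, minimum-FID checkpoint kept.

**Smoke scale.**  The test suite trains on 120 synthetic 64×64 images for
20 epochs at batch 16 — about 140 update steps.  Three adjustments make
this regime meaningful, packaged as `smoke_*_config()`:

- *norm-free critic*: batch/instance normalisation removes per-batch or
  per-sample colour statistics, which at this scale are the dominant
  real/fake signal (measured critic separation with BN: ~0.005);
- *n_critic = 1*: at 7 batches per epoch the canonical 5:1 ratio leaves
  the generator ~28 updates total;
- *learning rates 1e-3/2e-3*, preserving the 1:2 generator:critic ratio.

Under this configuration the selected checkpoint's toy-embedder FID beats
the untrained generator in 5/5 seeds; full-scale defaults are unchanged.

## MACRNet

Stem 7×7/2 (3→64, BN, GELU).  Stage channel chain fixed to
64→128→256→512→1024; stage 1 runs at 112² and enters through a stride-1
"convolutional" residual block (1×1-projection skip, 64→128), stages 2–4
enter through stride-2 "downsampling" blocks; all other blocks are
identity-skip "maintaining" blocks.  No stem max-pool: the budget
calibration is feasible without one, and the three-block-type reading
covers the 112² stage naturally.  Head: global average pool over the
1024 channels, dropout 0.2, linear to 6 classes.

Each block's branch widths sum to its output channels: the 1×1 branch
takes one third (plus rounding remainder), the four asymmetric branches
split the rest equally.  An asymmetric branch is pointwise →
depthwise k×1 → depthwise 1×k → pointwise, with hidden width
`round(m · branch_width)`; the multiplier m is the calibration's
continuous knob.  Concatenate → BN → GELU → add skip.  Downsampling
blocks stride the depthwise pair ((k,1)-conv strides vertically, the
(1,k)-conv horizontally) and use a strided 1×1 skip.

**Calibration.**  Stage depths d₁..d₄ ∈ {1..6} and m on a 0.001 grid are
searched exhaustively (parameter count is affine in m per depth choice,
so m is solved for the parameter target and refined locally), minimising
the maximum relative error against the published budget.  Result:
depths (2, 2, 6, 5), m = 1.115 → 8.442822 M parameters and
4.543750 G MACs (0.04 % from 8.446 M / 4.542 G); frozen in
`grainforge/configs/macrnet_reference.yaml`.  The search is deterministic
with lexicographic tie-breaks.

**Counting conventions.**  Parameters: every trainable scalar (conv
kernels, norm affine pairs, linear weights and biases).  MACs: conv
= k_h·k_w·(C_in/groups)·C_out·H_out·W_out, linear = in·out;
normalisation, activations, pooling and biases cost zero.  Under this
convention the 18-layer residual baseline counts 1.8136 G at 224²,
matching the published 1.826 G within 0.7 % — the counter's external
anchor.

**Ablation.**  `remove_branch(cfg, k)` deletes one asymmetric branch and
redistributes its width proportionally over the survivors (total width —
and hence parameter count — stays nearly constant, consistent with the
near-identical published ablation budgets).  The exact redistribution
rule used originally is unknown; proportional is a documented choice.

**Classifier training.**  Adam (0.9, 0.999), lr 1e-3 cosine-annealed to
1e-6, weight decay 1e-4, cross-entropy, dropout 0.2 before the head,
batch 64, 120 epochs at full scale; best-validation-accuracy weights are
returned (snapshots include BN running statistics).  The smoke
configuration (32² inputs, 16/24/48/48/64 channels, depth 1 per stage,
m = 0.5) memorises 60 images to 100 % training accuracy in 200 epochs —
a capacity/optimisation sanity check, not a generalisation claim.

## Metrics

- **IS**: rows are per-image conditional class distributions; contiguous
  split groups (default 10), per-split marginal, natural log, 0·log 0 = 0;
  mean and std over splits.  Bounds 1 ≤ IS ≤ K.
- **FID**: unbiased covariance (n−1); matrix square root by the Schur
  method; imaginary residue above 1e-6 is an error, below is discarded;
  values in (−1e-6, 0) clamp to 0 with a warning.  The evaluation driver
  refuses mismatched real/generated sample counts unless overridden.
- **Embedders** are pluggable.  The deterministic toy embedder (8-d:
  per-channel means and stds, downsampled-grayscale mean and std) makes
  the whole pipeline testable offline; it is sensitive to colour and
  coarse texture only, so smoke-scale FID statements say nothing about
  perceptual quality at full scale.  A 2048-d pool3-style embedder plugs
  into the same `feature_stats`/`fid` interface when available.
- **Run statistics**: stderr = std/√n rounded half-up to 3 decimals, CI
  half-width t·stderr rounded to 3 decimals, bounds to 2 — decimal
  arithmetic at each step, which reproduces the published three-run
  interval rows exactly.

## Synthetic data

`make_synthetic_kernel_set` draws, per image, an ellipse (jittered axes,
rotation, centre) on a warm-tan background with radial shading, additive
Gaussian noise (σ = 0.015) and a class signature: NOR smooth warm
yellow; MY dark green-gray spots (12–20); BN a planar cut removing one
end; AP 3–5 small dark boreholes; FM pale pink-white streaks; HD a
global red-brown base-colour shift.  Colours were set so the pooled
channel means sit near the real-data normalisation constants
(measured (0.603, 0.568, 0.365) vs (0.647, 0.638, 0.448), all within
0.15) and so mold spots force mean luminance MY < NOR.  The classes are
separable by colour statistics alone (nearest-centroid on pixel
mean+variance: ~0.72 on a fresh seed, chance 1/6) — enough signal for
split/training/metric machinery, but none of the intra-class photometric
complexity of real kernels: passing smoke tests demonstrates the
machinery, not field performance.

## Determinism and sizes

Every stochastic component takes a seed or Generator; the CLI fans one
top-level seed into named substreams (SHA-256 of `seed:name`).  Identical
seeds give identical splits, augmentations, weights and loss traces in
single-threaded execution.  Problem sizes in the test suite — 32²/64²
images, narrow channel widths, ≤ 200 epochs — are chosen so the whole
suite runs on one CPU in minutes.

## Known limitations

- The SCSA internals follow the published block diagram at the level of
  pooling/grouped-1-D-conv/self-attention structure; where the diagram
  is silent (shared vs per-direction kernels, Q/K/V kernel size 3) the
  choices here are documented, not claimed authoritative.
- BN in the critic is kept as the full-scale default for fidelity even
  though gradient-penalty objectives conventionally avoid it; the
  `norm` switch exists precisely because this interaction is unresolved.
- Full-scale (224², 1600-epoch) GAN training is far outside a CPU
  budget; nothing here validates generation quality at that scale.
- The calibrated stage depths/widths reproduce the published compute
  budget, not necessarily the authors' exact architecture: different
  (depths, m) combinations can meet the same budget.
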