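# grainforge

Recognition of imperfect corn kernels when labelled images are scarce.

In grain grading, kernels are sorted into a normal class (NOR) and five
defect classes — pest-attacked (AP), broken (BN), fusarium-infected (FM),
heat-damaged (HD) and moldy (MY).  Deep classifiers degrade sharply when
only ~10³ images per class are available.  `grainforge` implements a
two-stage countermeasure:

1. **Generative augmentation.**  A Wasserstein GAN with gradient penalty
   whose generator carries residual *spatial–channel synergistic
   attention* (SCSA) blocks between transposed-convolution upsampling
   stages, so the synthesis focuses on the small, local defect patterns
   that distinguish the classes.  The critic is fully convolutional (six
   stride-2 stages, no dense layers) and is trained on the duality-form
   objective

   ```
   L_D = E[-D(x)] + E[D(G(z))] + λ E[(‖∇_x̂ D(x̂)‖₂ − 1)²],   L_G = −E[D(G(z))]
   ```

   with x̂ = εx + (1−ε)G(z), ε ~ U[0,1] per sample, λ = 10.  Weights are
   checkpointed every 10 epochs and the checkpoint with the minimum FID
   against the training distribution is kept.

2. **Multi-scale asymmetric classification (MACRNet).**  A residual
   network whose core block runs five parallel branches — a 1×1 pointwise
   branch and, for k ∈ {3,5,7,9}, a depthwise-separable k×1 ∘ 1×k pair —
   concatenated, batch-normalised, GELU-activated and added to the skip
   path.  Small kernels capture mold spots and micro-cracks, large ones
   global kernel morphology.  The published compute budget (8.446 M
   parameters, 4.542 G MACs at 224²) pins neither stage depths nor branch
   hidden widths, so a deterministic calibration search recovers a
   configuration matching the budget to 0.04 % and freezes it as the
   reference network.

The evaluation stack implements the Inception Score
`IS = exp(E_x KL(p(y|x) ‖ p(y)))`, the Fréchet distance
`FID = ‖μ_r−μ_g‖² + Tr(Σ_r+Σ_g−2(Σ_rΣ_g)^{1/2})` with a pluggable
embedder, macro precision/recall/F1 from the 6×6 confusion matrix,
three-run t-interval statistics (t = 4.303) and parameter/MAC accounting.

Everything — including the networks — runs on a small numpy tensor engine
with reverse-mode autodiff shipped inside the package (`grainforge.nn`);
the engine supports the double backward pass the gradient penalty needs.
A procedural six-class synthetic kernel-image generator provides labelled
fixtures with per-class colour/texture signatures, so the whole pipeline
is exercisable offline on a single CPU.

## Worked example

Generate a fixture, reproduce report statistics, calibrate the reference
network and run a smoke-scale GAN training (all CPU-only):

```
$ grainforge synth --n-per-class 10 --seed 0 --image-size 64 --out data/
wrote 60 images (10/class) to data

$ grainforge stats --means-stds table.csv --t 4.303
InceptionNeXt: mean 97.293 stderr 0.026 CI 97.18-97.41
VAN: mean 94.882 stderr 0.044 CI 94.69-95.07

$ grainforge calibrate --out calib/
calibration ok: params 8.443 M (err 0.04%), macs 4.544 G (err 0.04%)

$ grainforge ablate --remove 7 --out abl/
remove 7x1/1x7: 8.423 M params, 4.465 G MACs

$ grainforge train-gan --epochs 20 --batch-size 16 --image-size 64 \
      --n-per-class 20 --seed 0 --out gan/
best checkpoint: epoch 20, FID 0.0599
```

The `stats` lines are the 95 % confidence intervals of three-run accuracy
summaries under a t-distribution with two degrees of freedom.  The
`calibrate` line reports the frozen reference configuration's parameter
and multiply–accumulate counts against the published budget.  The
`train-gan` FID (toy embedder, 8-d colour/texture statistics) is the
minimum over the run's checkpoints; the untrained generator scores ≈ 0.14
on the same data, so the augmentation stage demonstrably learns the
target colour statistics even at smoke scale.  Further subcommands:
`generate` (sample a trained generator), `train-clf` (classifier training
on the OD/GD/NGD/MD augmentation variants), `evaluate` (FID/IS reports
between image folders).

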