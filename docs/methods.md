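# Methods

## Problem and model

The package segments pancreatic tumors on 2D axial CT slices with a
two-stage cascade.  Stage 1 is a pancreas segmenter over the full slice;
its probability map P both *crops* the slice (binarize at 0.5, minimal
bounding box of the support, K-pixel margin, clamp to the image) and
*re-weights* the cropped intensities through the salient-change coupling
`x₂ = crop(x) ⊙ (ε + (1−ε)·crop(P))`, ε = 0.5.  Because the coupling is
differentiable, stage-2 losses backpropagate into stage-1 parameters —
the property that distinguishes this cascade from separately trained
two-stage pipelines.  Stage 2 segments the tumor inside the resized crop.

### Backbone (both stages)

A dual-encoder multi-scale U-Net.  Each of four contraction blocks runs
two branches on the same input: branch 1 applies 3×3∘3×3; branch 2 applies
1×1→3×3 and 5×5→3×3 in parallel and concatenates (a 1×1 fuse restores the
block width).  Both branches end in 2×2 max pooling.  The central layer
combines the deepest branch outputs through 1×1→3×3, 3×3→3×3 and 5×5→3×3
paths.  The decoder upsamples with stride-2 transposed convolutions and
concatenates *two* skips per level, one from each encoder branch; the
finest level's skips are the input image itself, mirroring how the
encoder chains start from the image.

Widths are config-driven; the published architecture does not print them.
The package's plan: block i outputs `base·2^(i−1)` channels (i = 1..4),
central paths are `8·base` wide and fuse to `16·base`, the decoder halves
back down to `base`.  Defaults: base 32; the test suite and the
desk-scale protocol use base 8.

Every convolution carries normalization + ReLU.  Normalization uses
per-channel batch moments at **both** train and test time: batch size is
fixed at 1, so this is instance-style normalization, keeps inference
deterministic, and avoids maintaining running statistics in a functional
parameterization.  A config switch (`norm: affine`) bypasses moment
normalization, which the hand-arithmetic tests use.

Prediction heads (stage-1 head, localization head, focusing heads) are
initialized with bias −2: foreground is rare in this problem, and an
initial foreground probability of ~0.12 rather than 0.5 substantially
speeds Dice/BCE convergence on small targets.

### Non-local localization

On the coarsest stage-2 feature level (N = H·W positions is small there).
Channel attention uses no learned projections: with A the C×N reshaped
features, `X = softmax_rows(A·Aᵀ)` and `F' = γ_c·(X·A) + F`.  Spatial
attention derives Q', K' by 1×1 convolutions to `C₁ = max(1, C/8)`
channels and V' at full width; for each output position the softmax
weights over source positions sum to 1 (the published index convention is
internally inconsistent; the standard non-local orientation is used and
verified against a nested-loop oracle).  Both scales γ init to 1; setting
both to 0 makes the module exactly its 7×7 prediction head, which the
tests exploit as an identity check.  Softmax is max-stabilized.

### Focusing modules

Four, one per remaining decoder level, coarse to fine.  The higher-level
prediction (logistic-squashed — the two-class softmax of a logit against
zero, keeping the [0,1] attention semantics for a single-channel map)
splits current-level features into `F_fa = F_c⊙a` and `F_ba = F_c⊙(1−a)`,
so `F_fa + F_ba = F_c` identically.  Two *separate* context-exploration
blocks mine false-positive interference from `F_fa` and false-negative
interference from `F_ba`.  A context-exploration block chains four
branches (3×3 reduce → K_i×K_i local → 3×3 dilated at rate r_i, K =
1,3,5,7, r = 1,2,4,8, all with BN+ReLU); branch i's output is **added** to
branch i+1's reduced input (concatenation is available by config — the
published wording "input the output of the i-th module into the i+1-th"
admits either), so the receptive field grows strictly: 5, 11, 23, 45
pixels along the chain.  Refinement follows
`F_up = U(CBR(F_h))`, `F_r = BR(F_up − λ·F_fpd)`, `F_r' = BR(F_r + γ·F_fnd)`
with bilinear U and λ, γ learnable (init 1).

### Losses

* Stage 1: soft Dice with ε = 1e-6 smoothing.
* Localization: `BCE + (1 − IoU)` on probabilities.
* Focusing: boundary-weighted BCE + IoU with weight map
  `w = 1 + μ·|meanpool₁₅(g) − g|`, μ = 5.  The mean pool replicates edges
  so a constant reference yields w ≡ 1 exactly and the loss reduces to
  the plain form.  The weighted-loss structure follows the standard
  salient/camouflaged-object formulation; the published text does not
  define it.
* Deep supervision: the stage-2 total is
  `L_pm + Σᵢ wᵢ·L_fm^i`, wᵢ = 4, 2, 1, 0.5 coarse→fine (the printed
  weight expression is unreadable; 2^(4−i) is adopted and config-exposed).
  All five stage-2 maps are bilinearly upsampled to the crop resolution
  before supervision, so a single reference resolution is used.
* ISB penalty: boundaries are counted as 4-adjacent pixel pairs with
  differing labels; the perimeter `l_i` additionally counts image-border
  edges of class-i pixels, but no shared term does, so row sums of the
  matrix never exceed 1.  `L_isb` is the MSE between predicted and
  reference matrices over n_c² entries.  It is evaluated on argmax-hard
  labels (ties break to the lowest class), hence non-differentiable: it
  is computed outside the gradient tape and added to the *reported*
  total `L = L_seg1 + α·L_seg2 + β·L_isb` (α = 0.9, β = 0.4).  The
  pipeline uses n_c = 2; the machinery is written for general n_c.

### Training schedule

S (2 epochs): saliency coupling off, crops from the ground-truth pancreas
box; no stage-2 gradient reaches stage 1.  I (4 epochs): coupling on,
still ground-truth crops.  J (50 epochs): crops from the stage-1
prediction — identical to inference.  (The published description of step
J is self-contradictory about the crop source; the stage-1 reading is
used for consistency with the crop definition.)  Optimizer: SGD, momentum
0.9, lr 1e-5, weight decay 1e-7, batch size 1; optimizer state persists
across steps.  An all-background P falls back to a full-image crop so
inference never fails.

## Numerical backend

Networks are pure functions of a flat float64 parameter vector;
reverse-mode differentiation is delegated to `autograd`.  Convolution
(stride 1, arbitrary dilation), 2×2 transposed convolution, 2×2 max
pooling (first-max tie break) and bilinear resampling (half-pixel-center
convention) are registered primitives with hand-written VJPs, each
verified against central finite differences to ~1e-9.  Bilinear resizing
is expressed as two cached interpolation matrices, making its adjoint
exact.  Nearest-neighbour resizing is reserved for label maps.

## Phantom generator

Emulates the stated difficulties of the real task: a pancreas ellipse
(2–8% of the image) at mean intensity 0.50 on a textured background
(mean 0.35, low-pass-filtered noise of amplitude 0.02), containing a
tumor ellipse (0.2–2% of the image) at contrast +0.05, with i.i.d.
Gaussian noise σ = 0.03 and clamping to [0,1].  Masks are exact
pre-noise ellipse supports (a pixel belongs to an ellipse iff its center
satisfies the inequality).  Ellipses are resampled until the rasterized
area respects the configured bounds (±20% on the bound) and the tumor is
fully nested in the pancreas; a case places the tumor on a contiguous
slice subrange.  Generation is a pure function of (config, seed).

What the phantom does **not** model: anatomical shape variability, organ
neighbours with pancreas-like intensity, CT physics (beam hardening, HU
calibration), partial-volume boundaries, or tumors extending outside the
organ.  Tests passing on phantoms therefore demonstrate that the
machinery — cascade coupling, attention, focusing, losses, schedule — is
implemented correctly and can be optimized end to end; they do not
predict clinical segmentation accuracy.

## Desk-scale protocol and problem sizes

The published benchmarks require external datasets and GPU-scale
training, so the package's own verification runs a slim configuration:
base 8 channels, 64×64 slices, 48×48 second stage, 4 phantom training
slices, schedule 2/4/200 with lr 1e-3 for the extended joint step.  Under
this protocol the cascade reaches training tumor Dice > 0.9 (typically
≈ 1.0), and `scripts/acceptance.py` reproduces the numbers from scratch.
The schedule-contract tests use 32×32 phantoms with the published 2/4/50
epoch counts.

## Known limitations

* Batch size is fixed at 1 end to end (as published); the normalization
  choice above is tied to that.
* The ISB penalty contributes no gradient (argmax is non-differentiable;
  the publication does not address this); it acts as a monitored
  regularizer in the reported total only.
* CT windowing for real NIfTI data defaults to per-volume min-max and is
  config-overridable; the publication does not state its windowing.
* Stage 2 sees a single probability-weighted channel; a two-channel
  (raw + weighted) variant is left to configuration.
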