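# pancseg

Cascaded coarse-to-fine segmentation of the pancreas and pancreatic tumors
on 2D CT slices.

Pancreatic tumors are hard targets for automatic segmentation: they occupy
a tiny fraction of an abdominal CT slice, show low contrast against the
surrounding pancreas, and have indistinct boundaries, so single-stage
networks produce both false positives and under-segmentation.  `pancseg`
implements a two-stage cascade that mirrors how a radiologist works: first
find the pancreas, then search inside it.

* **Stage 1** segments the pancreas on the full slice with a *multi-scale
  U-Net*: two encoder branches per block (plain 3×3 convolutions vs
  parallel 1×1→3×3 and 5×5→3×3 paths), a fused central layer, and a
  decoder with two skip connections per level.
* **Salient-change coupling**: the stage-1 probability map P is binarized,
  the minimal box around its support (plus a K-pixel margin) crops the
  slice, and the cropped image is re-weighted by `ε + (1−ε)·P`, so both
  stages train jointly by backpropagation.
* **Stage 2** segments the tumor inside the crop: a second multi-scale
  U-Net extracts five feature levels; a **non-local localization module**
  (channel attention then spatial attention, each residual with a
  learnable scale, followed by a 7×7 head) finds the approximate tumor
  region at the coarsest level; four **focusing modules** then refine it
  level by level, splitting features into foreground/background-attended
  parts, mining false-positive and false-negative interference with
  chained dilated context-exploration branches (K = 1,3,5,7; rates
  1,2,4,8), and removing it:
  `F_r = BR(F_up − λ·F_fpd)`, `F_r' = BR(F_r + γ·F_fnd)`.
* **Losses**: Dice loss for stage 1; BCE+IoU for the localization output
  and boundary-weighted BCE+IoU for the four focusing outputs (deep
  supervision weights 4, 2, 1, 0.5); plus an **inter-class shared-boundary
  (ISB) penalty** — the matrix `m_isb(i,j) = l_ij / l_i` of shared-boundary
  length over class perimeter, compared between prediction and ground
  truth by MSE — which amplifies boundary errors on small objects.  Total:
  `L = L_seg1 + α·L_seg2 + β·L_isb` with α = 0.9, β = 0.4.
* **Training schedule**: three steps S → I → J (2/4/50 epochs; SGD,
  lr 1e-5, momentum 0.9, weight decay 1e-7, batch 1).  S trains the stages
  separately with ground-truth crops, I switches the saliency coupling on,
  J crops from the model's own stage-1 output, matching test time.

The networks run on numpy with reverse-mode differentiation by
[`autograd`](https://github.com/HIPS/autograd); convolution, pooling and
resampling are custom primitives with hand-written vector-Jacobian
products, so the whole cascade trains on a CPU at desk scale.

A deterministic **phantom generator** produces CT-like slices (textured
background, elliptical pancreas, a small low-contrast tumor nested inside
it) so that every component is testable without downloading datasets; a
NIfTI→PNG converter and case-level splitter handle real data.

## Worked example

```bash
pancseg gen-data --out data --n-cases 4 --image-size 64 --seed 1
pancseg train --data data --out run          # S/I/J schedule, slim default
pancseg predict --checkpoint run/model.pkl --images data --out preds
pancseg evaluate --pred preds --data data --out report
```

`evaluate` prints a per-slice/per-case/global table of Dice, sensitivity
and specificity.  At desk scale (slim model, 4 phantom training slices,
64×64 slices with a 48×48 second stage, extended joint step at lr 1e-3)
the cascade overfits its training slices and generalizes partially to
unseen phantoms; one seeded run prints:

```
train_tumor_dice      0.957      # mean Dice on the 4 training slices
train_tumor_sen       0.955
train_tumor_spe       0.9997
train_pancreas_dice   0.511      # stage-1 organ Dice after 206 epochs
holdout_tumor_dice    0.615      # 4 unseen phantom slices
```

Training Dice near 1 shows the full differentiable pipeline (both stages,
attention, focusing, deep supervision) optimizes end to end; the
holdout number reflects what a 4-slice training set can support and is
expected to be modest.

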