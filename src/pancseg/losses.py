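"""Training objectives.

Stage 1 uses soft Dice loss.  Stage 2 is deeply supervised: the
localization prediction is scored with BCE + IoU, the four focusing
predictions with boundary-weighted BCE + IoU, combined with level weights
w_i = 2^(4-i) (4, 2, 1, 0.5 from coarse to fine).  An auxiliary penalty
compares inter-class shared-boundary (ISB) matrices of the hardened
prediction and the ground truth: m_isb(i, j) is the length of the boundary
class i shares with class j divided by the perimeter of class i, which
amplifies boundary errors on small objects.  The ISB penalty is evaluated
on hard labels (argmax), so it is non-differentiable and contributes no
gradient; it enters the reported total

    L = L_seg1 + alpha * L_seg2 + beta * L_isb     (alpha=0.9, beta=0.4)

Boundary counting for the ISB matrix is edge-based: 4-adjacent pixel pairs
with differing labels are shared-boundary edges; the perimeter l_i also
counts image-border edges of class-i pixels (but no l_ij does), so row sums
never exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from scipy.ndimage import uniform_filter

EPS = 1e-6


@dataclass
class LossWeights:
    alpha: float = 0.9
    beta: float = 0.4
    mu: float = 5.0                 # boundary-emphasis strength in w = 1 + mu*|meanpool(g) - g|
    boundary_pool: int = 15         # mean-pool window for the weight map
    deep_supervision: tuple[float, float, float, float] = (4.0, 2.0, 1.0, 0.5)  # coarse->fine

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or any(w < 0 for w in self.deep_supervision):
            raise ValueError("loss weights must be non-negative")


@dataclass
class ISBMatrix:
    values: np.ndarray
    n_c: int


def _check_shapes(pred, gt):
    if np.shape(pred) != np.shape(gt):
        raise ValueError(f"shape mismatch: pred {np.shape(pred)} vs gt {np.shape(gt)}")


def dice_loss(pred_prob, gt_mask):
    """Soft Dice loss 1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    _check_shapes(pred_prob, gt_mask)
    inter = anp.sum(pred_prob * gt_mask)
    return 1.0 - (2.0 * inter + EPS) / (anp.sum(pred_prob) + anp.sum(gt_mask) + EPS)


def _bce(pred, gt, w=None):
    p = anp.clip(pred, 1e-7, 1.0 - 1e-7)
    ce = -(gt * anp.log(p) + (1.0 - gt) * anp.log(1.0 - p))
    if w is None:
        return anp.mean(ce)
    return anp.sum(w * ce) / anp.sum(w)


def localization_loss(pred, gt):
    """BCE + IoU loss on the localization prediction (probabilities)."""
    _check_shapes(pred, gt)
    inter = anp.sum(pred * gt)
    union = anp.sum(pred + gt - pred * gt)
    l_iou = 1.0 - (inter + EPS) / (union + EPS)
    return _bce(pred, gt) + l_iou


def boundary_weight_map(gt, mu: float = 5.0, pool: int = 15) -> np.ndarray:
    """w = 1 + mu * |meanpool_k(g) - g|: large near boundaries and inside
    thin structures/cavities, exactly 1 in homogeneous regions.  The mean
    pool replicates edges, so a constant map yields w == 1 everywhere."""
    g = np.asarray(gt, dtype=float)
    smooth = uniform_filter(g, size=pool, mode="nearest")
    return 1.0 + mu * np.abs(smooth - g)


def focusing_loss(pred, gt, mu: float = 5.0, pool: int = 15):
    """Boundary-weighted BCE + boundary-weighted IoU."""
    _check_shapes(pred, gt)
    w = boundary_weight_map(np.asarray(gt, dtype=float), mu=mu, pool=pool)
    inter = anp.sum(w * pred * gt)
    union = anp.sum(w * (pred + gt - pred * gt))
    l_wiou = 1.0 - (inter + EPS) / (union + EPS)
    return _bce(pred, gt, w=w) + l_wiou


def stage2_total(loc_pred, focus_preds, gt, weights: LossWeights = LossWeights()):
    """L_seg2 = L_pm + sum_i w_i * L_fm^i over the four focusing levels,
    coarse to fine.  All predictions and gt must share one shape."""
    if len(focus_preds) != 4:
        raise ValueError(f"expected 4 focusing predictions, got {len(focus_preds)}")
    total = localization_loss(loc_pred, gt)
    for w, fp in zip(weights.deep_supervision, focus_preds):
        total = total + w * focusing_loss(fp, gt, mu=weights.mu, pool=weights.boundary_pool)
    return total


def hard_labels(pred_probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class labels (1-based); ties -> lowest class."""
    pred_probs = np.asarray(pred_probs)
    if pred_probs.ndim != 3 or pred_probs.shape[0] < 2:
        raise ValueError("pred_probs must be n_c x H x W with n_c >= 2")
    return pred_probs.argmax(axis=0) + 1


def foreground_to_labels(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary pipeline: background = class 1, foreground = class 2."""
    return np.asarray(prob > threshold, dtype=np.int64) + 1


def isb_matrix(label_map: np.ndarray, n_c: int) -> ISBMatrix:
    """Inter-class shared-boundary matrix from a label map in {1..n_c}."""
    lab = np.asarray(label_map)
    if lab.min() < 1 or lab.max() > n_c:
        raise ValueError(f"labels must lie in 1..{n_c}, got range {lab.min()}..{lab.max()}")
    shared = np.zeros((n_c, n_c), dtype=float)
    border = np.zeros(n_c, dtype=float)

    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        diff = a != b
        ai = a[diff] - 1
        bi = b[diff] - 1
        np.add.at(shared, (ai, bi), 1.0)
        np.add.at(shared, (bi, ai), 1.0)
    for edge in (lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]):
        np.add.at(border, edge - 1, 1.0)

    perimeter = shared.sum(axis=1) + border  # l_i
    values = np.zeros((n_c, n_c))
    nz = perimeter > 0
    values[nz, :] = shared[nz, :] / perimeter[nz, None]
    np.fill_diagonal(values, 0.0)
    return ISBMatrix(values=values, n_c=n_c)


def isb_loss(pred_probs, gt_labels, n_c: int) -> float:
    """MSE between ISB matrices of the hardened prediction and the ground
    truth.  Evaluated on hard labels; carries no gradient."""
    pred_probs = np.asarray(pred_probs)
    if pred_probs.ndim == 2:
        pred_lab = foreground_to_labels(pred_probs)
    else:
        pred_lab = hard_labels(pred_probs)
    gt_labels = np.asarray(gt_labels)
    _check_shapes(pred_lab, gt_labels)
    m_pred = isb_matrix(pred_lab, n_c).values
    m_gt = isb_matrix(gt_labels, n_c).values
    return float(np.mean((m_pred - m_gt) ** 2))


def total_loss(l_seg1, l_seg2, l_isb, weights: LossWeights = LossWeights()):
    """L = L_seg1 + alpha * L_seg2 + beta * L_isb."""
    return l_seg1 + weights.alpha * l_seg2 + weights.beta * l_isb
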