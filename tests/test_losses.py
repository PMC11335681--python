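"""Loss closed forms, the ISB boundary metric, and its brute-force oracle."""

from unittest import mock

import numpy as np
import pytest

from pancseg import losses
from pancseg.losses import (
    LossWeights,
    boundary_weight_map,
    dice_loss,
    focusing_loss,
    foreground_to_labels,
    hard_labels,
    isb_loss,
    isb_matrix,
    localization_loss,
    stage2_total,
    total_loss,
)


def isb_oracle(labels, n_c):
    """Exhaustive 4-adjacency edge enumeration, independent of the
    vectorized implementation."""
    h, w = labels.shape
    shared = np.zeros((n_c, n_c))
    border = np.zeros(n_c)
    for r in range(h):
        for c in range(w):
            me = labels[r, c] - 1
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w:
                    other = labels[rr, cc] - 1
                    if other != me:
                        shared[me, other] += 1
                        shared[other, me] += 1
            # image-border edges count into the perimeter
            border[me] += (r == 0) + (r == h - 1) + (c == 0) + (c == w - 1)
    out = np.zeros((n_c, n_c))
    for i in range(n_c):
        li = shared[i].sum() + border[i]
        if li > 0:
            out[i] = shared[i] / li
        out[i, i] = 0.0
    return out


# ------------------------------------------------------------- dice / bce

def test_dice_loss_closed_forms():
    gt = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
    assert dice_loss(gt, gt) < 1e-6
    assert dice_loss(1.0 - gt, gt) > 1 - 1e-6
    # |X|=2, |Y|=4, |X n Y|=2  ->  1 - 4/6 = 1/3
    pred = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    assert abs(dice_loss(pred, gt) - 1.0 / 3.0) < 1e-6


def test_dice_loss_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros(3), np.zeros(4))


def test_localization_loss_single_pixel_case():
    # p=0.5, g=1: BCE = ln 2, IoU loss = 1 - 0.5/1 = 0.5
    val = float(localization_loss(np.array([[0.5]]), np.array([[1.0]])))
    assert abs(val - (np.log(2.0) + 0.5)) < 1e-6


def test_localization_loss_vanishes_at_saturation():
    gt = np.zeros((8, 8)); gt[2:5, 2:5] = 1.0
    p = 1.0 / (1.0 + np.exp(-40.0 * (2 * gt - 1)))
    assert float(localization_loss(p, gt)) < 1e-3
    assert float(localization_loss(np.random.default_rng(0).random((8, 8)), gt)) >= 0.0


# --------------------------------------------------------------- focusing

def test_focusing_loss_reduces_to_plain_on_constant_gt():
    rng = np.random.default_rng(1)
    for const in (0.0, 1.0):
        gt = np.full((10, 10), const)
        pred = rng.random((10, 10))
        assert abs(float(focusing_loss(pred, gt)) - float(localization_loss(pred, gt))) < 1e-9


def test_boundary_weights_emphasize_edges():
    gt = np.zeros((41, 41)); gt[10:31, 10:31] = 1.0
    w = boundary_weight_map(gt)
    assert w[10, 10] > w[20, 20]      # corner of the square vs deep interior
    assert w[20, 20] == 1.0           # window fully inside the square
    assert w[0, 0] == 1.0             # window fully outside


def test_focusing_loss_matches_scalar_oracle():
    """3x3 case evaluated with explicit scalar sums (mu = 5)."""
    gt = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1.0]])
    pred = np.array([[0.8, 0.2, 0.1], [0.3, 0.5, 0.4], [0.2, 0.1, 0.6]])
    mu = 5.0
    w = np.zeros((3, 3))
    for r in range(3):
        for c in range(3):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), 2)  # replicate-edge padding
                    cc = min(max(c + dc, 0), 2)
                    acc += gt[rr, cc]
            w[r, c] = 1.0 + mu * abs(acc / 9.0 - gt[r, c])
    bce = -(gt * np.log(pred) + (1 - gt) * np.log(1 - pred))
    wbce = (w * bce).sum() / w.sum()
    eps = 1e-6
    wiou = 1 - ((w * pred * gt).sum() + eps) / ((w * (pred + gt - pred * gt)).sum() + eps)
    got = float(focusing_loss(pred, gt, mu=mu, pool=3))
    assert abs(got - (wbce + wiou)) < 1e-9


# -------------------------------------------------------------- stage 2

def test_stage2_total_composition():
    rng = np.random.default_rng(2)
    gt = (rng.random((8, 8)) > 0.7).astype(float)
    loc = rng.random((8, 8))
    fps = [rng.random((8, 8)) for _ in range(4)]
    w = LossWeights()
    expected = float(localization_loss(loc, gt)) + sum(
        wi * float(focusing_loss(fp, gt)) for wi, fp in zip(w.deep_supervision, fps)
    )
    assert abs(float(stage2_total(loc, fps, gt, w)) - expected) < 1e-9
    with pytest.raises(ValueError, match="4 focusing"):
        stage2_total(loc, fps[:3], gt, w)


def test_stage2_total_unit_losses_sum_to_weights():
    """With every component loss forced to 1 the deep-supervision weights
    4, 2, 1, 0.5 give a total of 8.5."""
    with mock.patch.object(losses, "localization_loss", return_value=1.0), \
         mock.patch.object(losses, "focusing_loss", return_value=1.0):
        val = float(stage2_total(np.zeros((2, 2)), [np.zeros((2, 2))] * 4, np.zeros((2, 2))))
    assert abs(val - 8.5) < 1e-12


# ------------------------------------------------------------------- ISB

def test_hard_labels_argmax_and_ties():
    probs = np.zeros((2, 1, 3))
    probs[0, 0] = [0.9, 0.5, 0.2]
    probs[1, 0] = [0.1, 0.5, 0.8]
    assert hard_labels(probs).tolist() == [[1, 1, 2]]  # tie -> lowest class
    with pytest.raises(ValueError):
        hard_labels(np.zeros((1, 2, 2)))
    assert foreground_to_labels(np.array([[0.6, 0.4]])).tolist() == [[2, 1]]


def test_isb_matrix_single_class_is_zero():
    m = isb_matrix(np.ones((4, 4), dtype=int), n_c=2)
    assert np.array_equal(m.values, np.zeros((2, 2)))


def test_isb_matrix_worked_three_by_three():
    """Class-1 2x2 block in the corner of a 3x3 grid: l_1 = 8 (4 border +
    4 shared edges), l_12 = 4, so m(1,2) = 0.5 and m(2,1) = 4/12."""
    lab = np.full((3, 3), 2, dtype=int)
    lab[:2, :2] = 1
    m = isb_matrix(lab, n_c=2).values
    assert m[0, 1] == 0.5
    assert abs(m[1, 0] - 4.0 / 12.0) < 1e-12
    assert m[0, 0] == 0.0 and m[1, 1] == 0.0
    assert m[0, 1] != m[1, 0]  # asymmetric by construction


def test_isb_matrix_rejects_out_of_range_labels():
    with pytest.raises(ValueError, match="labels"):
        isb_matrix(np.array([[0, 1]]), n_c=2)


@pytest.mark.parametrize("n_c", [2, 3, 4])
def test_isb_matrix_matches_oracle_exactly(n_c):
    rng = np.random.default_rng(100 + n_c)
    for _ in range(60):
        lab = rng.integers(1, n_c + 1, size=(8, 8))
        got = isb_matrix(lab, n_c).values
        assert np.array_equal(got, isb_oracle(lab, n_c))
        assert (got.sum(axis=1) <= 1.0 + 1e-12).all()


def test_isb_loss_values():
    lab = np.full((3, 3), 2, dtype=int)
    lab[:2, :2] = 1
    assert isb_loss(np.eye(2)[lab - 1].transpose(2, 0, 1), lab, n_c=2) == 0.0
    # all-class-2 prediction vs the worked 3x3 gt
    pred = np.zeros((2, 3, 3)); pred[1] = 1.0
    expected = (0.5 ** 2 + (4.0 / 12.0) ** 2) / 4.0
    assert abs(isb_loss(pred, lab, n_c=2) - expected) < 1e-12
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.random((2, 5, 5))
        g = rng.integers(1, 3, size=(5, 5))
        assert 0.0 <= isb_loss(p, g, n_c=2) <= 1.0


def test_total_loss_mix():
    w = LossWeights()
    assert abs(float(total_loss(1.0, 1.0, 1.0, w)) - 2.3) < 1e-12
    assert float(total_loss(0.0, 0.0, 0.0, w)) == 0.0
    assert float(total_loss(1.0, 1.0, 1.0, LossWeights(beta=0.0))) == 1.9
    with pytest.raises(ValueError):
        LossWeights(alpha=-1.0)


def test_dice_loss_complements_dice_metric():
    from pancseg.evaluation import confusion, dice
    rng = np.random.default_rng(3)
    for _ in range(100):
        pred = (rng.random((6, 6)) > 0.5).astype(int)
        gt = (rng.random((6, 6)) > 0.5).astype(int)
        if pred.sum() + gt.sum() == 0:
            continue
        metric = dice(confusion(pred, gt))
        assert abs((1.0 - float(dice_loss(pred.astype(float), gt))) - metric) < 1e-5
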