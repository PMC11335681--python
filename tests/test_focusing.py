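"""Focusing module: attention split algebra, context exploration, Eq-style
refinement chain, interference mining."""

import copy

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad, value_and_grad

from pancseg.focusing import (
    DILATIONS,
    KERNELS,
    ContextExplorationConfig,
    FocusConfig,
    context_exploration,
    init_context_exploration,
    init_focus,
    receptive_field,
    refine,
    split_attention,
)
from pancseg.nn import ops
from pancseg.nn.flat import flatten_tree, unflatten_tree


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def test_split_reconstructs_features(rng):
    f_c = rng.normal(size=(1, 8, 16, 16))
    pred_h = rng.normal(size=(1, 1, 8, 8))
    f_fa, f_ba = split_attention(f_c, pred_h)
    assert np.abs(np.asarray(f_fa + f_ba) - f_c).max() < 1e-6


def test_split_saturation_and_symmetry(rng):
    f_c = rng.normal(size=(1, 4, 8, 8))
    f_fa, f_ba = split_attention(f_c, np.full((1, 1, 8, 8), 40.0))
    assert np.abs(np.asarray(f_ba)).max() < 1e-12
    assert np.allclose(np.asarray(f_fa), f_c)
    f_fa, f_ba = split_attention(f_c, np.zeros((1, 1, 8, 8)))
    assert np.allclose(np.asarray(f_fa), f_c / 2)
    assert np.allclose(np.asarray(f_ba), f_c / 2)


def test_split_rejects_bad_resolution_ratio(rng):
    with pytest.raises(ValueError, match="resolution"):
        split_attention(rng.normal(size=(1, 4, 16, 16)), np.zeros((1, 1, 4, 4)))


def test_context_exploration_preserves_space(rng):
    cfg = ContextExplorationConfig(8)
    p = init_context_exploration(rng, cfg)
    out = context_exploration(p, rng.normal(size=(1, 8, 11, 13)), cfg)
    assert out.shape == (1, 8, 11, 13)


def _positive_identityish(params):
    """Make every conv weight positive so a perturbation propagates through
    ReLU without cancellation (for empirical receptive-field measurement)."""
    if isinstance(params, dict):
        for k, v in params.items():
            if k == "w":
                params[k] = np.abs(v) + 1e-3
            elif k == "b":
                params[k] = np.zeros_like(v)
            else:
                _positive_identityish(v)
    elif isinstance(params, list):
        for v in params:
            _positive_identityish(v)


def test_receptive_field_grows_across_branches(rng):
    """Empirical oracle: perturb the center pixel and measure the support
    of the change after each branch; must match the analytic kernel/
    dilation arithmetic and grow strictly."""
    cfg = ContextExplorationConfig(4)
    p = init_context_exploration(rng, cfg)
    _positive_identityish(p)
    size = 63
    x = np.ones((1, 4, size, size))
    xp = x.copy()
    xp[0, :, size // 2, size // 2] += 1.0

    def branch_outputs(inp):
        outs = []
        prev = None
        from pancseg.nn.layers import cbr
        for i, br in enumerate(p["branches"]):
            h = cbr(br["reduce"], inp, mode="affine")
            if i > 0:
                h = h + prev
            h = cbr(br["local"], h, mode="affine")
            h = cbr(br["dilated"], h, dilation=DILATIONS[i], mode="affine")
            outs.append(np.asarray(h))
            prev = h
        return outs

    base = branch_outputs(x)
    pert = branch_outputs(xp)
    expected = [receptive_field(i) for i in range(4)]
    assert expected == sorted(expected) and len(set(expected)) == 4
    for i in range(4):
        diff = np.abs(pert[i] - base[i]).sum(axis=(0, 1))
        rows = np.flatnonzero(diff.any(axis=1))
        measured = rows[-1] - rows[0] + 1
        assert measured == expected[i]


def test_fp_and_fn_paths_share_no_parameters(rng):
    p = init_focus(rng, FocusConfig(8))
    _, spec_fp = flatten_tree(p["ce_fp"])
    theta_fp, _ = flatten_tree(p["ce_fp"])
    theta_fn, _ = flatten_tree(p["ce_fn"])
    assert theta_fp.shape == theta_fn.shape
    assert not np.array_equal(theta_fp, theta_fn)

    def leaves(t):
        if isinstance(t, dict):
            for v in t.values():
                yield from leaves(v)
        elif isinstance(t, list):
            for v in t:
                yield from leaves(v)
        else:
            yield t

    fp_ids = {id(a) for a in leaves(p["ce_fp"])}
    fn_ids = {id(a) for a in leaves(p["ce_fn"])}
    assert fp_ids.isdisjoint(fn_ids)


def test_zero_scales_make_output_independent_of_current_features(rng):
    """lambda = gamma = 0: the refined features depend only on F_h."""
    cfg = FocusConfig(4)
    p = init_focus(rng, cfg)
    p["lam"] = np.array(0.0)
    p["gam"] = np.array(0.0)
    f_h = rng.normal(size=(1, 4, 8, 8))
    pred_h = rng.normal(size=(1, 1, 8, 8))
    f_c1 = rng.normal(size=(1, 4, 8, 8))
    f_c2 = f_c1 + rng.normal(size=(1, 4, 8, 8))  # finite perturbation
    out1, logit1 = refine(p, f_c1, f_h, pred_h, cfg)
    out2, logit2 = refine(p, f_c2, f_h, pred_h, cfg)
    assert np.abs(np.asarray(out1) - np.asarray(out2)).max() < 1e-12
    assert np.abs(np.asarray(logit1) - np.asarray(logit2)).max() < 1e-12


def _delta(k):
    w = np.zeros((1, 1, k, k))
    w[0, 0, k // 2, k // 2] = 1.0
    return w


def test_refine_hand_chain_with_identity_blocks(rng):
    """Single-channel case with identity convolutions and affine (identity)
    normalization reduces the refinement to
    relu(relu(F_up - F_fpd) + F_fnd), verifiable by hand."""
    cfg = FocusConfig(1, norm="affine")
    p = init_focus(rng, cfg)
    for ce in (p["ce_fp"], p["ce_fn"]):
        for i, br in enumerate(ce["branches"]):
            br["reduce"]["conv"]["w"] = _delta(3)
            br["reduce"]["conv"]["b"][:] = 0.0
            br["local"]["conv"]["w"] = _delta(KERNELS[i])
            br["local"]["conv"]["b"][:] = 0.0
            br["dilated"]["conv"]["w"] = _delta(3)
            br["dilated"]["conv"]["b"][:] = 0.0
        # fuse selects branch 1 (the plain identity branch)
        ce["fuse"]["conv"]["w"] = np.zeros((1, 4, 3, 3))
        ce["fuse"]["conv"]["w"][0, 0, 1, 1] = 1.0
        ce["fuse"]["conv"]["b"][:] = 0.0
    p["cbr_h"]["conv"]["w"] = _delta(3)
    p["cbr_h"]["conv"]["b"][:] = 0.0
    p["lam"] = np.array(1.0)
    p["gam"] = np.array(1.0)

    f_c = np.abs(rng.normal(size=(1, 1, 4, 4)))   # non-negative input
    f_h = np.abs(rng.normal(size=(1, 1, 4, 4)))
    pred_h = rng.normal(size=(1, 1, 4, 4))
    a = 1.0 / (1.0 + np.exp(-pred_h))
    f_fa = f_c * a
    f_ba = f_c * (1.0 - a)
    expected = np.maximum(np.maximum(f_h - f_fa, 0.0) + f_ba, 0.0)
    out, _ = refine(p, f_c, f_h, pred_h, cfg)
    assert np.abs(np.asarray(out) - expected).max() < 1e-10


def test_gradient_reaches_interference_scales(rng):
    cfg = FocusConfig(4)
    p = init_focus(rng, cfg)
    theta, spec = flatten_tree(p)
    f_c = rng.normal(size=(1, 4, 8, 8))
    f_h = rng.normal(size=(1, 4, 4, 4))
    pred_h = rng.normal(size=(1, 1, 4, 4))

    def loss(th):
        _, logits = refine(unflatten_tree(th, spec), f_c, f_h, pred_h, cfg)
        return anp.sum(logits ** 2)

    g = grad(loss)(theta)
    for name in ("lam", "gam"):
        off = [s for s in spec if s[0] == (name,)][0][1]
        assert g[off] != 0.0


def test_false_positive_path_learns_distractor(rng):
    """A bright distractor wrongly covered by the higher-level prediction
    raises false-positive interference energy in its support after a short
    fit of the module."""
    from pancseg.losses import focusing_loss

    size = 16
    true_region = np.zeros((size, size)); true_region[4:8, 4:8] = 1.0
    blob = np.zeros((size, size)); blob[10:14, 10:14] = 1.0
    image = 0.3 + 0.4 * true_region + 0.5 * blob
    f_c = np.repeat(image[None, None], 4, axis=1)
    f_h = f_c.copy()
    pred_h = 8.0 * (true_region + blob)[None, None] - 4.0  # confident on both

    cfg = FocusConfig(4)
    p = init_focus(rng, cfg)
    theta, spec = flatten_tree(p)

    def loss(th):
        _, logits = refine(unflatten_tree(th, spec), f_c, f_h, pred_h, cfg)
        return focusing_loss(ops.sigmoid(logits)[0, 0], true_region)

    for _ in range(60):
        _, g = value_and_grad(loss)(theta)
        theta = theta - 0.05 * g

    fitted = unflatten_tree(theta, spec)
    f_fa, _ = split_attention(f_c, pred_h)
    f_fpd = np.asarray(context_exploration(fitted["ce_fp"], f_fa, cfg.ce))
    energy = np.abs(f_fpd).mean(axis=(0, 1))
    inside = energy[blob > 0].mean()
    outside = energy[(blob == 0) & (true_region == 0)].mean()
    assert inside >= outside
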