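"""Focusing module: reverse-attention refinement with context exploration.

The refinement at each decoder level splits the current-level features into
foreground- and background-attended parts using the (upsampled, logistic-
squashed) prediction from the level above, mines false-positive
interference from the foreground part and false-negative interference from
the background part with two *separate* context-exploration blocks, and
removes them from the upsampled higher-level features:

    F_up = U(CBR(F_h));  F_r = BR(F_up - lambda * F_fpd);
    F_r' = BR(F_r + gamma * F_fnd)

(lambda, gamma learnable, init 1; U bilinear; BR = BN + ReLU).  A 3x3 head
on F_r' yields the refined prediction for the level.

A context-exploration block runs four chained branches: branch i reduces
channels with a 3x3 convolution, extracts local features with a K_i x K_i
convolution (K = 1, 3, 5, 7) and perceives context with a 3x3 dilated
convolution (rates r = 1, 2, 4, 8); each convolution carries BN + ReLU.
Branch i's output is added to branch i+1's reduced input, so the receptive
field grows strictly along the chain.  The four branch outputs are
concatenated and fused by a 3x3 convolution.

The single-channel higher-level prediction is squashed with the logistic
function (the two-class softmax of a logit against 0) to give attention
values in [0, 1], so F_fa + F_ba == F_c exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import ops
from .nn.layers import cbr, conv, init_bn, init_cbr, init_conv

KERNELS = (1, 3, 5, 7)
DILATIONS = (1, 2, 4, 8)


@dataclass
class ContextExplorationConfig:
    channels: int
    chain: str = "add"  # how branch i feeds branch i+1: "add" | "concat"

    @property
    def branch_width(self) -> int:
        return max(1, self.channels // 4)


def init_context_exploration(rng: np.random.Generator, cfg: ContextExplorationConfig) -> dict:
    c, bw = cfg.channels, cfg.branch_width
    branches = []
    for i, k in enumerate(KERNELS):
        red_in = c if (i == 0 or cfg.chain == "add") else c + bw
        branches.append({
            "reduce": init_cbr(rng, red_in, bw, 3),
            "local": init_cbr(rng, bw, bw, k),
            "dilated": init_cbr(rng, bw, bw, 3),
        })
    return {"branches": branches, "fuse": init_cbr(rng, 4 * bw, c, 3)}


def context_exploration(p: dict, f_in, cfg: ContextExplorationConfig, norm: str = "batch"):
    outs = []
    prev = None
    for i, br in enumerate(p["branches"]):
        if i == 0:
            x = f_in
        elif cfg.chain == "concat":
            x = anp.concatenate([f_in, prev], axis=1)
        else:
            x = f_in
        h = cbr(br["reduce"], x, mode=norm)
        if i > 0 and cfg.chain == "add":
            h = h + prev
        h = cbr(br["local"], h, mode=norm)
        h = cbr(br["dilated"], h, dilation=DILATIONS[i], mode=norm)
        outs.append(h)
        prev = h
    return cbr(p["fuse"], anp.concatenate(outs, axis=1), mode=norm)


def receptive_field(branch_index: int) -> int:
    """Analytic receptive-field side of the chained branch output.

    Branch i's output joins branch i+1 after its 3x3 reduce convolution,
    so from branch 1 on the deepest path runs through the previous branch
    (not through the shallower reduce conv)."""
    rf = 3  # 3x3 reduce of branch 1
    for i in range(branch_index + 1):
        if i > 0:
            rf = max(rf, 3)  # reduce conv path of this branch
        rf += KERNELS[i] - 1          # local K_i x K_i
        rf += 2 * DILATIONS[i]        # dilated 3x3, rate r_i
    return rf


@dataclass
class FocusConfig:
    channels: int
    chain: str = "add"
    norm: str = "batch"

    @property
    def ce(self) -> ContextExplorationConfig:
        return ContextExplorationConfig(self.channels, self.chain)


def init_focus(rng: np.random.Generator, cfg: FocusConfig) -> dict:
    c = cfg.channels
    return {
        "ce_fp": init_context_exploration(rng, cfg.ce),
        "ce_fn": init_context_exploration(rng, cfg.ce),
        "cbr_h": init_cbr(rng, c, c, 3),
        "lam": np.array(1.0),
        "gam": np.array(1.0),
        "bn_r": init_bn(c),
        "bn_r2": init_bn(c),
        "head": init_conv(rng, c, 1, 3, bias_init=-2.0),
    }


def split_attention(f_c, pred_h):
    """Foreground/background split of current-level features by the
    higher-level prediction (logits; upsampled x2 if at half resolution)."""
    h, w = f_c.shape[2], f_c.shape[3]
    ph, pw = pred_h.shape[2], pred_h.shape[3]
    if (ph, pw) == (h, w):
        up = pred_h
    elif (2 * ph, 2 * pw) == (h, w):
        up = ops.resize_bilinear(pred_h, h, w)
    else:
        raise ValueError(
            f"higher-level prediction {ph}x{pw} must be at the same or half "
            f"the resolution of features {h}x{w}"
        )
    a = ops.sigmoid(up)
    f_fa = f_c * a
    f_ba = f_c * (1.0 - a)
    return f_fa, f_ba


def refine(p: dict, f_c, f_h, pred_h, cfg: FocusConfig):
    """One focusing step; returns (refined features, refined logits)."""
    norm = cfg.norm
    f_fa, f_ba = split_attention(f_c, pred_h)
    f_fpd = context_exploration(p["ce_fp"], f_fa, cfg.ce, norm=norm)
    f_fnd = context_exploration(p["ce_fn"], f_ba, cfg.ce, norm=norm)
    h_feats = cbr(p["cbr_h"], f_h, mode=norm)
    if f_h.shape[2:] != f_c.shape[2:]:
        h_feats = ops.resize_bilinear(h_feats, f_c.shape[2], f_c.shape[3])
    f_r = ops.relu(ops.batchnorm(h_feats - p["lam"] * f_fpd, p["bn_r"]["g"], p["bn_r"]["b"], mode=norm))
    f_rp = ops.relu(ops.batchnorm(f_r + p["gam"] * f_fnd, p["bn_r2"]["g"], p["bn_r2"]["b"], mode=norm))
    logits = conv(p["head"], f_rp, padding=1)
    return f_rp, logits
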