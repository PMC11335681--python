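"""Dual-encoder multi-scale U-Net.

Two contraction branches run in parallel from the input image: branch 1
applies two 3x3 convolutions per block; branch 2 runs 1x1->3x3 and 5x5->3x3
paths in parallel and concatenates them, so each block sees the image at
three kernel scales.  Both branches end in 2x2 max pooling.  A central
layer fuses the two deepest branch outputs through 1x1/3x3/5x5 paths, and
the decoder upsamples with stride-2 transposed convolutions, consuming two
skip connections per level (one from each encoder branch).

Channel plan (a package decision; the widths are config-driven): block i of
either branch outputs base*2^(i-1) channels (i = 1..4), the central layer
runs three paths of 8*base each and fuses them by 1x1 to 16*base, and the
decoder halves widths back down to base.  Every convolution is followed by
normalization + ReLU (config-switchable normalization mode).

For an H x W input (divisible by 16) the forward pass returns a full-size
probability map plus five feature maps at sizes H/16, H/8, H/4, H/2, H
(coarsest first) for the second-stage network.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import ops
from .nn.layers import cbr, conv, init_bn, init_cbr, init_conv, init_deconv

DEPTH = 4  # contraction blocks per branch; input must be divisible by 2**DEPTH


@dataclass
class BackboneConfig:
    in_channels: int = 1
    base_channels: int = 32
    out_channels: int = 1
    norm: str = "batch"  # "batch" | "affine"

    @property
    def enc_widths(self) -> list[int]:
        """Output width of encoder blocks 1..4."""
        return [self.base_channels * 2**i for i in range(DEPTH)]

    @property
    def central_path_width(self) -> int:
        return 8 * self.base_channels

    @property
    def central_width(self) -> int:
        return 16 * self.base_channels

    @property
    def dec_widths(self) -> list[int]:
        """Decoder output widths, coarsest first (levels H/8 .. H)."""
        return [8 * self.base_channels, 4 * self.base_channels,
                2 * self.base_channels, self.base_channels]


# ---------------------------------------------------------------- encoder

def init_branch1_block(rng, cin: int, cout: int) -> dict:
    return {"c1": init_cbr(rng, cin, cout, 3), "c2": init_cbr(rng, cout, cout, 3)}


def encode_branch1(p: dict, x, norm: str = "batch"):
    """Two 3x3 conv(+BN+ReLU) then 2x2 max pooling."""
    h = cbr(p["c2"], cbr(p["c1"], x, mode=norm), mode=norm)
    _check_even(h)
    return ops.maxpool2x2(h)


def init_branch2_block(rng, cin: int, cout: int) -> dict:
    return {
        "p1a": init_cbr(rng, cin, cout, 1),
        "p1b": init_cbr(rng, cout, cout, 3),
        "p2a": init_cbr(rng, cin, cout, 5),
        "p2b": init_cbr(rng, cout, cout, 3),
        "fuse": init_cbr(rng, 2 * cout, cout, 1),
    }


def encode_branch2(p: dict, x, norm: str = "batch"):
    """Parallel 1x1->3x3 and 5x5->3x3 paths on the same input, channel
    concatenation, 1x1 width-restoring fuse, then 2x2 max pooling."""
    a = cbr(p["p1b"], cbr(p["p1a"], x, mode=norm), mode=norm)
    b = cbr(p["p2b"], cbr(p["p2a"], x, mode=norm), mode=norm)
    h = cbr(p["fuse"], anp.concatenate([a, b], axis=1), mode=norm)
    _check_even(h)
    return ops.maxpool2x2(h)


def init_central(rng, cin: int, path: int, cout: int) -> dict:
    return {
        "a1": init_cbr(rng, cin, path, 1), "a2": init_cbr(rng, path, path, 3),
        "b1": init_cbr(rng, cin, path, 3), "b2": init_cbr(rng, path, path, 3),
        "c1": init_cbr(rng, cin, path, 5), "c2": init_cbr(rng, path, path, 3),
        "fuse": init_cbr(rng, 3 * path, cout, 1),
    }


def central_fuse(p: dict, c4_1, c4_2, norm: str = "batch"):
    """Fuse the deepest branch outputs: 1x1->3x3 on branch 1, 3x3->3x3 and
    5x5->3x3 on branch 2, concatenated (branch-1 path first) and fused by a
    1x1 convolution.  No pooling."""
    if c4_1.shape[2:] != c4_2.shape[2:]:
        raise ValueError(f"central inputs misaligned: {c4_1.shape} vs {c4_2.shape}")
    a = cbr(p["a2"], cbr(p["a1"], c4_1, mode=norm), mode=norm)
    b = cbr(p["b2"], cbr(p["b1"], c4_2, mode=norm), mode=norm)
    c = cbr(p["c2"], cbr(p["c1"], c4_2, mode=norm), mode=norm)
    return cbr(p["fuse"], anp.concatenate([a, b, c], axis=1), mode=norm)


# ---------------------------------------------------------------- decoder

def init_decode_block(rng, cin: int, skip: int, cout: int) -> dict:
    return {
        "up": init_deconv(rng, cin, cout),
        "bn_up": init_bn(cout),
        "c1": init_cbr(rng, cout + skip, cout, 3),
        "c2": init_cbr(rng, cout + skip, cout, 3),
    }


def decode_block(p: dict, u, skip1, skip2, norm: str = "batch"):
    """Transposed-conv upsample x2, concat branch-1 skip, 3x3 conv, concat
    branch-2 skip, 3x3 conv."""
    h = ops.relu(ops.batchnorm(
        ops.conv_transpose2x2(u, p["up"]["w"], p["up"]["b"]),
        p["bn_up"]["g"], p["bn_up"]["b"], mode=norm))
    if h.shape[2:] != skip1.shape[2:] or h.shape[2:] != skip2.shape[2:]:
        raise ValueError(
            f"skip size mismatch: upsampled {h.shape} vs skips "
            f"{skip1.shape}/{skip2.shape}"
        )
    h = cbr(p["c1"], anp.concatenate([h, skip1], axis=1), mode=norm)
    h = cbr(p["c2"], anp.concatenate([h, skip2], axis=1), mode=norm)
    return h


# ---------------------------------------------------------------- network

def init_backbone(rng: np.random.Generator, config: BackboneConfig) -> dict:
    w = config.enc_widths
    ins = [config.in_channels] + w[:-1]
    params = {
        "enc1": [init_branch1_block(rng, ins[i], w[i]) for i in range(DEPTH)],
        "enc2": [init_branch2_block(rng, ins[i], w[i]) for i in range(DEPTH)],
        "central": init_central(rng, w[-1], config.central_path_width, config.central_width),
    }
    dec_in = [config.central_width] + config.dec_widths[:-1]
    skips = [w[2], w[1], w[0], config.in_channels]  # post-pool C3..C1, then the image
    params["dec"] = [
        init_decode_block(rng, dec_in[j], skips[j], config.dec_widths[j]) for j in range(DEPTH)
    ]
    params["head"] = init_conv(rng, config.dec_widths[-1], config.out_channels, 1,
                               bias_init=-2.0)
    return params


def backbone_features(params: dict, image, config: BackboneConfig):
    """Run encoder + decoder; return (logits, features coarsest-first)."""
    h, w = image.shape[2], image.shape[3]
    if h % 2**DEPTH or w % 2**DEPTH:
        raise ValueError(f"input spatial size {h}x{w} must be divisible by {2 ** DEPTH}")
    norm = config.norm
    c1 = [image]  # C0..C4 of branch 1 (post-pool outputs)
    c2 = [image]
    for i in range(DEPTH):
        c1.append(encode_branch1(params["enc1"][i], c1[-1], norm=norm))
        c2.append(encode_branch2(params["enc2"][i], c2[-1], norm=norm))
    central = central_fuse(params["central"], c1[-1], c2[-1], norm=norm)

    feats = [central]
    u = central
    for j, lvl in enumerate(range(DEPTH - 1, -1, -1)):  # skip levels 3,2,1,0
        u = decode_block(params["dec"][j], u, c1[lvl], c2[lvl], norm=norm)
        feats.append(u)
    logits = conv(params["head"], u)
    return logits, feats


def backbone_forward(params: dict, image, config: BackboneConfig):
    """Full forward pass: (probability map in [0,1], 5 decoder/central
    feature maps at sizes H/16, H/8, H/4, H/2, H)."""
    logits, feats = backbone_features(params, image, config)
    return ops.sigmoid(logits), feats


def _check_even(x):
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ValueError(f"spatial dims must be even before pooling, got {x.shape}")
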