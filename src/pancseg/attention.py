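"""Non-local localization: channel attention, spatial attention, 7x7 head.

Applied to the deepest second-stage feature map, this module aggregates
global context to point at the approximate tumor region.  The channel
branch uses no learned projections (queries/keys/values are the reshaped
features themselves); the spatial branch derives Q'/K' through 1x1
convolutions to C1 = max(1, C // 8) channels and V' through a 1x1
convolution at full width.  Both branches are residual with learnable
scales (gamma_c, gamma_s, init 1), so setting both scales to zero reduces
the module exactly to its 7x7 prediction head.

Attention maps are row-stochastic: for each target channel (or output
position) the softmax-normalized weights over source channels (positions)
sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .nn import ops
from .nn.layers import conv, init_conv


@dataclass
class NonLocalConfig:
    channels: int
    enabled: bool = True  # ablation "L": off -> plain 1x1-equivalent head only

    @property
    def reduced(self) -> int:
        return max(1, self.channels // 8)


def init_nonlocal(rng: np.random.Generator, config: NonLocalConfig) -> dict:
    c, c1 = config.channels, config.reduced
    return {
        "gamma_c": np.array(1.0),
        "gamma_s": np.array(1.0),
        "q": init_conv(rng, c, c1, 1),
        "k": init_conv(rng, c, c1, 1),
        "v": init_conv(rng, c, c, 1),
        "head": init_conv(rng, c, 1, 7, bias_init=-2.0),
    }


def channel_attention(gamma_c, f):
    """Residual channel attention on NCHW features.

    X[i, j] = softmax_j(A_i . A_j) over reshaped features A (C x N);
    output = gamma_c * (X A) + F.
    """
    n, c, h, w = f.shape
    if c < 1:
        raise ValueError("need at least one channel")
    a = anp.reshape(f, (n, c, h * w))
    scores = anp.einsum("bin,bjn->bij", a, a)
    x = ops.softmax(scores, axis=2)  # rows over source channels j sum to 1
    out = anp.einsum("bij,bjn->bin", x, a)
    return gamma_c * anp.reshape(out, f.shape) + f


def spatial_attention(p: dict, gamma_s, f):
    """Residual spatial (position) attention.

    Q', K' (C1 x N) and V' (C x N) come from 1x1 convolutions; for each
    output position i the weights over source positions j are
    softmax_j(Q'_i . K'_j) and the output is gamma_s * sum_j V'_j w_ij + F.
    """
    n, c, h, w = f.shape
    q = anp.reshape(conv(p["q"], f), (n, -1, h * w))
    k = anp.reshape(conv(p["k"], f), (n, -1, h * w))
    v = anp.reshape(conv(p["v"], f), (n, c, h * w))
    scores = anp.einsum("bqi,bqj->bij", q, k)
    x = ops.softmax(scores, axis=2)
    out = anp.einsum("bcj,bij->bci", v, x)
    return gamma_s * anp.reshape(out, f.shape) + f


def localize(params: dict, f_top, enabled: bool = True):
    """Full module: channel attention -> spatial attention -> 7x7 head.

    Returns (logits 1xHxW, attended features) — the features feed the
    first focusing module.  With ``enabled=False`` (ablation) the head is
    applied to the raw features.
    """
    if enabled:
        f1 = channel_attention(params["gamma_c"], f_top)
        f2 = spatial_attention(params, params["gamma_s"], f1)
    else:
        f2 = f_top
    logits = conv(params["head"], f2, padding=3)
    return logits, f2
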