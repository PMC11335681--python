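"""Parameter initialization and functional application of common layers.

Parameters live in nested dicts of plain numpy arrays (an autograd pytree);
every ``apply`` function is pure so the whole model is differentiable with
``autograd.grad`` over the parameter tree.
"""

from __future__ import annotations

import numpy as np

from . import ops


def init_conv(rng: np.random.Generator, cin: int, cout: int, k: int,
              bias_init: float = 0.0) -> dict:
    """He-normal weights for a k x k convolution.

    ``bias_init`` is used for prediction heads: a negative value encodes
    the prior that foreground is rare, which speeds up Dice/BCE training
    on small targets."""
    std = np.sqrt(2.0 / (cin * k * k))
    return {
        "w": rng.normal(0.0, std, size=(cout, cin, k, k)),
        "b": np.full(cout, float(bias_init)),
    }


def init_deconv(rng: np.random.Generator, cin: int, cout: int) -> dict:
    std = np.sqrt(2.0 / (cin * 4))
    return {
        "w": rng.normal(0.0, std, size=(cin, cout, 2, 2)),
        "b": np.zeros(cout),
    }


def init_bn(c: int) -> dict:
    return {"g": np.ones(c), "b": np.zeros(c)}


def init_cbr(rng: np.random.Generator, cin: int, cout: int, k: int) -> dict:
    return {"conv": init_conv(rng, cin, cout, k), "bn": init_bn(cout)}


def conv(p: dict, x, padding: int = 0, dilation: int = 1):
    return ops.conv2d(x, p["w"], p["b"], padding=padding, dilation=dilation)


def bn(p: dict, x, mode: str = "batch"):
    return ops.batchnorm(x, p["g"], p["b"], mode=mode)


def cbr(p: dict, x, padding=None, dilation: int = 1, mode: str = "batch"):
    """Convolution + normalization + ReLU with same-size padding by default."""
    k = p["conv"]["w"].shape[2]
    if padding is None:
        padding = dilation * (k - 1) // 2
    return ops.relu(bn(p["bn"], conv(p["conv"], x, padding=padding, dilation=dilation), mode=mode))


def n_params(tree) -> int:
    if isinstance(tree, dict):
        return sum(n_params(v) for v in tree.values())
    if isinstance(tree, (list, tuple)):
        return sum(n_params(v) for v in tree)
    return int(np.size(tree))
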