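"""Stochastic gradient descent with momentum and weight decay."""

from __future__ import annotations

import numpy as np


class SGD:
    """Momentum SGD over a flat parameter vector.

    Update rule (L2 decay folded into the gradient):
    v <- momentum*v + g + wd*p ;  p <- p - lr*v.
    """

    def __init__(self, n_params: int, lr: float = 1e-5, momentum: float = 0.9,
                 weight_decay: float = 1e-7):
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = np.zeros(n_params)

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        g = grad + self.weight_decay * theta
        self._velocity = self.momentum * self._velocity + g
        return theta - self.lr * self._velocity
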