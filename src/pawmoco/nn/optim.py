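"""Optimizers: SGD with momentum, Adam, and LARS.

LARS rescales each parameter tensor's step by the trust ratio
``trust * ||w|| / (||g|| + wd * ||w||)``; bias and batch-norm parameters are
excluded from both adaptation and weight decay by default (their
``Parameter.adapt``/``decay`` flags), following common large-batch practice.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9, weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def lars_local_lr(w_norm: float, g_norm: float, weight_decay: float,
                  trust_coefficient: float) -> float:
    """Trust ratio for one parameter tensor; 1.0 when either norm vanishes."""
    if w_norm == 0.0 or g_norm == 0.0:
        return 1.0
    return trust_coefficient * w_norm / (g_norm + weight_decay * w_norm)


class LARS(Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9,
                 weight_decay: float = 1e-6, trust_coefficient: float = 0.001,
                 exclude_bias_bn: bool = True):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.trust_coefficient = trust_coefficient
        self.exclude_bias_bn = exclude_bias_bn
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient in LARS step")
            adapted = p.adapt or not self.exclude_bias_bn
            wd = self.weight_decay if (p.decay or not self.exclude_bias_bn) else 0.0
            if wd:
                g = g + wd * p.data
            if adapted:
                local = lars_local_lr(float(np.linalg.norm(p.data)),
                                      float(np.linalg.norm(p.grad)),
                                      wd, self.trust_coefficient)
            else:
                local = 1.0
            v *= self.momentum
            v += local * g
            p.data -= self.lr * v


def lars_step(params: list[Parameter], lr: float, weight_decay: float = 0.0,
              trust_coefficient: float = 0.001) -> None:
    """Single momentum-free LARS update, applied in place.

    ``w <- w - lr * local_lr * (g + wd * w)`` with
    ``local_lr = trust * ||w|| / (||g|| + wd * ||w||)`` (norm-0 guarded).
    """
    for p in params:
        g = p.grad
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in LARS step")
        local = lars_local_lr(float(np.linalg.norm(p.data)),
                              float(np.linalg.norm(g)),
                              weight_decay, trust_coefficient)
        p.data -= lr * local * (g + weight_decay * p.data)
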