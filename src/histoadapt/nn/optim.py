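"""Stochastic optimizers over :class:`~histoadapt.nn.layers.Layer` parameters.

Both optimizers skip parameters whose gradient is ``None`` (i.e. layers that
did not participate in the last backward pass); an Adam step on a parameter
with a present-but-stale gradient is the caller's bug, which is why training
loops zero gradients before every backward phase.
"""

from __future__ import annotations

import numpy as np


class SGD:
    """SGD with classical momentum and optional L2 weight decay.

    Weight decay is applied to weight matrices only (parameter name ``W``),
    not to biases or batch-norm affine parameters.
    """

    def __init__(self, layers, lr, momentum=0.9, weight_decay=0.0):
        self.layers = list(layers)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = {}

    def step(self):
        for li, layer in enumerate(self.layers):
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                grad = grad.astype(np.float32, copy=False)
                if self.weight_decay and name == "W":
                    grad = grad + self.weight_decay * param
                key = (li, name)
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(param)
                v = self.momentum * v - self.lr * grad
                self._velocity[key] = v
                param += v


class Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {}
        self._v = {}
        self._t = {}

    def step(self):
        for li, layer in enumerate(self.layers):
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                grad = grad.astype(np.float32, copy=False)
                key = (li, name)
                t = self._t.get(key, 0) + 1
                m = self._m.get(key)
                v = self._v.get(key)
                if m is None:
                    m = np.zeros_like(param)
                    v = np.zeros_like(param)
                m = self.beta1 * m + (1 - self.beta1) * grad
                v = self.beta2 * v + (1 - self.beta2) * grad * grad
                mhat = m / (1 - self.beta1**t)
                vhat = v / (1 - self.beta2**t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                self._m[key], self._v[key], self._t[key] = m, v, t
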