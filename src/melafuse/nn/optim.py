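"""Nadam: Adam with Nesterov momentum (Dozat 2016 variant without the
momentum warmup schedule, matching common framework defaults).

Weight decay is applied as an L2 term added to the gradient before the
moment updates, as in mainstream Adam/Nadam implementations.
"""

from __future__ import annotations

import numpy as np


class Nadam:
    def __init__(
        self,
        parameters: list[tuple[object, str]],
        lr: float = 2e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.parameters = parameters
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(layer.params[name]) for layer, name in parameters]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[name]
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            # Nesterov look-ahead on the first moment
            update = (b1 * m_hat + (1 - b1) * g / bc1) / (np.sqrt(v_hat) + self.eps)
            layer.params[name] -= self.lr * update

    def zero_grad(self) -> None:
        for layer, name in self.parameters:
            if name in layer.grads:
                layer.grads[name][...] = 0.0
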