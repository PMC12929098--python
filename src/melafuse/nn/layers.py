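"""Layers with forward caches and hand-derived backward passes."""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: ``params`` and ``grads`` are parallel name->array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style strided convolution over (N, C, H, W) batches."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 2,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        # He initialization, appropriate for the ReLU that follows
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size, kernel_size)
        )
        self.params["b"] = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self.kernel_size = kernel_size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        s, p, k = self.stride, self.padding, self.kernel_size
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        out = np.einsum("ncijhw,ochw->noij", windows, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None, None]
        self._cache = (x.shape, windows)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x_shape, windows = self._cache
        s, p, k = self.stride, self.padding, self.kernel_size
        self.grads["W"] = np.einsum("ncijhw,noij->ochw", windows, grad, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))

        n, c, h, w = x_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        ho, wo = grad.shape[2], grad.shape[3]
        for kh in range(k):
            for kw in range(k):
                contrib = np.einsum(
                    "noij,oc->ncij", grad, self.params["W"][:, :, kh, kw], optimize=True
                )
                dxp[:, :, kh : kh + ho * s : s, kw : kw + wo * s : s] += contrib
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            self.params["W"] = np.zeros((out_features, in_features))
        else:
            self.params["W"] = rng.normal(
                0.0, np.sqrt(2.0 / in_features), (out_features, in_features)
            )
        self.params["b"] = np.zeros(out_features)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads["W"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        found: list[tuple[Layer, str]] = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                found.extend(layer.parameters())
            else:
                found.extend((layer, name) for name in layer.params)
        return found
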