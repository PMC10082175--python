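"""Layers of the numpy CNN engine.

Each layer exposes ``forward(x, train)`` and ``backward(grad)``; in training
mode the forward pass caches what the backward pass needs, in inference mode
nothing is retained. Convolution is stride-1 same-padding via im2col; its
adjoint (col2im) accumulates over the k*k kernel offsets, which keeps the
whole engine vectorized.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """3x3 (or 1x1) stride-1 convolution with zero same-padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        weight_std: float | None = None,
        name: str = "conv",
    ) -> None:
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        std = weight_std if weight_std is not None else float(np.sqrt(2.0 / fan_in))
        self.weight = Param(
            rng.normal(0.0, std, size=(out_channels, fan_in)), name=f"{name}.weight"
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        # (n, c, h, w, k, k) view -> (n*h*w, c*k*k)
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        out = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        else:
            self._cols = self._shape = None
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "backward() requires a train-mode forward()"
        n, c, h, w = self._shape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.weight.grad += (g2.T @ self._cols).astype(DTYPE)
        self.bias.grad += g2.sum(axis=0).astype(DTYPE)
        dcols = (g2 @ self.weight.value).reshape(n, h, w, c, self.k, self.k)
        dxp = np.zeros((n, c, hp, wp), dtype=DTYPE)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        self._cols = self._shape = None
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = (x > 0) if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._out * (1.0 - self._out)
        self._out = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties resolved to the first element (deterministic)."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pool input dims must be even (pad first)"
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        else:
            self._idx = self._shape = None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        scat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(scat, self._idx[..., None], grad[..., None].astype(DTYPE), axis=-1)
        out = (
            scat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = self._shape = None
        return out


class BilinearUp2(Layer):
    """x2 bilinear upsampling, half-pixel-center convention (corners not aligned).

    Implemented as separable linear maps: y = W_r x W_c^T per channel, so the
    backward pass is just the transposed maps applied to the gradient.
    """

    def __init__(self) -> None:
        self._cache: dict[int, np.ndarray] = {}
        self._shape: tuple[int, ...] | None = None

    def _weights(self, n_in: int) -> np.ndarray:
        wmat = self._cache.get(n_in)
        if wmat is None:
            out = np.arange(2 * n_in)
            src = np.maximum((out + 0.5) / 2.0 - 0.5, 0.0)
            i0 = np.minimum(src.astype(np.int64), n_in - 1)
            i1 = np.minimum(i0 + 1, n_in - 1)
            f = src - i0
            wmat = np.zeros((2 * n_in, n_in), dtype=DTYPE)
            wmat[out, i0] += (1.0 - f).astype(DTYPE)
            wmat[out, i1] += f.astype(DTYPE)
            self._cache[n_in] = wmat
        return wmat

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = (n, c, h, w) if train else None
        wr, wc = self._weights(h), self._weights(w)
        # rows then cols; tensordot keeps everything as one big matmul
        y = np.tensordot(wr, x, axes=(1, 2))  # (2h, n, c, w)
        y = np.tensordot(y, wc, axes=(3, 1))  # (2h, n, c, 2w)
        return y.transpose(1, 2, 0, 3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        wr, wc = self._weights(h), self._weights(w)
        g = np.tensordot(wr.T, grad.astype(DTYPE), axes=(1, 2))  # (h, n, c, 2w)
        g = np.tensordot(g, wc, axes=(3, 0))  # (h, n, c, w)
        self._shape = None
        return g.transpose(1, 2, 0, 3)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]
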