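"""Layers with explicit forward/backward passes.

Conventions: activations are float32 arrays in NCHW layout; every layer
caches what its backward pass needs; ``backward`` consumes the gradient of
the loss w.r.t. the layer output and returns the gradient w.r.t. its input,
accumulating parameter gradients in ``.grads`` (same keys as ``.params``).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "ConstrainedConv2d", "ReLU", "Sigmoid",
    "MaxPool2", "Upsample2", "Adam", "mae_loss",
]


class Layer:
    """Base class; parameter-free layers leave params/grads empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> windows (N, H, W, C, k, k) with zero padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N, C, H, W, k, k
    return win.transpose(0, 2, 3, 1, 4, 5)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                  pad: int) -> tuple[np.ndarray, np.ndarray]:
    k = w.shape[-1]
    cols = _im2col(x, k, pad)                        # N,H,W,Cin,k,k
    out = np.tensordot(cols, w, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,Cout
    out = out.transpose(0, 3, 1, 2)
    if b is not None:
        out += b[None, :, None, None]
    return np.ascontiguousarray(out), cols


def _conv_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray,
                   cols: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[-1]
    # dW[o,i,p,q] = sum_{n,h,w'} dout[n,o,h,w'] * cols[n,h,w',i,p,q]
    dw = np.tensordot(dout, cols, axes=([0, 2, 3], [0, 1, 2]))
    db = dout.sum(axis=(0, 2, 3))
    # dX = 'full' correlation of dout with weights flipped in space,
    # transposed in channels; realized with the same im2col machinery.
    w_t = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # Cin,Cout,k,k
    gcols = _im2col(dout, k, k - 1 - pad if pad < k else pad)
    # padding for the transposed conv must be k-1-pad to invert 'same'
    dx = np.tensordot(gcols, w_t, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db


class Conv2d(Layer):
    """Same-padded 2D convolution with free weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        self.params = {
            "w": (rng.standard_normal(
                (out_channels, in_channels, kernel_size, kernel_size)
            ) * scale).astype(np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out, self._cols = _conv_forward(x, self.params["w"], self.params["b"], self.pad)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx, dw, db = _conv_backward(dout, self._x, self.params["w"], self._cols, self.pad)
        self.grads["w"] += dw
        self.grads["b"] += db
        self._x = self._cols = None
        return dx


class ConstrainedConv2d(Layer):
    """Convolution whose kernels are linear combinations of a fixed basis.

    The effective kernel for output channel o, input channel i is
    ``sum_b coeff[o, i, b] * basis[b]``; only the combination coefficients
    (and the bias) are trainable, so the parameter count is independent of
    the spatial kernel size.
    """

    def __init__(self, in_channels: int, out_channels: int, basis: np.ndarray,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        basis = np.asarray(basis, dtype=np.float32)
        if basis.ndim != 3 or basis.shape[1] != basis.shape[2]:
            raise ValueError(
                f"basis must have shape (n_basis, k, k), got {basis.shape}"
            )
        if basis.shape[0] < 2:
            raise ValueError("need at least 2 basis kernels")
        if basis.shape[1] % 2 == 0:
            raise ValueError("basis kernel size must be odd")
        rng = rng or np.random.default_rng()
        self.basis = basis
        self.kernel_size = basis.shape[1]
        self.pad = self.kernel_size // 2
        n_basis = basis.shape[0]
        scale = np.sqrt(2.0 / (in_channels * n_basis))
        self.params = {
            "coeff": (rng.standard_normal((out_channels, in_channels, n_basis))
                      * scale).astype(np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def effective_weight(self) -> np.ndarray:
        return np.tensordot(self.params["coeff"], self.basis, axes=([2], [0]))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._w = self.effective_weight()
        out, self._cols = _conv_forward(x, self._w, self.params["b"], self.pad)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx, dw, db = _conv_backward(dout, self._x, self._w, self._cols, self.pad)
        self.grads["coeff"] += np.tensordot(dw, self.basis, axes=([2, 3], [1, 2]))
        self.grads["b"] += db
        self._x = self._cols = self._w = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -50.0, 50.0)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class HardSigmoid(Layer):
    """Clip to [0, 1] with a leaky straight-through gradient.

    Unlike the logistic function this head can emit exactly 0 and 1, so a
    mean-absolute-error objective can reach zero on binary targets and the
    gradient in the saturated zones never fully dies (slope ``leak``).
    """

    def __init__(self, leak: float = 0.01) -> None:
        super().__init__()
        self.leak = leak

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._active = (x > 0.0) & (x < 1.0)
        return np.clip(x, 0.0, 1.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._active, dout, self.leak * dout)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {(h, w)}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x up-sampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(np.float32)
    return loss, grad


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m[key] = self.beta1 * m[key] + (1 - self.beta1) * g
                v[key] = self.beta2 * v[key] + (1 - self.beta2) * g * g
                p -= self.lr * (m[key] / b1t) / (np.sqrt(v[key] / b2t) + self.eps)
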