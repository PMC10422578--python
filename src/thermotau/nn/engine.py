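"""Minimal NumPy feed-forward engine with reverse-mode gradients.

Implements exactly the layer types the thermal regression network needs:
dense layers, 3x3 same-padding 2-D convolutions (via im2col so the inner
loop is a BLAS matmul), sigmoid activations and shape rearrangements.
Parameters and activations are float32; updates are plain SGD with
(optional) classical momentum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "Reshape", "Sequential", "sigmoid", "glorot_uniform"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # Numerically safe logistic; float32 in, float32 out.
    out = np.clip(x, -40.0, 40.0)
    np.negative(out, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def glorot_uniform(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fan_in: int,
    fan_out: int,
    gain: float = 1.0,
) -> np.ndarray:
    """Glorot/Xavier uniform initialization with an activation gain.

    For logistic-sigmoid layers ``gain=4`` compensates the derivative at the
    origin (1/4), keeping activation variance roughly constant with depth;
    without it a deep sigmoid stack collapses to constant outputs and
    gradients vanish.
    """
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _gain(activation: str) -> float:
    return 4.0 if activation == "sigmoid" else 1.0


class Layer:
    """Base class: forward caches whatever backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    #: per-layer learning-rate multiplier (classic constant per-layer
    #: scaling; lets slow-gradient layers train at their own pace)
    lr_scale: float = 1.0

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer ``y = act(x @ W + b)``."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str,
        rng: np.random.Generator,
        gain: float | None = None,
    ) -> None:
        super().__init__()
        if activation not in ("sigmoid", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        if gain is None:
            gain = _gain(activation)
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out, gain=gain)
        # centering bias: cancels the mean pre-activation offset for inputs
        # with mean ~0.5 (sigmoid outputs / unit-box signals), so no unit
        # starts saturated
        self.b = (-0.5 * self.W.sum(axis=0)).astype(np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W + self.b
        if self.activation == "sigmoid":
            y = sigmoid(y)
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            dy = dy * (self._y * (1.0 - self._y))
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Conv2D(Layer):
    """3x3 (or kxk) 2-D convolution, stride 1, same padding, NHWC layout.

    The kernel is stored as (k, k, c_in, c_out); forward and both backward
    passes accumulate one channel-space matmul per spatial offset over the
    zero-padded input, which keeps every BLAS operand contiguous without
    materializing the k*k-fold patch matrix.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        activation: str,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        if activation not in ("sigmoid", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.activation = activation
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.W = glorot_uniform(
            rng, (kernel, kernel, c_in, c_out), fan_in, fan_out, gain=_gain(activation)
        )
        # centering bias (see Dense): cancel the mean-0.5 input offset
        self.b = (-0.5 * self.W.sum(axis=(0, 1, 2))).astype(np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @staticmethod
    def _pad(x: np.ndarray, p: int) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        xp[:, p : p + h, p : p + w, :] = x
        return xp

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        p = self.k // 2
        xp = self._pad(x, p)
        self._shape = (b, h, w)
        yf = np.zeros((b * h * w, self.c_out), dtype=x.dtype)
        tmp = np.empty_like(yf)
        patches = []
        for i in range(self.k):
            for j in range(self.k):
                patch = np.ascontiguousarray(
                    xp[:, i : i + h, j : j + w, :]
                ).reshape(-1, self.c_in)
                patches.append(patch)
                np.matmul(patch, self.W[i, j], out=tmp)
                yf += tmp
        self._patches = patches
        yf += self.b
        y = yf.reshape(b, h, w, self.c_out)
        if self.activation == "sigmoid":
            y = sigmoid(y)
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w = self._shape
        p = self.k // 2
        if self.activation == "sigmoid":
            dy = dy * (self._y * (1.0 - self._y))
        dy_flat = dy.reshape(-1, self.c_out)
        self.grads[1][...] = dy_flat.sum(axis=0)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, self.c_in), dtype=dy.dtype)
        tmp = np.empty((b * h * w, self.c_in), dtype=dy.dtype)
        for idx, (i, j) in enumerate(
            (i, j) for i in range(self.k) for j in range(self.k)
        ):
            self.grads[0][i, j] = self._patches[idx].T @ dy_flat
            # scatter-add the input gradient back through the same window
            np.matmul(dy_flat, self.W[i, j].T, out=tmp)
            dxp[:, i : i + h, j : j + w, :] += tmp.reshape(b, h, w, self.c_in)
        self._patches = None
        return dxp[:, p : p + h, p : p + w, :]


class Reshape(Layer):
    """Free rearrangement between flat vectors and NHWC maps."""

    def __init__(self, out_shape: tuple[int, ...]) -> None:
        super().__init__()
        self.out_shape = out_shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape[1:]
        return x.reshape(x.shape[0], *self.out_shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(dy.shape[0], *self._in_shape)


class Sequential:
    """A layer stack with SGD(+momentum) updates."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self._velocity = [
            [np.zeros_like(p) for p in layer.params] for layer in self.layers
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def sgd_step(self, lr: float, momentum: float = 0.0) -> None:
        for layer, vel in zip(self.layers, self._velocity):
            lr_l = lr * layer.lr_scale
            for p, g, v in zip(layer.params, layer.grads, vel):
                if momentum:
                    v *= momentum
                    v -= lr_l * g
                    p += v
                else:
                    p -= lr_l * g

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w.astype(np.float32)
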