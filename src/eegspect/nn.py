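"""A compact numpy CNN engine: the layers, loss and optimizer needed by the
three spectrogram classifiers.

Supports 3x3 same-padding convolutions (stride 1), 2x2 max pooling,
inverted dropout, dense layers, ReLU, softmax cross-entropy and Adam.
Everything is float32 and fully seeded: one master seed fixes weight
initialization, dropout masks and shuffling, so training runs are
reproducible on a fixed thread configuration.

Array layout is channels-last: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; parameterless by default."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) patch matrix for a 3x3 same-pad window."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    view = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    return view.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, optional fused ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 relu: bool = True) -> None:
        super().__init__()
        self.cin, self.cout, self.relu = in_channels, out_channels, relu
        fan_in = 9 * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.w = w.astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        cols = _im2col3(x)
        out = cols @ self.w + self.b
        n, h, w, _ = x.shape
        out = out.reshape(n, h, w, self.cout)
        if train:
            self._cols = cols
        if self.relu:
            self._mask = out > 0
            out = np.maximum(out, 0.0)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * self._mask
        n, h, w, _ = self._shape
        gmat = grad.reshape(n * h * w, self.cout)
        self.grads[0][...] = self._cols.T @ gmat
        self.grads[1][...] = gmat.sum(axis=0)
        del self._cols
        # dx = "full" correlation of grad with the flipped kernel
        wk = self.w.reshape(3, 3, self.cin, self.cout)
        wback = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.cout, self.cin)
        dx = _im2col3(grad) @ wback
        return dx.reshape(n, h, w, self.cin)

    def out_shape(self, in_shape):
        return (*in_shape[:2], self.cout)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xv = x[:, : ho * 2, : wo * 2].reshape(n, ho, 2, wo, 2, c)
        flat = xv.transpose(0, 1, 3, 2, 4, 5).reshape(n, ho, wo, 4, c)
        self._arg = flat.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        flat = np.zeros((n, ho, wo, 4, c), dtype=grad.dtype)
        np.put_along_axis(flat, self._arg[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, : ho * 2, : wo * 2] = (
            flat.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, ho * 2, wo * 2, c)
        )
        return dx

    def out_shape(self, in_shape):
        return (in_shape[0] // 2, in_shape[1] // 2, in_shape[2])


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 relu: bool = False) -> None:
        super().__init__()
        self.relu = relu
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.w = w.astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        if self.relu:
            self._mask = out > 0
            out = np.maximum(out, 0.0)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * self._mask
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T

    def out_shape(self, in_shape):
        return (self.w.shape[1],)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class Sequential:
    """A feed-forward stack of layers trained with softmax cross-entropy.

    ``input_offset`` is subtracted from every input before the first layer;
    training sets it to the training-set mean (uncentered inputs prolong
    the initial chance-level plateau badly), and it is part of the fitted
    state so prediction applies the same shift.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self.input_offset: float = 0.0

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.input_offset:
            x = x - np.float32(self.input_offset)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size].astype(np.float32))))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)
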