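"""Minimal numpy layers for the 2D slice classifier.

Implements exactly the blocks the architecture needs -- 3x3 same-padding
convolution (stride 1), batch normalization, ReLU, 2x2/stride-2 max
pooling, fully connected layers and a softmax cross-entropy head -- with
analytic backward passes (verified against numeric gradients in the test
suite) and SGD-with-momentum updates with L2 weight decay on weights.

Data layout is NCHW, float32. Convolution uses im2col + matmul; the
backward col2im is a 9-term vectorized scatter.
"""
from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    params: dict
    grads: dict
    decay: frozenset = frozenset()  # param names subject to L2

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) of 3x3 same-padded patches."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding."""

    def __init__(self, c_in, c_out, rng):
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": glorot_uniform(rng, (c_in * 9, c_out), c_in * 9, c_out * 9),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {}
        self.decay = frozenset({"W"})

    def forward(self, x, training):
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape = self._cache
        n, c, h, w = xshape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = cols.T @ g
        self.grads["b"] = g.sum(axis=0)
        dcols = g @ self.params["W"].T
        return _col2im(dcols, xshape)


class BatchNorm(Layer):
    """Channel-wise batch normalization for NCHW tensors.

    Training uses batch statistics; inference uses exponential running
    averages collected during training.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.grads = {}
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(x.dtype)

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        axes = (0, 2, 3)
        m = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"][None, :, None, None]
        if not training:
            return g * inv[None, :, None, None]
        dxhat_sum = g.sum(axis=axes)
        dxhat_x_sum = (g * xhat).sum(axis=axes)
        return (inv[None, :, None, None] / m) * (
            m * g
            - dxhat_sum[None, :, None, None]
            - xhat * dxhat_x_sum[None, :, None, None]
        )


class ReLU(Layer):
    params = {}
    grads = {}

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/column dropped."""

    params = {}
    grads = {}

    def forward(self, x, training):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, : 2 * ho, : 2 * wo]
        win = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, 4
        )
        self._argmax = win.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._inshape
        ho, wo = h // 2, w // 2
        dwin = np.zeros((n, c, ho, wo, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._inshape, dtype=grad.dtype)
        dx[:, :, : 2 * ho, : 2 * wo] = (
            dwin.reshape(n, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * ho, 2 * wo)
        )
        return dx


class Flatten(Layer):
    params = {}
    grads = {}

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        self.params = {
            "W": glorot_uniform(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out, dtype=F32),
        }
        self.grads = {}
        self.decay = frozenset({"W"})

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain sequential network with softmax cross-entropy loss and
    SGD-with-momentum (velocity update v <- m v - lr (g + l2 w))."""

    def __init__(self, layers):
        self.layers = layers
        self._velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in layers
        ]

    def forward(self, x, training=False, upto=None):
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training)
            if upto is not None and i == upto:
                return x
        return x

    def loss_and_backward(self, x, y_onehot):
        logits = self.forward(x, training=True)
        p = softmax(logits)
        n = x.shape[0]
        loss = float(-(y_onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
        grad = ((p - y_onehot) / n).astype(F32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def sgdm_step(self, lr, momentum, l2):
        for layer, vel in zip(self.layers, self._velocity):
            for k, w in layer.params.items():
                g = layer.grads[k].astype(w.dtype)
                if k in layer.decay:
                    g = g + l2 * w
                vel[k] = momentum * vel[k] - lr * g
                w += vel[k]
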