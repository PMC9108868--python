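"""Minimal 1-D convolutional network engine (numpy, manual backprop).

Implements exactly the layer vocabulary the regression network needs —
1-D convolution (im2col + BLAS matmul), batch normalization, ReLU, max
pooling, dropout, global average pooling and a linear head — together with
residual/downsampling units and an Adam optimizer.  Everything is float32
and fully deterministic given the seeds supplied by the caller.

Shapes follow the (batch, channels, length) convention.  All strided layers
use "same"-style padding (output length = ceil(L / stride)), so odd input
lengths survive the stem and the downsampling chain.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "GlobalAvgPool",
    "Linear",
    "ResidualUnit",
    "Adam",
]


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output length and (left, right) padding for ceil-mode convolution."""
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


class Layer:
    """Base: parameter/grad dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Cross-correlation with 'same' ceil-mode padding, no bias (BN follows)."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.params["w"] = w.astype(np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])

    def forward(self, x, training=False):
        n, c, length = x.shape
        out_len, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win[:, :, :: self.stride, :]  # (n, c, out_len, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * out_len, c * self.kernel
        )
        out = cols @ self.params["w"].T
        self._cache = (cols, n, c, length, out_len, pl, pr, xp.shape[2])
        return out.reshape(n, out_len, self.out_ch).transpose(0, 2, 1)

    def backward(self, dout):
        cols, n, c, length, out_len, pl, pr, padded = self._cache
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(
            n * out_len, self.out_ch
        )
        self.grads["w"][...] = d2.T @ cols
        dcols = (d2 @ self.params["w"]).reshape(n, out_len, c, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (n, c, out_len, k)
        dxp = np.zeros((n, c, padded), dtype=dout.dtype)
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * out_len : self.stride] += dcols[
                :, :, :, j
            ]
        return dxp[:, :, pl : padded - pr if pr else None]


class BatchNorm1d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.grads["gamma"] = np.zeros(channels, dtype=np.float32)
        self.grads["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, x.shape[0] * x.shape[2], training)
        return self.params["gamma"][None, :, None] * xhat + self.params[
            "beta"
        ][None, :, None]

    def backward(self, dout):
        xhat, ivar, m, training = self._cache
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        self.grads["gamma"][...] = dgamma
        self.grads["beta"][...] = dbeta
        g_iv = (self.params["gamma"] * ivar)[None, :, None]
        if not training:
            return dout * g_iv
        return g_iv * (
            dout
            - (dbeta / m)[None, :, None]
            - xhat * (dgamma / m)[None, :, None]
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    def __init__(self, kernel=3, stride=2):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x, training=False):
        n, c, length = x.shape
        out_len, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]  # (n, c, out_len, k)
        self._argmax = win.argmax(axis=3)
        self._shape = (n, c, length, out_len, pl, pr, xp.shape[2])
        return win.max(axis=3)

    def backward(self, dout):
        n, c, length, out_len, pl, pr, padded = self._shape
        dxp = np.zeros((n, c, padded), dtype=dout.dtype)
        for j in range(self.kernel):
            dxp[:, :, j : j + self.stride * out_len : self.stride] += (
                dout * (self._argmax == j)
            )
        return dxp[:, :, pl : padded - pr if pr else None]


class Dropout(Layer):
    """Inverted dropout; identity at inference.

    ``channel_wise=True`` drops whole feature maps per sample (the 1-D
    convolutional reading of dropout, as in torch's Dropout1d / Keras
    SpatialDropout1D): positions within a conv feature map are strongly
    correlated, so masking individual positions mostly perturbs local sums
    instead of removing features, and the train/eval mismatch it induces
    under downstream batch norm is severe.
    """

    def __init__(self, rate, channel_wise=True):
        super().__init__()
        self.rate = rate
        self.channel_wise = channel_wise
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0], x.shape[1], 1) if self.channel_wise and x.ndim == 3 \
            else x.shape
        self._mask = (
            self.rng.random(shape) < keep
        ).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(
            dout[:, :, None] / self._length, self._length, axis=2
        )


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(out_features, in_features))
        self.params["w"] = w.astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout):
        self.grads["w"][...] = dout.T @ self._x
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["w"]


class ResidualUnit(Layer):
    """activation(x + F(x)) with F = conv-norm-activation-conv-norm.

    With ``stride=2`` the unit downsamples: the first convolution strides by
    2 and the skip path is projected by a kernel-1 stride-2 convolution with
    its own batch norm.
    """

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        super().__init__()
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.conv1 = Conv1d(in_ch, out_ch, 3, stride, rng=rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_ch, out_ch, 3, 1, rng=rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.project = stride != 1 or in_ch != out_ch
        if self.project:
            self.proj_conv = Conv1d(in_ch, out_ch, 1, stride, rng=rng)
            self.proj_bn = BatchNorm1d(out_ch)
        self.relu_out = ReLU()

    @property
    def kind(self) -> str:
        return "downsample" if self.stride != 1 else "residual"

    def sublayers(self):
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.project:
            subs += [self.proj_conv, self.proj_bn]
        return subs

    def forward(self, x, training=False):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        skip = x
        if self.project:
            skip = self.proj_conv.forward(x, training)
            skip = self.proj_bn.forward(skip, training)
        return self.relu_out.forward(h + skip, training)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.project:
            dskip = self.proj_bn.backward(d)
            dx = dx + self.proj_conv.backward(dskip)
        else:
            dx = dx + d
        return dx


class Adam:
    """Adaptive moment estimation over a flat list of (params, grads) dicts."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.slots = []
        for layer in layers:
            for name in layer.params:
                self.slots.append(
                    (
                        layer.params,
                        layer.grads,
                        name,
                        np.zeros_like(layer.params[name]),
                        np.zeros_like(layer.params[name]),
                    )
                )
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for params, grads, name, m, v in self.slots:
            g = grads[name]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[name] -= self.lr * (m / b1t) / (
                np.sqrt(v / b2t) + self.eps
            )


def flatten_layers(layers) -> list[Layer]:
    """Expand residual units into their parameterized sublayers."""
    flat = []
    for layer in layers:
        if isinstance(layer, ResidualUnit):
            flat.extend(layer.sublayers())
        elif layer.params:
            flat.append(layer)
    return flat
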