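"""A compact CPU neural-network layer framework on numpy.

Implements exactly the layer set the classifier zoo needs — 1D/2D
convolution, batch normalization, ReLU, max pooling, dropout, flatten,
linear, and a 2D residual block — each with an explicit forward and
backward pass (im2col convolutions backed by BLAS matmuls, float32
throughout).  Parameters carry a ``trainable`` flag so a frozen backbone
is excluded from optimizer updates while still propagating gradients.

Determinism: all weight initialization and dropout masks draw from
generators supplied by the caller; the framework keeps no global state.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Sequential", "Conv1d", "Conv2d", "BatchNorm",
    "ReLU", "MaxPool1d", "MaxPool2d", "Dropout", "Flatten", "Linear",
    "BasicBlock2d", "softmax", "cross_entropy", "SGD", "Adam",
    "conv_output_length",
]


def conv_output_length(length: int, kernel: int, stride: int, padding: int
                       ) -> int:
    """floor((L + 2p - k) / s) + 1 — the shape rule every layer follows."""
    out = (length + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"kernel {kernel} (stride {stride}, padding {padding}) does not "
            f"fit input extent {length}")
    return out


class Param:
    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.trainable = True
        self.name = name


class Layer:
    def params(self) -> List[Param]:
        return []

    def buffers(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, shape: Tuple[int, ...]) -> Tuple[int, ...]:
        """Propagate a (channels, *spatial) sample shape through the layer."""
        return shape

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def output_shape(self, shape):
        for l in self.layers:
            shape = l.output_shape(shape)
        return shape


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float32) \
        * np.float32(np.sqrt(2.0 / fan_in))


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        self.w = Param(_he_init(rng, (out_channels, in_channels * kernel),
                                in_channels * kernel), "conv1d.w")
        self.b = Param(np.zeros(out_channels), "conv1d.b")

    def params(self):
        return [self.w, self.b]

    def output_shape(self, shape):
        c, L = shape
        if c != self.cin:
            raise ValueError(
                f"conv1d expects {self.cin} input channels, got {c}")
        return (self.cout, conv_output_length(L, self.k, self.s, self.p))

    def forward(self, x, training=False):
        b, c, L = x.shape
        lo = conv_output_length(L, self.k, self.s, self.p)
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p))) if self.p else x
        v = sliding_window_view(xp, self.k, axis=2)[:, :, ::self.s, :]
        cols = np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(
            b * lo, c * self.k)
        y = cols @ self.w.data.T + self.b.data
        self._cache = (cols, x.shape, xp.shape, lo)
        return np.ascontiguousarray(
            y.reshape(b, lo, self.cout).transpose(0, 2, 1))

    def backward(self, grad):
        cols, x_shape, xp_shape, lo = self._cache
        b, c, L = x_shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(
            b * lo, self.cout)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.data).reshape(b, lo, c, self.k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j:j + self.s * lo:self.s] += \
                dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, self.p:self.p + L] if self.p else dxp


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.p = kernel, stride, padding
        fan_in = in_channels * kernel * kernel
        self.w = Param(_he_init(rng, (out_channels, fan_in), fan_in),
                       "conv2d.w")
        self.b = Param(np.zeros(out_channels), "conv2d.b")

    def params(self):
        return [self.w, self.b]

    def output_shape(self, shape):
        c, h, w = shape
        if c != self.cin:
            raise ValueError(
                f"conv2d expects {self.cin} input channels, got {c}")
        return (self.cout,
                conv_output_length(h, self.k, self.s, self.p),
                conv_output_length(w, self.k, self.s, self.p))

    def forward(self, x, training=False):
        b, c, h, w = x.shape
        ho = conv_output_length(h, self.k, self.s, self.p)
        wo = conv_output_length(w, self.k, self.s, self.p)
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p),
                        (self.p, self.p))) if self.p else x
        v = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        v = v[:, :, ::self.s, ::self.s]              # (b,c,ho,wo,k,k)
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * self.k * self.k)
        y = cols @ self.w.data.T + self.b.data
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def backward(self, grad):
        cols, x_shape, xp_shape, ho, wo = self._cache
        b, c, h, w = x_shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            b * ho * wo, self.cout)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.data).reshape(b, ho, wo, c, self.k, self.k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for jh in range(self.k):
            for jw in range(self.k):
                dxp[:, :, jh:jh + self.s * ho:self.s,
                    jw:jw + self.s * wo:self.s] += \
                    dcols[:, :, :, :, jh, jw].transpose(0, 3, 1, 2)
        if self.p:
            return dxp[:, :, self.p:self.p + h, self.p:self.p + w]
        return dxp


class BatchNorm(Layer):
    """Batch normalization over the channel axis (1D or 2D feature maps)."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features), "bn.gamma")
        self.beta = Param(np.zeros(num_features), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _expand(self, v, x):
        shape = [1] * x.ndim
        shape[1] = -1
        return v.reshape(shape)

    @staticmethod
    def _channel_dot(a, b):
        # sum over all axes but 1, without materializing a*b
        spec = {3: "bcl,bcl->c", 4: "bchw,bchw->c"}[a.ndim]
        return np.einsum(spec, a, b)

    def forward(self, x, training=False):
        axes = self._axes(x)
        if training:
            n = np.prod([x.shape[a] for a in axes])
            mean = x.mean(axis=axes)
            xhat = x - self._expand(mean, x)
            var = self._channel_dot(xhat, xhat) / n
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat *= self._expand(inv_std, x)
            self._cache = (xhat, inv_std.astype(np.float32), axes, n)
            return xhat * self._expand(self.gamma.data, x) \
                + self._expand(self.beta.data, x)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        self._cache = None
        return (x - self._expand(self.running_mean, x)) \
            * self._expand((self.gamma.data * inv_std).astype(np.float32), x) \
            + self._expand(self.beta.data, x)

    def backward(self, grad):
        if self._cache is None:
            raise RuntimeError("backward called outside training mode")
        xhat, inv_std, axes, n = self._cache
        self.gamma.grad += self._channel_dot(grad, xhat)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self._expand(self.gamma.data, grad)
        mean_dxhat = dxhat.mean(axis=axes)
        mean_dxhat_xhat = self._channel_dot(dxhat, xhat) / n
        dxhat -= self._expand(mean_dxhat, grad)
        dxhat -= xhat * self._expand(mean_dxhat_xhat, grad)
        dxhat *= self._expand(inv_std, grad)
        return dxhat


class ReLU(Layer):
    # mutates its input and the incoming gradient in place; safe because
    # every producer in this framework hands over a fresh array
    def forward(self, x, training=False):
        self._mask = x > 0
        np.multiply(x, self._mask, out=x)
        return x

    def backward(self, grad):
        np.multiply(grad, self._mask, out=grad)
        return grad


class _MaxPoolBase(Layer):
    def __init__(self, kernel: int, stride: int):
        self.k, self.s = kernel, stride


class MaxPool1d(_MaxPoolBase):
    def output_shape(self, shape):
        c, L = shape
        return (c, conv_output_length(L, self.k, self.s, 0))

    def forward(self, x, training=False):
        v = sliding_window_view(x, self.k, axis=2)[:, :, ::self.s, :]
        self._idx = v.argmax(axis=-1)
        self._x_shape = x.shape
        return np.ascontiguousarray(v.max(axis=-1))

    def backward(self, grad):
        dx = np.zeros(self._x_shape, dtype=np.float32)
        lo = grad.shape[-1]
        for j in range(self.k):
            dx[:, :, j:j + self.s * lo:self.s] += grad * (self._idx == j)
        return dx


class MaxPool2d(_MaxPoolBase):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__(kernel, stride)
        self.p = padding

    def output_shape(self, shape):
        c, h, w = shape
        return (c, conv_output_length(h, self.k, self.s, self.p),
                conv_output_length(w, self.k, self.s, self.p))

    def forward(self, x, training=False):
        if self.p:
            x = np.pad(x, ((0, 0), (0, 0), (self.p, self.p),
                           (self.p, self.p)), constant_values=-np.inf)
        v = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        v = v[:, :, ::self.s, ::self.s]
        b, c, ho, wo = v.shape[:4]
        vr = v.reshape(b, c, ho, wo, self.k * self.k)
        self._idx = vr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.ascontiguousarray(vr.max(axis=-1))

    def backward(self, grad):
        dx = np.zeros(self._x_shape, dtype=np.float32)
        ho, wo = grad.shape[2], grad.shape[3]
        for j in range(self.k * self.k):
            jh, jw = divmod(j, self.k)
            dx[:, :, jh:jh + self.s * ho:self.s,
               jw:jw + self.s * wo:self.s] += grad * (self._idx == j)
        if self.p:
            return dx[:, :, self.p:-self.p, self.p:-self.p]
        return dx


class Dropout(Layer):
    def __init__(self, rate: float = 0.5,
                 rng: Optional[np.random.Generator] = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = np.asarray(
            self.rng.random(x.shape, dtype=np.float32) >= self.rate,
            dtype=np.float32)
        self._mask /= keep
        np.multiply(x, self._mask, out=x)
        return x

    def backward(self, grad):
        if self._mask is not None:
            np.multiply(grad, self._mask, out=grad)
        return grad


class Flatten(Layer):
    def output_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.nin, self.nout = in_features, out_features
        self.w = Param(_he_init(rng, (out_features, in_features), in_features),
                       "linear.w")
        self.b = Param(np.zeros(out_features), "linear.b")

    def params(self):
        return [self.w, self.b]

    def output_shape(self, shape):
        if shape != (self.nin,):
            raise ValueError(
                f"linear expects {self.nin} features, got {shape}")
        return (self.nout,)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.data


class BasicBlock2d(Layer):
    """Two 3x3 convolutions with identity (or 1x1-projected) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng)
        self.bn1 = BatchNorm(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng)
        self.bn2 = BatchNorm(out_channels)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.down: Optional[Sequential] = Sequential([
                Conv2d(in_channels, out_channels, 1, stride, 0, rng),
                BatchNorm(out_channels)])
        else:
            self.down = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.down is not None:
            out += self.down.params()
        return out

    def output_shape(self, shape):
        return self.conv2.output_shape(self.conv1.output_shape(shape))

    def forward(self, x, training=False):
        h = self.relu1(self.bn1(self.conv1(x, training), training), training)
        h = self.bn2(self.conv2(h, training), training)
        s = self.down(x, training) if self.down is not None else x
        return self.relu_out(h + s, training)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        gs = self.down.backward(g) if self.down is not None else g
        return gh + gs


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray
                  ) -> Tuple[float, np.ndarray]:
    """Mean 3-class cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), targets] + 1e-12).mean())
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


class _Optimizer:
    def __init__(self, params: Sequence[Param], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            if not p.trainable:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam(_Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
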