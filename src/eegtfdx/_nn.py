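"""A small NumPy layer stack for image classifiers.

Implements exactly the pieces the package's architectures need: 2-D
convolution (im2col), ReLU, max/adaptive-average pooling, batch
normalisation, dropout, dense layers, fire modules (SqueezeNet) and
bottleneck residual blocks (ResNet), plus softmax cross-entropy and the
Adam optimizer.  Data layout is NCHW float32 throughout.  All parameter
initialisation draws from a generator passed in at construction time, so
identical seeds give bit-identical models.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base: stateless unless it holds parameters (params/grads lists)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _window_cols(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_h, out_w, padded_shape) for a k x k sliding window."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * k * k
    )
    return cols, oh, ow, (n, c, h, w)


class Conv2D(Layer):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x, train):
        cols, oh, ow, pshape = _window_cols(x, self.k, self.stride, self.pad)
        self._cache = (cols, x.shape, pshape, oh, ow)
        wm = self.W.reshape(self.W.shape[0], -1)
        y = cols @ wm.T
        if self.b is not None:
            y += self.b
        n = x.shape[0]
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, pshape, oh, ow = self._cache
        n, c = xshape[0], xshape[1]
        out_ch = self.W.shape[0]
        gm = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, out_ch)
        self.dW[...] = (gm.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.db[...] = gm.sum(axis=0)
        dcols = (gm @ self.W.reshape(out_ch, -1)).reshape(n, oh, ow, c, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        _, _, hp, wp = pshape
        dxp = np.zeros((n, c, hp, wp), dtype=F32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[..., i, j]
        p = self.pad
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2D(Layer):
    def __init__(self, k, stride=None):
        self.k = k
        self.stride = stride or k

    def forward(self, x, train):
        cols, oh, ow, pshape = _window_cols(x, self.k, self.stride, 0)
        n, c = x.shape[0], x.shape[1]
        win = cols.reshape(n, oh, ow, c, self.k * self.k).transpose(0, 3, 1, 2, 4)
        self._arg = win.argmax(axis=-1)
        self._xshape = x.shape
        self._oh, self._ow = oh, ow
        return win.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._xshape
        oh, ow = self._oh, self._ow
        dx = np.zeros((n, c, h, w), dtype=F32)
        ohg, owg = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        hi = ohg[None, None] * self.stride + self._arg // self.k
        wi = owg[None, None] * self.stride + self._arg % self.k
        nidx = np.arange(n)[:, None, None, None]
        cidx = np.arange(c)[None, :, None, None]
        np.add.at(dx, (nidx, cidx, hi, wi), grad)
        return dx


class AdaptiveAvgPool2D(Layer):
    """Averages over integer bins like the standard adaptive pooling."""

    def __init__(self, out_hw: int):
        self.out_hw = out_hw

    @staticmethod
    def _bins(size, out):
        starts = (np.arange(out) * size) // out
        ends = -((-(np.arange(1, out + 1) * size)) // out)
        return starts, ends

    def forward(self, x, train):
        n, c, h, w = x.shape
        o = self.out_hw
        hs, he = self._bins(h, o)
        ws, we = self._bins(w, o)
        y = np.empty((n, c, o, o), dtype=F32)
        for i in range(o):
            for j in range(o):
                y[:, :, i, j] = x[:, :, hs[i] : he[i], ws[j] : we[j]].mean(axis=(2, 3))
        self._xshape, self._hbins, self._wbins = x.shape, (hs, he), (ws, we)
        return y

    def backward(self, grad):
        n, c, h, w = self._xshape
        o = self.out_hw
        hs, he = self._hbins
        ws, we = self._wbins
        dx = np.zeros((n, c, h, w), dtype=F32)
        for i in range(o):
            for j in range(o):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i] : he[i], ws[j] : we[j]] += (
                    grad[:, :, i : i + 1, j : j + 1] / area
                )
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    def __init__(self, p, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm2D(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(ch, dtype=F32)
        self.beta = np.zeros(ch, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = grad * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        )
        return term * inv[None, :, None, None]

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class Fire(Layer):
    """SqueezeNet fire module: 1x1 squeeze, concatenated 1x1 + 3x3 expand."""

    def __init__(self, in_ch, squeeze, expand1, expand3, rng):
        self.squeeze = Sequential(Conv2D(in_ch, squeeze, 1, rng=rng), ReLU())
        self.e1 = Sequential(Conv2D(squeeze, expand1, 1, rng=rng), ReLU())
        self.e3 = Sequential(Conv2D(squeeze, expand3, 3, pad=1, rng=rng), ReLU())
        self.n1 = expand1

    def forward(self, x, train):
        s = self.squeeze.forward(x, train)
        return np.concatenate(
            [self.e1.forward(s, train), self.e3.forward(s, train)], axis=1
        )

    def backward(self, grad):
        g1 = self.e1.backward(grad[:, : self.n1])
        g3 = self.e3.backward(grad[:, self.n1 :])
        return self.squeeze.backward(g1 + g3)

    def params(self):
        return self.squeeze.params() + self.e1.params() + self.e3.params()

    def grads(self):
        return self.squeeze.grads() + self.e1.grads() + self.e3.grads()


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 -> 3x3 -> 1x1 convs with a residual add."""

    def __init__(self, in_ch, mid, out_ch, stride, rng):
        self.main = Sequential(
            Conv2D(in_ch, mid, 1, rng=rng, bias=False),
            BatchNorm2D(mid),
            ReLU(),
            Conv2D(mid, mid, 3, stride=stride, pad=1, rng=rng, bias=False),
            BatchNorm2D(mid),
            ReLU(),
            Conv2D(mid, out_ch, 1, rng=rng, bias=False),
            BatchNorm2D(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.short = Sequential(
                Conv2D(in_ch, out_ch, 1, stride=stride, rng=rng, bias=False),
                BatchNorm2D(out_ch),
            )
        else:
            self.short = None
        self.relu = ReLU()

    def forward(self, x, train):
        y = self.main.forward(x, train)
        s = self.short.forward(x, train) if self.short else x
        return self.relu.forward(y + s, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        gs = self.short.backward(grad) if self.short else grad
        return self.main.backward(grad) + gs

    def params(self):
        return self.main.params() + (self.short.params() if self.short else [])

    def grads(self):
        return self.main.grads() + (self.short.grads() if self.short else [])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Combined softmax + mean cross-entropy with its analytic gradient."""

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> float:
        self._probs = softmax(logits.astype(np.float64))
        self._targets = targets
        picked = self._probs[np.arange(len(targets)), targets]
        return float(-np.mean(np.log(np.maximum(picked, 1e-12))))

    def backward(self) -> np.ndarray:
        grad = self._probs.copy()
        grad[np.arange(len(self._targets)), self._targets] -= 1.0
        return (grad / len(self._targets)).astype(F32)


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.wd and p.ndim > 1:  # decay weights, not biases/norm params
                g = g + self.wd * p
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g.astype(np.float64) ** 2 - v)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
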