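"""Minimal NumPy neural-network engine used by the residual CNN.

Implements exactly the pieces the swallowing classifier needs — 3x3/1x1
convolutions via im2col, batch normalization, ReLU, 2x2 max pooling,
dense layers, softmax cross-entropy and Adam — with hand-written
backward passes.  Gradient correctness is verified against finite
differences in the test suite.  float32 throughout; all initialization
is driven by an explicit numpy Generator so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool", "Flatten", "Dense", "Dropout",
    "ResidualBlock", "softmax", "cross_entropy_grad", "Adam",
]


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H_out*W_out) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, ho, wo, _, _ = windows.shape
    col = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(col)


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col (stride 1)."""
    n, c, h, w = x_shape
    ho, wo = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    dcol = dcol.reshape(n, c, kh, kw, ho, wo)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + ho, j : j + wo] += dcol[:, :, i, j]
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


class Layer:
    """Base: subclasses hold .params / .grads dicts keyed identically."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' convolution (square kernel, He-normal init)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        self.params["W"] = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._col = _im2col(x, self.k, self.k, self.pad)
        n = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        out = np.matmul(self.params["W"], self._col) + self.params["b"][:, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, -1)
        self.grads["W"] = np.einsum("nfp,nkp->fk", dflat, self._col, optimize=True)
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcol = np.matmul(self.params["W"].T, dflat)
        return _col2im(dcol, self._x_shape, self.k, self.k, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.params["gamma"][None, :, None, None] * self._xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        if not self.training:
            return dout * g / self._std[None, :, None, None]
        dxhat = dout * g
        term1 = dxhat - dxhat.mean(axis=axes)[None, :, None, None]
        term2 = self._xhat * (dxhat * self._xhat).sum(axis=axes)[None, :, None, None] / m
        return (term1 - term2) / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling with window (ph, pw); trailing rows or
    columns that do not fill a window are dropped."""

    def __init__(self, ph: int = 2, pw: int = 2):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = self.ph, self.pw
        self._x_shape = x.shape
        h2, w2 = h // ph, w // pw
        xc = x[:, :, : h2 * ph, : w2 * pw].reshape(n, c, h2, ph, w2, pw)
        out = xc.max(axis=(3, 5))
        self._mask = xc == out[:, :, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        ph, pw = self.ph, self.pw
        h2, w2 = h // ph, w // pw
        # split ties evenly so the adjoint stays exact
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        dx_c = self._mask * (dout[:, :, :, None, :, None] / counts)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, :, : h2 * ph, : w2 * pw] = dx_c.reshape(n, c, h2 * ph, w2 * pw)
        return dx


MaxPool2x2 = MaxPool  # default window is 2x2


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  Mask randomness comes
    from the generator handed in at construction."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn with an identity shortcut (1x1 conv + bn
    projection when the channel width changes), ReLU after the sum."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, k, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, k, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.project = c_in != c_out
        if self.project:
            self.conv_sc = Conv2d(c_in, c_out, 1, rng)
            self.bn_sc = BatchNorm2d(c_out)
        self.relu_out = ReLU()

    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.project:
            subs += [self.conv_sc, self.bn_sc]
        return subs

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn2.forward(self.conv2.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        sc = self.bn_sc.forward(self.conv_sc.forward(x)) if self.project else x
        return self.relu_out.forward(out + sc)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        d_sc = self.conv_sc.backward(self.bn_sc.backward(d)) if self.project else d
        return d_main + d_sc


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and d(loss)/d(logits) for integer labels y."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam over a list of (layer, name) parameter references."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.refs = [(lay, name) for lay in layers for name in lay.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(lay.params[name]) for lay, name in self.refs]
        self.v = [np.zeros_like(lay.params[name]) for lay, name in self.refs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (lay, name) in enumerate(self.refs):
            g = lay.grads[name].astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            lay.params[name] -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.wd > 0 and name == "W":  # decoupled decay on weights only
                lay.params[name] -= self.lr * self.wd * lay.params[name]
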