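"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for a small encoder–decoder segmentation network:
3x3/1x1 convolutions (stride 1 or 2), batch normalisation, ReLU, nearest
2x upsampling, channel concatenation, residual blocks and Adam.  Tensors
are ``(N, C, H, W)`` float32.  Every layer caches what its backward pass
needs during ``forward``; ``backward`` consumes the upstream gradient and
accumulates parameter gradients in place.
"""

from __future__ import annotations

import numpy as np

#: Computation dtype; float32 for speed, switchable to float64 for verification.
DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv2d:
    """2-D convolution, square kernel, 'same' padding for stride 1.

    He-normal weight init.  Forward/backward loop over the k*k kernel
    offsets with strided views, so no im2col copies are materialised.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride = k, stride
        self.pad = k // 2
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cout = self.W.value.shape[0]
        acc = np.zeros((n, ho, wo, cout), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                acc += np.tensordot(xs, self.W.value[:, :, i, j], axes=([1], [1]))
        self._cache = (xp, x.shape)
        out = acc.transpose(0, 3, 1, 2)
        out += self.b.value[None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = dout.shape[2], dout.shape[3]
        dout_t = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (N,Ho,Wo,cout)
        self.b.grad += dout_t.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                self.W.grad[:, :, i, j] += np.tensordot(
                    dout_t, xs, axes=([0, 1, 2], [0, 2, 3])
                )
                dxs = np.tensordot(dout_t, self.W.value[:, :, i, j], axes=([3], [0]))
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dxs.transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward in terms of xhat
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (term1 - term2 - term3)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Upsample2x:
    """Nearest-neighbour 2x spatial upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBNReLU:
    """Conv -> BatchNorm -> ReLU."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv = Conv2d(cin, cout, k, stride, rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class ResidualBlock:
    """Basic two-convolution residual block (identity or 1x1 projection skip)."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj: Conv2d | None = Conv2d(cin, cout, 1, stride, rng)
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def params(self) -> list[Param]:
        out = (
            self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        )
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.proj is not None:
            idn = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            idn = x
        return self.relu2.forward(h + idn, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        if self.proj is not None:
            d_idn = self.proj.backward(self.proj_bn.backward(d))
        else:
            d_idn = d
        return d_main + d_idn


class Adam:
    """Adam optimiser with the conventional defaults."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_warm_restart_lr(
    epoch: int, lr_init: float, lr_min: float, period: int
) -> float:
    """Cosine-annealing-with-warm-restarts schedule, evaluated per epoch.

    ``lr(t) = lr_min + 0.5 (lr_init - lr_min) (1 + cos(pi t_cycle / period))``
    with ``t_cycle = epoch mod period``; the rate snaps back to ``lr_init``
    at every restart boundary.
    """
    t_cycle = epoch % period
    return lr_min + 0.5 * (lr_init - lr_min) * (1 + np.cos(np.pi * t_cycle / period))
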