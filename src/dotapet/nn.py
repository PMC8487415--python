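"""A compact CPU neural-network engine for 2D convolutional models.

Implements exactly the layers the residual U-Net needs — 2D convolution
(im2col + matmul), transposed convolution with kernel size equal to its
stride (non-overlapping learned upsampling), batch normalization, ReLU and
sigmoid — each with an explicit, hand-derived backward pass.  Arrays are
NCHW float32; gradients accumulate into ``Parameter.grad`` and are consumed
by the SGD optimizer in :mod:`dotapet.train`.

All computation is deterministic on CPU for a fixed seed: initialization
draws from a caller-supplied ``numpy.random.Generator`` and no operation
introduces nondeterminism.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    """Base class: children discovered by attribute scan."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module state (parameters + buffers)."""
        return [p.value for p in self.parameters()]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (C*k*k, N*L) patch matrix (BLAS-friendly layout)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]           # (N,C,Ho,Wo,k,k)
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)
                                ).reshape(c * k * k, n * ho * wo)
    return cols, (n, ho, wo)


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain cross-correlation, NCHW x (Co,Ci,k,k)."""
    co, ci, k, _ = w.shape
    cols, (n, ho, wo) = _im2col(x, k, stride, pad)
    out = w.reshape(co, ci * k * k) @ cols
    return out.reshape(co, n, ho, wo).transpose(1, 0, 2, 3)


class Conv2d(Module):
    """k×k convolution, zero padding k//2 ('same' at stride 1)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        co = self.weight.value.shape[0]
        cols, (n, ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.weight.value.reshape(co, -1)
        out = w2 @ cols                            # (co, n*L)
        out += self.bias.value[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(co, n, ho, wo).transpose(1, 0, 2, 3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, co = gout.shape[:2]
        g2 = np.ascontiguousarray(gout.transpose(1, 0, 2, 3)).reshape(co, -1)
        self.weight.grad += (g2 @ cols.T).reshape(self.weight.value.shape)
        self.bias.grad += g2.sum(axis=1)
        # dx = transposed convolution of gout with the kernel
        k, s, p = self.k, self.stride, self.pad
        if s > 1:
            up = np.zeros((n, co, (gout.shape[2] - 1) * s + 1,
                           (gout.shape[3] - 1) * s + 1), DTYPE)
            up[:, :, ::s, ::s] = gout
        else:
            up = gout
        w_flip = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx_full = _conv_raw(up, np.ascontiguousarray(w_flip), 1, k - 1)
        h, w_ = x_shape[2], x_shape[3]
        dx = np.zeros(x_shape, DTYPE)
        dx_crop = dx_full[:, :, p:p + h, p:p + w_]
        dx[:, :, :dx_crop.shape[2], :dx_crop.shape[3]] = dx_crop
        return dx


class ConvTranspose2d(Module):
    """Transposed convolution with kernel size == stride (no overlap)."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (c_in, c_out, stride, stride)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        n, ci, h, w = x.shape
        co = self.weight.value.shape[1]
        xm = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(ci, -1)
        w2 = self.weight.value.reshape(ci, co * s * s)
        y = (w2.T @ xm).reshape(co, s, s, n, h, w)     # (co,a,b,n,i,j)
        out = np.ascontiguousarray(y.transpose(3, 0, 4, 1, 5, 2)
                                   ).reshape(n, co, h * s, w * s)
        out += self.bias.value[None, :, None, None]
        self._cache = xm
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xm = self._cache
        s = self.stride
        ci, co = self.weight.value.shape[:2]
        n = gout.shape[0]
        h, w = gout.shape[2] // s, gout.shape[3] // s
        g6 = np.ascontiguousarray(
            gout.reshape(n, co, h, s, w, s).transpose(1, 3, 5, 0, 2, 4)
        ).reshape(co * s * s, n * h * w)               # (co*a*b, n*i*j)
        self.weight.grad += (xm @ g6.T).reshape(self.weight.value.shape)
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        w2 = self.weight.value.reshape(ci, co * s * s)
        dx = (w2 @ g6).reshape(ci, n, h, w)
        return dx.transpose(1, 0, 2, 3)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, DTYPE)
        self.running_var = np.ones(c, DTYPE)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxhat = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * g - gsum - xhat * gxhat)

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.value, self.beta.value,
                self.running_mean, self.running_var]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Sigmoid(Module):
    """Logistic output clamped to [δ, 1−δ].

    The clamp matches the probability clipping of the binary cross-entropy
    loss, so the gradient chained through this layer is exactly (p − t)/N —
    the fused sigmoid+BCE gradient — and never vanishes when the layer
    saturates.  Without it, deeply saturated score maps (p ≈ 1e-20) would
    multiply the clipped loss gradient by p(1 − p) ≈ 0 and training could
    permanently collapse to the all-background solution.
    """

    DELTA = 1e-7

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.clip(x, -60.0, 60.0)   # exp-safe
        np.negative(out, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        np.clip(out, self.DELTA, 1.0 - self.DELTA, out=out)
        self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._out * (1.0 - self._out)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class ResBlock(Module):
    """conv-bn-relu-conv-bn + projection shortcut, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.project = None
        if c_in != c_out:
            self.project = Conv2d(c_in, c_out, 1, rng=rng)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x))
        h = self.relu1.forward(h)
        h = self.bn2.forward(self.conv2.forward(h))
        shortcut = x if self.project is None else self.project.forward(x)
        return self.relu_out.forward(h + shortcut)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        g_short = g if self.project is None else self.project.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return g + g_short


def num_parameters(module: Module) -> int:
    return int(sum(p.value.size for p in module.parameters()))


def get_state(module: Module) -> list[np.ndarray]:
    """Copies of all parameter values and batch-norm running buffers."""
    out = []
    _collect_state(module, out)
    return [a.copy() for a in out]


def set_state(module: Module, state: list[np.ndarray]) -> None:
    arrays: list[np.ndarray] = []
    _collect_state(module, arrays)
    if len(arrays) != len(state):
        raise ValueError("state length mismatch")
    for dst, src in zip(arrays, state):
        dst[...] = src


def _collect_state(module: Module, out: list[np.ndarray]) -> None:
    if isinstance(module, BatchNorm2d):
        out.extend([module.gamma.value, module.beta.value,
                    module.running_mean, module.running_var])
        return
    for v in module.__dict__.values():
        if isinstance(v, Parameter):
            out.append(v.value)
        elif isinstance(v, Module):
            _collect_state(v, out)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    _collect_state(item, out)
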