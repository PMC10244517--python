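"""Minimal CPU building blocks for the 3-D segmentation network.

This is a compact, self-contained implementation of the handful of layer
types the U-Net needs — 3x3x3 convolution (stride 1 and 2), instance
normalisation, ReLU, nearest-neighbour upsampling, a 1x1x1 classification
head, softmax cross-entropy and Adam — with explicit forward/backward
passes on float32 NumPy arrays.  The 3x3x3 convolution inner loops are
JIT-compiled with numba; everything else is plain vectorised NumPy.

Array layout is channels-first: activations are ``(C, X, Y, Z)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# numba convolution kernels
# ---------------------------------------------------------------------------


@njit(fastmath=True, cache=True)
def _conv_fwd_s1(xp, w, out):  # pragma: no cover - exercised via Conv3x3
    cout, cin = w.shape[0], w.shape[1]
    nx, ny, nz = out.shape[1], out.shape[2], out.shape[3]
    for i in range(nx):
        for j in range(ny):
            for co in range(cout):
                for ci in range(cin):
                    for dx in range(3):
                        for dy in range(3):
                            row = xp[ci, i + dx, j + dy]
                            w0 = w[co, ci, dx, dy, 0]
                            w1 = w[co, ci, dx, dy, 1]
                            w2 = w[co, ci, dx, dy, 2]
                            for k in range(nz):
                                out[co, i, j, k] += w0 * row[k] + w1 * row[k + 1] + w2 * row[k + 2]


@njit(fastmath=True, cache=True)
def _conv_bwd_w_s1(xp, dout, dw):  # pragma: no cover
    cout, cin = dw.shape[0], dw.shape[1]
    nx, ny, nz = dout.shape[1], dout.shape[2], dout.shape[3]
    for i in range(nx):
        for j in range(ny):
            for co in range(cout):
                g = dout[co, i, j]
                for ci in range(cin):
                    for dx in range(3):
                        for dy in range(3):
                            row = xp[ci, i + dx, j + dy]
                            s0 = np.float32(0.0)
                            s1 = np.float32(0.0)
                            s2 = np.float32(0.0)
                            for k in range(nz):
                                gk = g[k]
                                s0 += row[k] * gk
                                s1 += row[k + 1] * gk
                                s2 += row[k + 2] * gk
                            dw[co, ci, dx, dy, 0] += s0
                            dw[co, ci, dx, dy, 1] += s1
                            dw[co, ci, dx, dy, 2] += s2


def _pad1(x: np.ndarray) -> np.ndarray:
    c, nx, ny, nz = x.shape
    out = np.zeros((c, nx + 2, ny + 2, nz + 2), dtype=np.float32)
    out[:, 1:-1, 1:-1, 1:-1] = x
    return out


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


_OFFSETS = [(dx, dy, dz) for dx in range(3) for dy in range(3) for dz in range(3)]


class Conv3x3:
    """3x3x3 convolution, zero-padded, stride 1 or 2 (same / halved output).

    Two execution paths with identical arithmetic: JIT loop kernels for
    thin-channel stride-1 layers, and 27-shift BLAS matmuls for
    wide-channel or strided layers (where sgemm wins).
    """

    BLAS_MIN_CIN = 16

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        fan_in = cin * 27
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3, 3)))
        self.b = Param(np.zeros(cout))
        self.stride = stride
        self._xp: np.ndarray | None = None
        self._out_shape: tuple[int, int, int] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _use_blas(self, cin: int) -> bool:
        return self.stride > 1 or cin >= self.BLAS_MIN_CIN

    def _views(self, xp: np.ndarray, out_shape) -> list[np.ndarray]:
        s = self.stride
        nx, ny, nz = out_shape
        return [
            xp[:, dx : dx + (nx - 1) * s + 1 : s, dy : dy + (ny - 1) * s + 1 : s, dz : dz + (nz - 1) * s + 1 : s]
            for dx, dy, dz in _OFFSETS
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = _pad1(x)
        self._xp = xp
        s = self.stride
        cout, cin = self.w.value.shape[:2]
        out_shape = tuple((d + s - 1) // s for d in x.shape[1:])
        self._out_shape = out_shape
        if self._use_blas(cin):
            n = int(np.prod(out_shape))
            flat = np.zeros((cout, n), dtype=np.float32)
            for (dx, dy, dz), view in zip(_OFFSETS, self._views(xp, out_shape)):
                w_off = np.ascontiguousarray(self.w.value[:, :, dx, dy, dz])
                flat += w_off @ view.reshape(cin, n)
            out = flat.reshape(cout, *out_shape)
        else:
            out = np.zeros((cout, *out_shape), dtype=np.float32)
            _conv_fwd_s1(xp, self.w.value, out)
        out += self.b.value[:, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        self.b.grad += dout.sum(axis=(1, 2, 3))
        cout, cin = self.w.value.shape[:2]
        if self._use_blas(cin):
            n = dout[0].size
            flat = dout.reshape(cout, n)
            dxp = np.zeros_like(self._xp)
            dviews = self._views(dxp, self._out_shape)
            for (dx, dy, dz), view, dview in zip(
                _OFFSETS, self._views(self._xp, self._out_shape), dviews
            ):
                self.w.grad[:, :, dx, dy, dz] += flat @ view.reshape(cin, n).T
                w_off = np.ascontiguousarray(self.w.value[:, :, dx, dy, dz])
                dview += (w_off.T @ flat).reshape(cin, *self._out_shape)
            dx_full = dxp[:, 1:-1, 1:-1, 1:-1]
        else:
            _conv_bwd_w_s1(self._xp, dout, self.w.grad)
            # input gradient = correlation of dout with the flipped,
            # transposed kernel — reuse the fast forward kernel
            wt = np.ascontiguousarray(
                self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            dx_full = np.zeros((cin, *(d - 2 for d in self._xp.shape[1:])), dtype=np.float32)
            _conv_fwd_s1(_pad1(dout), wt, dx_full)
        self._xp = None
        return np.ascontiguousarray(dx_full)


class InstanceNorm:
    """Per-channel normalisation over the spatial axes (batch size is 1)."""

    EPS = 1e-5

    def __init__(self, channels: int):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1)
        var = flat.var(axis=1)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (flat - mu[:, None]) * inv[:, None]
        self._cache = (xhat, inv, x.shape)
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        c = shape[0]
        dflat = dout.reshape(c, -1).astype(np.float32)
        n = dflat.shape[1]
        self.gamma.grad += (dflat * xhat).sum(axis=1)
        self.beta.grad += dflat.sum(axis=1)
        dxhat = dflat * self.gamma.value[:, None]
        dx = (
            inv[:, None]
            / n
            * (n * dxhat - dxhat.sum(axis=1, keepdims=True) - xhat * (dxhat * xhat).sum(axis=1, keepdims=True))
        )
        return dx.reshape(shape).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Upsample2x:
    """Nearest-neighbour doubling of all three spatial axes."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, nx, ny, nz = dout.shape
        d = dout.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
        return d.sum(axis=(2, 4, 6)).astype(np.float32)


class Head1x1:
    """1x1x1 convolution producing per-voxel class scores."""

    def __init__(self, cin: int, n_classes: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (n_classes, cin)))
        self.b = Param(np.zeros(n_classes))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.tensordot(self.w.value, x, axes=(1, 0))
        return (out + self.b.value[:, None, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._x.shape[0]
        k = dout.shape[0]
        self.w.grad += dout.reshape(k, -1) @ self._x.reshape(c, -1).T
        self.b.grad += dout.sum(axis=(1, 2, 3))
        dx = np.tensordot(self.w.value.T, dout, axes=(1, 0)).astype(np.float32)
        self._x = None
        return dx


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean voxel-wise cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is ``(n_classes, X, Y, Z)``, ``labels`` integer ``(X, Y, Z)``.
    """
    p = softmax(logits, axis=0)
    n = labels.size
    flat_idx = labels.reshape(-1).astype(np.int64)
    p_true = p.reshape(p.shape[0], -1)[flat_idx, np.arange(n)]
    loss = float(-np.log(np.maximum(p_true, 1e-12)).mean())
    grad = p  # p is a fresh softmax output; safe to reuse in place
    grad.reshape(p.shape[0], -1)[flat_idx, np.arange(n)] -= 1.0
    grad *= np.float32(1.0 / n)
    return loss, grad


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.grad[:] = 0.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0.0
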