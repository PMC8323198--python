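"""Minimal NumPy neural-network engine used by the segmentation models.

Layers operate on float32 channels-last (N, H, W, C) tensors and implement an
explicit forward/backward pair; the backward pass accumulates gradients into
``Param.grad``.  Convolutions are stride-1 "same" correlations computed as
k*k shifted GEMMs over the padded image rather than via materialized im2col
patch matrices, whose strided copies would dominate NumPy runtime; the
channels-last layout keeps every GEMM operand contiguous, which is what
makes a pure-NumPy training loop viable on one CPU.  Bilinear resampling is
expressed as two small dense resize matrices (rows/columns), so its adjoint
is exact.

The engine implements only the operations the segmentation architectures
need; it is not a general autodiff system.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

F32 = np.float32

# Upper bound on im2col scratch elements (~300 MB of float32).
_MAX_COL_ELEMS = 75_000_000


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable arrays carried by the layer (e.g. BN moving stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _correlate(x: np.ndarray, kernel: np.ndarray, pad_mode: str) -> np.ndarray:
    """Stride-1 same-size correlation of NHWC ``x`` with ``kernel`` (k,k,Ci,Co).

    Computed as k*k shifted GEMMs over the padded image: each tap multiplies
    the whole (contiguous) padded tensor by one (Ci, Co) kernel slice and
    accumulates a shifted window of the result.  This avoids materializing
    im2col patch columns, whose strided copies dominate runtime in NumPy.
    """
    n, h, w, c = x.shape
    k, _, ci, co = kernel.shape
    assert ci == c, (ci, c)
    p = k // 2
    if p == 0:
        y = x.reshape(n * h * w, c) @ kernel.reshape(ci, co)
        return y.reshape(n, h, w, co)
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode=pad_mode)
    hp, wp = h + 2 * p, w + 2 * p
    xf = xp.reshape(n * hp * wp, c)
    out = np.zeros((n, h, w, co), F32)
    if n * hp * wp * k * k * co <= _MAX_COL_ELEMS:
        # One fat GEMM for all k*k taps, then k*k shifted accumulations.
        taps = (xf @ kernel.transpose(2, 0, 1, 3).reshape(c, k * k * co)).reshape(
            n, hp, wp, k * k, co
        )
        for di in range(k):
            for dj in range(k):
                out += taps[:, di : di + h, dj : dj + w, di * k + dj, :]
    else:
        for di in range(k):
            for dj in range(k):
                t = (xf @ kernel[di, dj]).reshape(n, hp, wp, co)
                out += t[:, di : di + h, dj : dj + w, :]
    return out


class Conv2d(Layer):
    """3x3 (or 1x1) convolution, stride 1, same padding, He-normal init.

    Kernels are stored as (k, k, cin, cout) to match the im2col layout.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        ksize: int = 3,
        rng: Optional[np.random.Generator] = None,
        padding_mode: str = "zeros",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * ksize * ksize
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k = ksize
        if padding_mode not in ("zeros", "circular"):
            raise ValueError(f"unknown padding_mode {padding_mode!r}")
        self.pad_mode = "constant" if padding_mode == "zeros" else "wrap"
        self._x: Optional[np.ndarray] = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        y = _correlate(x, self.W.data, self.pad_mode)
        y += self.b.data
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward() requires a forward(training=True) call"
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        cout = self.W.data.shape[-1]
        dy = np.ascontiguousarray(dy, dtype=F32)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        if p == 0:
            dW = x.reshape(n * h * w, c).T @ dy.reshape(n * h * w, cout)
            self.W.grad += dW.reshape(self.W.data.shape)
        else:
            # dW[di, dj] = (shifted window of padded x)^T @ dy; realised by
            # sliding dy inside a zero buffer so both GEMM operands stay
            # contiguous.
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode=self.pad_mode)
            hp, wp = h + 2 * p, w + 2 * p
            xf = xp.reshape(n * hp * wp, c)
            buf = np.zeros((n, hp, wp, cout), F32)
            for di in range(k):
                for dj in range(k):
                    buf[:, di : di + h, dj : dj + w, :] = dy
                    self.W.grad[di, dj] += xf.T @ buf.reshape(n * hp * wp, cout)
                    buf[:, di : di + h, dj : dj + w, :] = 0.0
        # Adjoint of a same-padded stride-1 correlation: correlate dy with the
        # spatially flipped, channel-transposed kernel under the same padding.
        wt = np.ascontiguousarray(self.W.data[::-1, ::-1].transpose(0, 1, 3, 2))
        dx = _correlate(dy, wt, self.pad_mode)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with moving statistics.

    Carries 4 values per channel: scale, shift, moving mean, moving variance.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.moving_mean = np.zeros(channels, F32)
        self.moving_var = np.ones(channels, F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> list[np.ndarray]:
        return [self.moving_mean, self.moving_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            xhat = (x - mean.astype(F32)) * inv
            self.moving_mean[:] = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var[:] = self.momentum * self.moving_var + (1 - self.momentum) * var
            self._cache = (xhat, inv)
        else:
            inv = (1.0 / np.sqrt(self.moving_var + self.eps)).astype(F32)
            xhat = (x - self.moving_mean) * inv
            self._cache = None
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward() requires forward(training=True)"
        xhat, inv = self._cache
        n, h, w, c = dy.shape
        m = n * h * w
        sdy = dy.sum(axis=(0, 1, 2))
        sdyx = (dy * xhat).sum(axis=(0, 1, 2))
        self.gamma.grad += sdyx.astype(F32)
        self.beta.grad += sdy.astype(F32)
        coef = self.gamma.data * inv / m
        dx = coef * (m * dy - sdy - xhat * sdyx)
        self._cache = None
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0 if training else None
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool input must have even H, W; got {(h, w)}")
        quads = np.stack(
            [x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]],
            axis=-1,
        )  # (n, h/2, w/2, c, 4)
        idx = quads.argmax(axis=-1)
        y = np.take_along_axis(quads, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, h, w, c)) if training else None
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        dx = np.zeros((n, h, w, c), F32)
        offsets = ((0, 0), (0, 1), (1, 0), (1, 1))
        for j, (di, dj) in enumerate(offsets):
            sel = idx == j
            dx[:, di::2, dj::2][sel] = dy[sel]
        self._cache = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def _resize_matrix(n_in: int, n_out: int, wrap: bool) -> np.ndarray:
    """Dense 1-D bilinear resize matrix (align_corners=False convention)."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.floor(src).astype(np.int64)
    t = (src - i0).astype(np.float64)
    i1 = i0 + 1
    if wrap:
        i0 %= n_in
        i1 %= n_in
    else:
        i0 = np.clip(i0, 0, n_in - 1)
        i1 = np.clip(i1, 0, n_in - 1)
    mat = np.zeros((n_out, n_in), np.float64)
    np.add.at(mat, (np.arange(n_out), i0), 1.0 - t)
    np.add.at(mat, (np.arange(n_out), i1), t)
    return mat.astype(F32)


class BilinearUpsample(Layer):
    """Bilinear up-sampling by an integer factor via resize matrices."""

    def __init__(self, factor: int, wrap: bool = False):
        self.factor = int(factor)
        self.wrap = wrap
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _resize_matrix(n_in, n_in * self.factor, self.wrap)
        return self._mats[n_in]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        self._in_shape = (n, h, w, c)
        f = self.factor
        wr, wc = self._mat(h), self._mat(w)
        # rows: (H, h) @ (n, h, w*c) -> (n, H, w*c)
        y = np.matmul(wr, x.reshape(n, h, w * c))
        # cols: (W, w) @ (n*H, w, c) -> (n*H, W, c)
        y = np.matmul(wc, y.reshape(n * h * f, w, c))
        return np.ascontiguousarray(y.reshape(n, h * f, w * f, c))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        f = self.factor
        wr, wc = self._mat(h), self._mat(w)
        dy = np.ascontiguousarray(dy, dtype=F32)
        d = np.matmul(wc.T, dy.reshape(n * h * f, w * f, c))
        d = np.matmul(wr.T, d.reshape(n, h * f, w * c))
        self._in_shape = None
        return np.ascontiguousarray(d.reshape(n, h, w, c))


class Softmax(Layer):
    """Channel-axis (last-axis) softmax; backward maps dL/dP to dL/dlogits."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._p = p if training else None
        return p.astype(F32, copy=False)

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        s = (dp * p).sum(axis=-1, keepdims=True)
        dz = p * (dp - s)
        self._p = None
        return dz.astype(F32, copy=False)


class ConvUnit(Layer):
    """The architecture's atomic block: 3x3 conv -> BN -> ReLU."""

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: Optional[np.random.Generator] = None,
        padding_mode: str = "zeros",
        ksize: int = 3,
    ):
        self.conv = Conv2d(cin, cout, ksize=ksize, rng=rng, padding_mode=padding_mode)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def state(self) -> list[np.ndarray]:
        return self.bn.state()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class Adam:
    """Adam optimizer with bias correction; learning rate is passed per step."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
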