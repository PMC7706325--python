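"""Minimal NumPy neural-network layers with hand-derived backprop.

Tensors are NCHW ``float32`` by default. Each layer keeps its parameters in
``params`` and writes gradients of the scalar loss into ``grads`` during
``backward``. Convolutions are lowered to im2col/col2im matrix products so
that nearly all arithmetic lands in BLAS; the transposed convolution is
implemented as input dilation followed by a stride-1 convolution, which makes
its backward pass a reuse of the ordinary convolution backward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "Dense",
    "ReLU",
    "Flatten",
    "Reshape",
    "Sequential",
]


def _he_init(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _im2col(xp: np.ndarray, k: int, stride: int):
    """Lower padded input (N,C,Hp,Wp) to (N, C*k*k, Ho*Wo) patch columns."""
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, padded_shape, k: int, stride: int, ho: int, wo: int):
    """Adjoint of :func:`_im2col` — scatter-add patch gradients back."""
    n, c, hp, wp = padded_shape
    dxp = np.zeros(padded_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        si = slice(i, i + (ho - 1) * stride + 1, stride)
        for j in range(k):
            sj = slice(j, j + (wo - 1) * stride + 1, stride)
            dxp[:, :, si, sj] += d[:, :, i, j]
    return dxp


def _bmm(a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(p, q) @ (N, q, L) -> (N, p, L).

    For small per-sample panels (L below ~64 columns) the batch is folded
    into one large GEMM — N tiny matmuls would be launch-overhead bound.
    For larger L the batched matmul is already BLAS-efficient and the fold's
    transpose copies would dominate, so it is used directly.
    """
    n, q, l = x.shape
    if l > 64:
        return np.matmul(a, x)
    xt = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(q, n * l)
    y = a @ xt
    return np.ascontiguousarray(y.reshape(a.shape[0], n, l).transpose(1, 0, 2))


def _conv_input_grad_stride1(dy: np.ndarray, w: np.ndarray, cin: int, k: int, pad: int):
    """Input gradient of a stride-1 conv as a matmul correlation.

    Equivalent to col2im scatter-add but BLAS-bound: correlate dy (padded by
    k-1-pad) with the spatially flipped, channel-transposed kernel.
    """
    cout = w.shape[0]
    wr = w.reshape(cout, cin, k, k)[:, :, ::-1, ::-1]
    wt = np.ascontiguousarray(wr.transpose(1, 0, 2, 3)).reshape(cin, cout * k * k)
    pb = k - 1 - pad
    dyp = np.pad(dy, ((0, 0), (0, 0), (pb, pb), (pb, pb))) if pb else dy
    cols, ho, wo = _im2col(dyp, k, 1)
    dx = _bmm(wt, cols)
    return dx.reshape(dy.shape[0], cin, ho, wo)


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray, param_grads: bool = True) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """2-D cross-correlation, weight shape (cout, cin*k*k)."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.params["W"] = _he_init(rng, cin * k * k, (cout, cin * k * k), dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self._cache = None

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        y = _bmm(self.params["W"], cols) + self.params["b"][:, None]
        self._cache = (cols, xp.shape, ho, wo)
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy, param_grads: bool = True):
        cols, padded_shape, ho, wo = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, ho * wo)
        if param_grads:
            self.grads["W"] = np.tensordot(dyf, cols, axes=([0, 2], [0, 2]))
            self.grads["b"] = dyf.sum(axis=(0, 2))
        if self.stride == 1:
            return _conv_input_grad_stride1(dy, self.params["W"], self.cin, self.k, self.pad)
        dcols = _bmm(self.params["W"].T, dyf)
        dxp = _col2im(dcols, padded_shape, self.k, self.stride, ho, wo)
        p = self.pad
        return dxp[:, :, p:-p, p:-p] if p else dxp


class ConvTranspose2D(Layer):
    """Stride-s learnable upsampling: dilate the input, then stride-1 conv.

    With ``k=4, stride=2, pad=1`` the spatial size exactly doubles.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.params["W"] = _he_init(rng, cin * k * k, (cout, cin * k * k), dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self._cache = None

    @property
    def _blockwise(self) -> bool:
        # k == stride, no padding: output 2x2 (or kxk) blocks depend on one
        # input pixel each — a pure matmul, no im2col needed.
        return self.k == self.stride and self.pad == 0

    def forward(self, x):
        n, c, h, w = x.shape
        s = self.stride
        k = self.k
        if self._blockwise:
            xf = x.reshape(n, c, h * w)
            # W rows are (cout, cin*k*k) with patch layout (cin, k, k)
            wm = self.params["W"].reshape(self.cout, c, k * k)
            wm = np.ascontiguousarray(wm.transpose(0, 2, 1)).reshape(self.cout * k * k, c)
            y = _bmm(wm, xf)  # (N, cout*k*k, H*W)
            y = y.reshape(n, self.cout, k, k, h, w).transpose(0, 1, 4, 2, 5, 3)
            y = np.ascontiguousarray(y).reshape(n, self.cout, h * k, w * k)
            y += self.params["b"][None, :, None, None]
            self._cache = (xf, (n, c, h, w))
            return y
        hd, wd = (h - 1) * s + 1, (w - 1) * s + 1
        pp = k - 1 - self.pad
        xd = np.zeros((n, c, hd + 2 * pp, wd + 2 * pp), dtype=x.dtype)
        xd[:, :, pp : pp + hd : s, pp : pp + wd : s] = x
        cols, ho, wo = _im2col(xd, k, 1)
        y = np.matmul(self.params["W"], cols) + self.params["b"][:, None]
        self._cache = (cols, xd.shape, ho, wo, (hd, wd, pp))
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy, param_grads: bool = True):
        n = dy.shape[0]
        k = self.k
        if self._blockwise:
            xf, (n, c, h, w) = self._cache
            dyb = dy.reshape(n, self.cout, h, k, w, k).transpose(0, 1, 3, 5, 2, 4)
            dyb = np.ascontiguousarray(dyb).reshape(n, self.cout * k * k, h * w)
            wm = self.params["W"].reshape(self.cout, c, k * k)
            wm = np.ascontiguousarray(wm.transpose(0, 2, 1)).reshape(self.cout * k * k, c)
            if param_grads:
                dwm = np.tensordot(dyb, xf, axes=([0, 2], [0, 2]))  # (cout*k*k, cin)
                dw = dwm.reshape(self.cout, k * k, c).transpose(0, 2, 1).reshape(self.cout, c * k * k)
                self.grads["W"] = np.ascontiguousarray(dw)
                self.grads["b"] = dy.sum(axis=(0, 2, 3))
            dx = _bmm(wm.T, dyb)
            return dx.reshape(n, c, h, w)
        cols, padded_shape, ho, wo, (hd, wd, pp) = self._cache
        dyf = dy.reshape(n, self.cout, ho * wo)
        if param_grads:
            self.grads["W"] = np.tensordot(dyf, cols, axes=([0, 2], [0, 2]))
            self.grads["b"] = dyf.sum(axis=(0, 2))
        # input grad of the internal stride-1 conv, then undo dilation/pad
        dxd = _conv_input_grad_stride1(dy, self.params["W"], self.cin, self.k, 0)
        s = self.stride
        return dxd[:, :, pp : pp + hd : s, pp : pp + wd : s]


class Dense(Layer):
    def __init__(self, din, dout, rng=None, dtype=np.float32, scale=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if scale is None:
            self.params["W"] = _he_init(rng, din, (din, dout), dtype)
        else:
            self.params["W"] = (rng.standard_normal((din, dout)) * scale).astype(dtype)
        self.params["b"] = np.zeros(dout, dtype=dtype)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy, param_grads: bool = True):
        if param_grads:
            self.grads["W"] = self._x.T @ dy
            self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, param_grads: bool = True):
        return dy * self._mask


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, param_grads: bool = True):
        return dy.reshape(self._shape)


class Reshape(Layer):
    """Reshape each sample to ``target`` (excluding the batch axis)."""

    def __init__(self, target):
        super().__init__()
        self.target = tuple(target)
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy, param_grads: bool = True):
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy, param_grads: bool = True):
        for layer in reversed(self.layers):
            dy = layer.backward(dy, param_grads=param_grads)
        return dy

    def named_params(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}.{name}", layer, name

    def l2_penalty(self, coeff: float) -> float:
        """Sum of squared weights (biases excluded), times ``coeff``."""
        total = 0.0
        for name, layer, key in self.named_params():
            if key == "W":
                w = layer.params[key]
                total += float(np.vdot(w, w))
        return coeff * total

    def add_l2_grads(self, coeff: float) -> None:
        for name, layer, key in self.named_params():
            if key == "W":
                layer.grads[key] = layer.grads[key] + 2.0 * coeff * layer.params[key]
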