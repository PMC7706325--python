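"""Single-layer LSTM with full backpropagation through time.

Input is (N, T, D); the layer returns the full hidden sequence (N, T, H).
Gate order in the fused weight matrix is input, forget, cell, output; the
forget-gate bias is initialised to 1 (standard practice for short sequences).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    def __init__(self, din, hidden, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.din, self.hidden = din, hidden
        scale = 1.0 / np.sqrt(din + hidden)
        self.params["W"] = (rng.standard_normal((din + hidden, 4 * hidden)) * scale).astype(dtype)
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget bias
        self.params["b"] = b
        self._cache = None

    def forward(self, x):
        n, t, d = x.shape
        h_dim = self.hidden
        w, b = self.params["W"], self.params["b"]
        h = np.zeros((n, h_dim), dtype=x.dtype)
        c = np.zeros((n, h_dim), dtype=x.dtype)
        hs = np.empty((n, t, h_dim), dtype=x.dtype)
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            concat = np.concatenate([xt, h], axis=1)
            z = concat @ w + b
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h = o * tanh_c
            hs[:, step, :] = h
            cache.append((concat, i, f, g, o, c, c_new, tanh_c))
            c = c_new
        self._cache = (cache, x.shape)
        return hs

    def backward(self, dhs):
        cache, (n, t, d) = self._cache
        h_dim = self.hidden
        w = self.params["W"]
        dw = np.zeros_like(w)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((n, t, d), dtype=dhs.dtype)
        dh_next = np.zeros((n, h_dim), dtype=dhs.dtype)
        dc_next = np.zeros((n, h_dim), dtype=dhs.dtype)
        for step in range(t - 1, -1, -1):
            concat, i, f, g, o, c_prev, c_new, tanh_c = cache[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dw += concat.T @ dz
            db += dz.sum(axis=0)
            dconcat = dz @ w.T
            dx[:, step, :] = dconcat[:, :d]
            dh_next = dconcat[:, d:]
        self.grads["W"] = dw
        self.grads["b"] = db
        return dx
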