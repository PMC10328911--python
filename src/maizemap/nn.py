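"""A small NumPy neural-network core: stacked LSTM, MLP head, Adam.

The pipeline's classifier is a 3-layer LSTM over short (4-step) band
sequences followed by a fully connected head; sequences are tiny, batches
small, so plain vectorised NumPy with hand-written backpropagation is fast
enough and keeps the whole training loop dependency-free and bit-reproducible
on one thread.

Shapes: inputs are (N, T, D); the LSTM returns the final hidden state
(N, H); gates are ordered i, f, g, o in the concatenated weight matrices.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _uniform(rng, shape, fan_in):
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape)


class LSTMStack:
    """``n_layers`` LSTM layers, hidden size H, returning h_T of the top layer."""

    def __init__(self, input_dim: int, hidden: int, n_layers: int, rng):
        self.hidden = hidden
        self.n_layers = n_layers
        self.params: dict[str, np.ndarray] = {}
        for l in range(n_layers):
            d = input_dim if l == 0 else hidden
            self.params[f"Wx{l}"] = _uniform(rng, (d, 4 * hidden), hidden)
            self.params[f"Wh{l}"] = _uniform(rng, (hidden, 4 * hidden), hidden)
            self.params[f"b{l}"] = _uniform(rng, (4 * hidden,), hidden)

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        n, t, _ = x.shape
        h_dim = self.hidden
        inp = x
        for l in range(self.n_layers):
            wx, wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"])
            h = np.zeros((n, h_dim))
            c = np.zeros((n, h_dim))
            outs = np.empty((n, t, h_dim))
            for ti in range(t):
                z = inp[:, ti, :] @ wx + h @ wh + b
                i, f = sigmoid(z[:, :h_dim]), sigmoid(z[:, h_dim:2 * h_dim])
                g, o = np.tanh(z[:, 2 * h_dim:3 * h_dim]), sigmoid(z[:, 3 * h_dim:])
                c_prev = c
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                outs[:, ti, :] = h
                if cache is not None:
                    cache[(l, ti)] = (inp[:, ti, :], i, f, g, o, c_prev, tc)
            if cache is not None:
                cache[("out", l)] = outs
            inp = outs
        return inp[:, -1, :]

    def backward(self, x: np.ndarray, cache: dict, dh_last: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT given the gradient on the top layer's final hidden state."""
        n, t, _ = x.shape
        h_dim = self.hidden
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        # gradient flowing into each layer's output sequence
        d_out = np.zeros((n, t, h_dim))
        d_out[:, -1, :] = dh_last
        for l in range(self.n_layers - 1, -1, -1):
            wx, wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            d_inp = np.zeros((n, t, wx.shape[0]))
            dh_next = np.zeros((n, h_dim))
            dc_next = np.zeros((n, h_dim))
            for ti in range(t - 1, -1, -1):
                x_t, i, f, g, o, c_prev, tc = cache[(l, ti)]
                dh = d_out[:, ti, :] + dh_next
                dc = dc_next + dh * o * (1.0 - tc ** 2)
                di = dc * g * i * (1.0 - i)
                df = dc * c_prev * f * (1.0 - f)
                dg = dc * i * (1.0 - g ** 2)
                do = dh * tc * o * (1.0 - o)
                dz = np.concatenate([di, df, dg, do], axis=1)
                grads[f"Wx{l}"] += x_t.T @ dz
                h_prev = cache[("out", l)][:, ti - 1, :] if ti > 0 else np.zeros((n, h_dim))
                grads[f"Wh{l}"] += h_prev.T @ dz
                grads[f"b{l}"] += dz.sum(axis=0)
                d_inp[:, ti, :] = dz @ wx.T
                dh_next = dz @ wh.T
                dc_next = dc * f
            d_out = d_inp  # becomes dh on the layer below's outputs
        return grads


class Dense:
    """Fully connected layer with optional tanh activation."""

    def __init__(self, d_in: int, d_out: int, activation: str, rng, name: str):
        self.activation = activation
        self.name = name
        self.params = {f"W_{name}": _uniform(rng, (d_in, d_out), d_in),
                       f"b_{name}": _uniform(rng, (d_out,), d_in)}

    def forward(self, x, cache=None):
        z = x @ self.params[f"W_{self.name}"] + self.params[f"b_{self.name}"]
        a = np.tanh(z) if self.activation == "tanh" else z
        if cache is not None:
            cache[self.name] = (x, a)
        return a

    def backward(self, cache, da):
        x, a = cache[self.name]
        dz = da * (1.0 - a ** 2) if self.activation == "tanh" else da
        grads = {f"W_{self.name}": x.T @ dz, f"b_{self.name}": dz.sum(axis=0)}
        return grads, dz @ self.params[f"W_{self.name}"].T


class Adam:
    """Adaptive-moment optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
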