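"""Minimal numpy neural-network kernels: LSTM, dense layers, Adam.

Only what the single-step actor-critic needs: batched forward passes with
caches, exact reverse-mode gradients, and an Adam optimiser over named
parameter dicts.  Shapes follow the (batch, time, feature) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glorot", "lstm_init", "lstm_forward", "lstm_backward",
           "dense_init", "Adam"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape=None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, (fan_in, fan_out) if shape is None else shape)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_init(rng: np.random.Generator, d_in: int, d_hidden: int,
              prefix: str = "lstm") -> dict:
    """Parameters of one LSTM layer; forget-gate bias starts at +1."""
    b = np.zeros(4 * d_hidden)
    b[d_hidden:2 * d_hidden] = 1.0
    return {
        f"{prefix}.Wx": glorot(rng, d_in, 4 * d_hidden),
        f"{prefix}.Wh": glorot(rng, d_hidden, 4 * d_hidden),
        f"{prefix}.b": b,
    }


def lstm_forward(params: dict, x: np.ndarray, prefix: str = "lstm"):
    """Run an LSTM over ``x`` of shape (B, T, D); return the final hidden
    state (B, H) and a cache for :func:`lstm_backward`."""
    Wx, Wh, b = (params[f"{prefix}.Wx"], params[f"{prefix}.Wh"],
                 params[f"{prefix}.b"])
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        steps.append((x[:, t], h, c, i, f, g, o, tc))
        h, c = o * tc, c_new
    return h, {"steps": steps, "prefix": prefix, "H": H}


def lstm_backward(params: dict, dh_last: np.ndarray, cache: dict) -> dict:
    """Gradients of a scalar loss w.r.t. LSTM parameters given the gradient
    at the final hidden state."""
    prefix, H = cache["prefix"], cache["H"]
    Wx, Wh = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for x_t, h_prev, c_prev, i, f, g, o, tc in reversed(cache["steps"]):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di, df, dg = dc * g, dc * c_prev, dc * i
        dz = np.concatenate([
            di * i * (1 - i), df * f * (1 - f),
            dg * (1 - g * g), do * o * (1 - o)], axis=1)
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return {f"{prefix}.Wx": dWx, f"{prefix}.Wh": dWh, f"{prefix}.b": db}


def dense_init(rng: np.random.Generator, d_in: int, d_out: int,
               prefix: str) -> dict:
    return {f"{prefix}.W": glorot(rng, d_in, d_out),
            f"{prefix}.b": np.zeros(d_out)}


class Adam:
    """Adam over a named parameter dict (in-place updates)."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in {k}")
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}
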