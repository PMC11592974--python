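"""Minimal NumPy neural-network primitives: LSTM, affine layers, Adam.

Parameters are flat dicts of arrays so optimizers and (de)serialization
stay trivial.  Initialization is the standard uniform fan-in scheme
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) from a caller-supplied Generator, so
every training run is reproducible from its seed.

The LSTM uses the conventional cell

    z_t = x_t Wx + h_{t-1} Wh + b          (gate order i, f, g, o)
    c_t = sigma(f) * c_{t-1} + sigma(i) * tanh(g)
    h_t = sigma(o) * tanh(c_t)

and the backward pass here propagates the gradient of a loss that depends
only on the final hidden state h_T (the slice summary used downstream),
including the gradient with respect to the inputs so stacked layers work.
Correctness is pinned by numeric-gradient tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "relu",
    "softmax",
    "uniform_init",
    "dense_init",
    "dense_forward",
    "lstm_init",
    "lstm_forward",
    "lstm_backward",
    "Adam",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def dense_init(rng: np.random.Generator, d_in: int, d_out: int, prefix: str) -> dict:
    return {
        f"{prefix}.W": uniform_init(rng, (d_in, d_out), d_in),
        f"{prefix}.b": np.zeros(d_out),
    }


def dense_forward(params: dict, prefix: str, x: np.ndarray) -> np.ndarray:
    return x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]


def lstm_init(rng: np.random.Generator, d_in: int, hidden: int, prefix: str) -> dict:
    return {
        f"{prefix}.Wx": uniform_init(rng, (d_in, 4 * hidden), d_in),
        f"{prefix}.Wh": uniform_init(rng, (hidden, 4 * hidden), hidden),
        f"{prefix}.b": np.zeros(4 * hidden),
    }


def lstm_forward(params: dict, prefix: str, X: np.ndarray):
    """Run the LSTM over X (B, L, d); return (h_T (B, H), cache)."""
    Wx, Wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    B, L, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    H_seq = np.empty((B, L, H))
    for t in range(L):
        z = X[:, t] @ Wx + h @ Wh + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        H_seq[:, t] = h
        steps.append((i, f, g, o, c_prev, c))
    cache = {"X": X, "steps": steps, "prefix": prefix, "H": H, "H_seq": H_seq}
    return h, cache


def lstm_backward(params: dict, cache: dict, dh_T: np.ndarray | None = None,
                  dH_seq: np.ndarray | None = None):
    """Backprop gradients on the hidden states; return (grads, dX).

    ``dh_T`` is a gradient on the final hidden state only; ``dH_seq``
    (B, L, H) supplies per-step gradients (used when a stacked layer
    consumes the full hidden sequence).  Either or both may be given.
    """
    prefix, H = cache["prefix"], cache["H"]
    Wx, Wh = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"]
    X, steps = cache["X"], cache["steps"]
    B, L, d = X.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros_like(X)
    dh = np.zeros((B, H)) if dh_T is None else dh_T.copy()
    dc = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        if dH_seq is not None:
            dh = dh + dH_seq[:, t]
        i, f, g, o, c_prev, c = steps[t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        if t == 0:
            h_prev = np.zeros((B, H))
        else:
            _, _, _, o_prev, _, c_prev_step = steps[t - 1]
            h_prev = o_prev * np.tanh(c_prev_step)
        dWx += X[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh = dz @ Wh.T
        dc = dc * f
    grads = {f"{prefix}.Wx": dWx, f"{prefix}.Wh": dWh, f"{prefix}.b": db}
    return grads, dX


class Adam:
    """Adaptive-moment optimizer over a flat parameter dict (in-place steps)."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
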