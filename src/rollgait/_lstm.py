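"""Numerical engine: stacked-LSTM forward/backward, Adam, gradient clipping.

Implements a standard stacked LSTM for scalar-per-step sequences followed by
a single linear unit with sigmoid output. Written directly in NumPy
(float32): per-timestep recurrences are looped, while every computation that
does not depend on the recurrence — input projections, weight-gradient
contractions — is batched over all timesteps into single BLAS calls, which is
what makes CPU training of the 2x256 configuration practical.

Gate order in the fused weight matrices is (input, forget, cell, output).
Forget-gate biases start at 1, a common initialization that keeps early
memory cells open. Weights start Uniform(-k, k) with fan-in scaling:
k = 1/sqrt(input_dim) for input-to-hidden matrices and k = 1/sqrt(hidden)
for recurrent matrices and the head. Fan-in scaling matters here because
the first layer's input is a single scalar: scaling its weights by
1/sqrt(hidden) instead would leave the hidden dynamics almost insensitive
to the input at large layer widths, and training stalls at the
constant-output plateau.

Dropout (inverted scaling) is applied to the output sequence of every LSTM
layer except the last — the stacked-RNN convention — with masks drawn
i.i.d. per element and timestep. It is active only when a training RNG is
supplied. The final hidden state feeds the head undropped: corrupting the
head's only input at tiny batch sizes injects so much gradient noise that
optimization reliably stalls on the constant-output plateau.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def init_params(
    input_size: int, hidden_units: int, num_layers: int, seed
) -> dict[str, np.ndarray]:
    """Deterministically initialize all weights for a given seed."""
    rng = np.random.default_rng(seed)
    h = hidden_units
    k = 1.0 / np.sqrt(h)
    params: dict[str, np.ndarray] = {}
    for layer in range(num_layers):
        d = input_size if layer == 0 else h
        kx = 1.0 / np.sqrt(d)
        params[f"lstm{layer}.Wx"] = rng.uniform(-kx, kx, (d, 4 * h)).astype(DTYPE)
        params[f"lstm{layer}.Wh"] = rng.uniform(-k, k, (h, 4 * h)).astype(DTYPE)
        b = np.zeros(4 * h, dtype=DTYPE)
        b[h : 2 * h] = 1.0  # open forget gates
        params[f"lstm{layer}.b"] = b
    params["head.w"] = rng.uniform(-k, k, (h, 1)).astype(DTYPE)
    params["head.b"] = np.zeros(1, dtype=DTYPE)
    return params


def forward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    num_layers: int,
    hidden_units: int,
    *,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Run the network on a batch of sequences.

    Parameters
    ----------
    X : (B, T) array of scalar inputs per step.
    dropout, rng : dropout is applied only when ``rng`` is given (training).

    Returns ``(probs, cache)`` where ``probs`` has shape (B,) and ``cache``
    is None unless ``want_cache``.
    """
    B, T = X.shape
    H = hidden_units
    train = rng is not None and dropout > 0.0
    keep = 1.0 - dropout

    seq = np.ascontiguousarray(X.T[:, :, None], dtype=DTYPE)  # (T, B, 1)
    layers = []
    for layer in range(num_layers):
        Wx = params[f"lstm{layer}.Wx"]
        Wh = params[f"lstm{layer}.Wh"]
        b = params[f"lstm{layer}.b"]
        d = seq.shape[2]
        pre = (seq.reshape(T * B, d) @ Wx + b).reshape(T, B, 4 * H)

        i_s = np.empty((T, B, H), dtype=DTYPE)
        f_s = np.empty((T, B, H), dtype=DTYPE)
        g_s = np.empty((T, B, H), dtype=DTYPE)
        o_s = np.empty((T, B, H), dtype=DTYPE)
        tc_s = np.empty((T, B, H), dtype=DTYPE)
        c_s = np.empty((T, B, H), dtype=DTYPE)
        h_s = np.zeros((T + 1, B, H), dtype=DTYPE)  # h_s[t] = state before step t

        h = h_s[0]
        c = np.zeros((B, H), dtype=DTYPE)
        for t in range(T):
            a = pre[t] + h @ Wh
            i = expit(a[:, :H])
            f = expit(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = expit(a[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            i_s[t], f_s[t], g_s[t], o_s[t] = i, f, g, o
            c_s[t], tc_s[t], h_s[t + 1] = c, tc, h

        out = h_s[1:]  # (T, B, H)
        mask = None
        if layer < num_layers - 1 and train:
            mask = (rng.random((T, B, H)) < keep).astype(DTYPE) / keep
            out = out * mask
        layers.append(
            {"x": seq, "pre_shape": d, "i": i_s, "f": f_s, "g": g_s, "o": o_s,
             "c": c_s, "tc": tc_s, "h": h_s, "mask": mask, "out": out}
        )
        seq = out

    h_last = layers[-1]["out"][T - 1]  # (B, H)
    score = h_last @ params["head.w"] + params["head.b"]  # (B, 1)
    probs = expit(score[:, 0]).astype(np.float64)

    cache = None
    if want_cache:
        cache = {
            "layers": layers, "h_last": h_last,
            "probs": probs, "B": B, "T": T, "H": H, "num_layers": num_layers,
        }
    return probs, cache


def backward(
    params: dict[str, np.ndarray], cache: dict, dprobs: np.ndarray
) -> dict[str, np.ndarray]:
    """Backpropagate dL/dprobs through the cached forward pass."""
    B, T, H = cache["B"], cache["T"], cache["H"]
    num_layers = cache["num_layers"]
    grads: dict[str, np.ndarray] = {}

    p = cache["probs"]
    ds = (dprobs * p * (1.0 - p)).astype(DTYPE)[:, None]  # (B, 1)
    h_last = cache["h_last"]
    grads["head.w"] = h_last.T @ ds
    grads["head.b"] = ds.sum(axis=0)
    dh_last = ds @ params["head.w"].T  # (B, H)

    # Gradient w.r.t. each layer's (post-dropout) output sequence.
    dout = np.zeros((T, B, H), dtype=DTYPE)
    dout[T - 1] = dh_last

    for layer in range(num_layers - 1, -1, -1):
        lc = cache["layers"][layer]
        Wx = params[f"lstm{layer}.Wx"]
        Wh = params[f"lstm{layer}.Wh"]
        WhT = np.ascontiguousarray(Wh.T)
        dh_ext = dout * lc["mask"] if lc["mask"] is not None else dout

        i_s, f_s, g_s, o_s = lc["i"], lc["f"], lc["g"], lc["o"]
        c_s, tc_s, h_s = lc["c"], lc["tc"], lc["h"]
        dpre = np.empty((T, B, 4 * H), dtype=DTYPE)
        dh_rec = np.zeros((B, H), dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            dh = dh_ext[t] + dh_rec
            o, tc = o_s[t], tc_s[t]
            dc = dc + dh * o * (1.0 - tc * tc)
            c_prev = c_s[t - 1] if t > 0 else 0.0
            i, f, g = i_s[t], f_s[t], g_s[t]
            blk = dpre[t]
            blk[:, :H] = dc * g * i * (1.0 - i)
            blk[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
            blk[:, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
            blk[:, 3 * H :] = dh * tc * o * (1.0 - o)
            dh_rec = blk @ WhT
            dc = dc * f

        flat = dpre.reshape(T * B, 4 * H)
        d = lc["x"].shape[2]
        grads[f"lstm{layer}.Wx"] = lc["x"].reshape(T * B, d).T @ flat
        grads[f"lstm{layer}.Wh"] = h_s[:T].reshape(T * B, H).T @ flat
        grads[f"lstm{layer}.b"] = flat.sum(axis=0)
        if layer > 0:
            dout = (flat @ Wx.T).reshape(T, B, d)
    return grads


def global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values())))


def clip_gradients(grads: dict[str, np.ndarray], clip_norm: float) -> float:
    """Scale all gradients in place so the global norm is <= clip_norm.

    Returns the pre-clip global norm.
    """
    norm = global_norm(grads)
    if clip_norm is not None and norm > clip_norm > 0:
        scale = DTYPE(clip_norm / norm)
        for g in grads.values():
            g *= scale
    return norm


class AdamOptimizer:
    """Standard Adam with bias correction."""

    def __init__(self, params, learning_rate=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
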