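"""Minimal NumPy implementation of the guided multi-task LSTM network.

One LSTM layer unrolled over 4-hour windows, a linear projection from the
hidden state to the per-window encoding, and four small one-hidden-layer
prediction heads (90-day mortality, remaining LOS, next-window RRT,
next-window MV) read off the encoding. Forward, backward-through-time
(including gradients with respect to the *inputs*, needed for Integrated
Gradients) and an Adam optimizer are written out explicitly; gradient
correctness is pinned down by finite-difference tests.

All arrays are float64 and all randomness flows through a caller-supplied
``numpy`` Generator, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

HEADS = ("mort", "los", "rrt", "mv")
BINARY_HEADS = ("mort", "rrt", "mv")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise numerically stable binary cross-entropy."""
    return np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))


class MultiTaskLSTM:
    """LSTM encoder with four prediction heads; plain-NumPy parameters."""

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int = 64,
        encoding_dim: int = 16,
        head_hidden: int = 16,
        rng: np.random.Generator | None = None,
    ):
        if encoding_dim >= input_dim:
            raise ValueError(
                f"encoding_dim ({encoding_dim}) must be smaller than "
                f"input_dim ({input_dim})"
            )
        rng = rng or np.random.default_rng(0)
        self.D, self.H, self.E = input_dim, hidden_dim, encoding_dim
        self.head_hidden = head_hidden
        k = 1.0 / np.sqrt(hidden_dim)

        def u(*shape):
            return rng.uniform(-k, k, shape)

        ki = 1.0 / np.sqrt(input_dim)
        self.params: dict[str, np.ndarray] = {
            "W": u(input_dim + hidden_dim, 4 * hidden_dim),
            "b": u(4 * hidden_dim),
            "We": u(hidden_dim, encoding_dim),
            # skip connection: the current window feeds the encoding directly,
            # so encodings react within the window while the LSTM adds context
            "Wxe": rng.uniform(-ki, ki, (input_dim, encoding_dim)),
            "be": u(encoding_dim),
        }
        self.params["b"][hidden_dim : 2 * hidden_dim] += 1.0  # forget-gate bias
        ke = 1.0 / np.sqrt(encoding_dim)
        kh = 1.0 / np.sqrt(head_hidden)
        for h in HEADS:
            self.params[f"{h}_W1"] = rng.uniform(-ke, ke, (encoding_dim, head_hidden))
            self.params[f"{h}_b1"] = rng.uniform(-ke, ke, head_hidden)
            self.params[f"{h}_W2"] = rng.uniform(-kh, kh, (head_hidden, 1))
            self.params[f"{h}_b2"] = rng.uniform(-kh, kh, 1)

    # ------------------------------------------------------------------ fwd

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        """Unroll over time. X: (B, T, D). Returns encodings (B, T, E) and a
        cache for the backward pass. Padding windows are simply computed and
        later masked out of every loss."""
        B, T, D = X.shape
        assert D == self.D, f"feature dimension mismatch: got {D}, expected {self.D}"
        H = self.H
        p = self.params
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates, cs, hs, tanhcs = [], [], [], []
        for t in range(T):
            z = np.hstack([X[:, t, :], h]) @ p["W"] + p["b"]
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            gates.append((i, f, g, o, c_prev))
            cs.append(c)
            hs.append(h)
            tanhcs.append(tc)
        Hseq = np.stack(hs, axis=1)  # (B, T, H)
        enc = Hseq @ p["We"] + X @ p["Wxe"] + p["be"]
        cache = {"X": X, "gates": gates, "tanhcs": tanhcs, "Hseq": Hseq}
        return enc, cache

    def head_forward(self, enc: np.ndarray) -> tuple[dict[str, np.ndarray], dict]:
        """Per-window head outputs (logits for binary tasks, linear for LOS)."""
        p = self.params
        outs, hcache = {}, {}
        for hname in HEADS:
            a = enc @ p[f"{hname}_W1"] + p[f"{hname}_b1"]
            r = np.maximum(a, 0.0)
            out = (r @ p[f"{hname}_W2"] + p[f"{hname}_b2"])[..., 0]
            outs[hname] = out
            hcache[hname] = (a, r)
        return outs, hcache

    # ------------------------------------------------------------------ bwd

    def head_backward(
        self, enc: np.ndarray, hcache: dict, d_outs: dict[str, np.ndarray], grads: dict
    ) -> np.ndarray:
        """Backprop the heads; returns d(encodings)."""
        p = self.params
        dE = np.zeros_like(enc)
        for hname in HEADS:
            a, r = hcache[hname]
            dout = d_outs[hname][..., None]  # (B, T, 1)
            grads[f"{hname}_W2"] += np.einsum("btj,btk->jk", r, dout)
            grads[f"{hname}_b2"] += dout.sum(axis=(0, 1))
            dr = dout @ p[f"{hname}_W2"].T
            da = dr * (a > 0)
            grads[f"{hname}_W1"] += np.einsum("bte,btj->ej", enc, da)
            grads[f"{hname}_b1"] += da.sum(axis=(0, 1))
            dE += da @ p[f"{hname}_W1"].T
        return dE

    def backward(
        self, cache: dict, dE: np.ndarray, grads: dict | None = None
    ) -> np.ndarray:
        """BPTT from d(encodings). Returns d(inputs) of shape (B, T, D);
        parameter gradients are accumulated into ``grads`` when given."""
        p = self.params
        X, Hseq = cache["X"], cache["Hseq"]
        B, T, D = X.shape
        H = self.H
        track = grads is not None
        if track:
            grads["We"] += np.einsum("bth,bte->he", Hseq, dE)
            grads["Wxe"] += np.einsum("btd,bte->de", X, dE)
            grads["be"] += dE.sum(axis=(0, 1))
        dX = dE @ p["Wxe"].T
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        WeT = p["We"].T
        Wx = p["W"][:D, :]
        Wh = p["W"][D:, :]
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev = cache["gates"][t]
            tc = cache["tanhcs"][t]
            dh = dE[:, t, :] @ WeT + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.hstack(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            h_prev = Hseq[:, t - 1, :] if t > 0 else np.zeros((B, H))
            if track:
                grads["W"] += np.hstack([X[:, t, :], h_prev]).T @ dz
                grads["b"] += dz.sum(axis=0)
            dX[:, t, :] += dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dX

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def input_gradients(self, X: np.ndarray, dE: np.ndarray) -> np.ndarray:
        """d(seeded encoding scalar)/d(inputs); used by Integrated Gradients."""
        _, cache = self.forward(X)
        return self.backward(cache, dE, grads=None)

    def clone(self) -> "MultiTaskLSTM":
        other = object.__new__(MultiTaskLSTM)
        other.D, other.H, other.E = self.D, self.H, self.E
        other.head_hidden = self.head_hidden
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other


class Adam:
    """Adam with bias correction and decoupled (AdamW-style) weight decay."""

    def __init__(
        self,
        params: dict,
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * params[k]
            )


def masked_loss_and_head_grads(
    outs: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    window_mask: np.ndarray,
    weights: dict[str, float],
) -> tuple[float, dict[str, float], dict[str, np.ndarray]]:
    """Weighted multi-task loss over valid cells plus d(loss)/d(head output).

    ``labels['los']``/``labels['rrt']``/``labels['mv']`` are (B, T) with NaN
    at undefined cells; ``labels['mort']`` is (B,) and supervised at every
    valid window. Each component is averaged over its own valid cells.
    """
    comps: dict[str, float] = {}
    d_outs: dict[str, np.ndarray] = {}
    total = 0.0
    for h in HEADS:
        z = outs[h]
        if h == "mort":
            y = np.broadcast_to(labels["mort"][:, None], z.shape).astype(float)
            valid = window_mask > 0
        else:
            y = labels[h]
            valid = (window_mask > 0) & ~np.isnan(y)
            y = np.where(np.isnan(y), 0.0, y)
        n = int(valid.sum())
        if n == 0:
            if weights.get(h, 0.0) > 0:
                raise ValueError(f"task {h!r}: positive weight but no valid cells")
            comps[h] = np.nan
            d_outs[h] = np.zeros_like(z)
            continue
        if h == "los":
            err = z - y
            comp = float((err[valid] ** 2).mean())
            d = 2.0 * err / n
        else:
            comp = float(bce_with_logits(z, y)[valid].mean())
            d = (sigmoid(z) - y) / n
        d = np.where(valid, d, 0.0) * weights.get(h, 0.0)
        comps[h] = comp
        d_outs[h] = d
        total += weights.get(h, 0.0) * comp
    if not np.isfinite(total):
        raise FloatingPointError(f"non-finite training loss; components={comps}")
    return total, comps, d_outs
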