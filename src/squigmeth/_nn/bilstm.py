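"""Stacked bidirectional LSTM classifier with hand-written backprop.

The recurrent cell follows the standard formulation (gate order i, f, g, o)
with two bias vectors per direction (``b_ih`` and ``b_hh``), so parameter
counts match the conventional deep-learning-framework layout.  All 21
timestep outputs of the top layer are concatenated (21 x hidden x 2
directions) and fed through a dense layer to ``fc_dim`` and a final dense
layer to one logit; :meth:`predict_proba` applies the sigmoid.

Gradients are computed by explicit backpropagation through time; tests
check them against numerical differentiation.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(X, W_ih, W_hh, b_ih, b_hh):
    """One direction over (B, T, in) -> (B, T, H) with caches for backprop."""
    B, T, _ = X.shape
    H = W_hh.shape[0]
    pre_x = X @ W_ih + b_ih + b_hh  # input contribution, all timesteps at once
    h = np.zeros((B, H), dtype=X.dtype)
    c = np.zeros((B, H), dtype=X.dtype)
    Hs = np.empty((B, T, H), dtype=X.dtype)
    cache = []
    for t in range(T):
        gates = pre_x[:, t] + h @ W_hh
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H:2 * H])
        g = np.tanh(gates[:, 2 * H:3 * H])
        o = _sigmoid(gates[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        Hs[:, t] = h
        cache.append((h_prev, c_prev, i, f, g, o, tc))
    return Hs, cache


def _lstm_backward(dHs, X, W_ih, W_hh, cache):
    B, T, _ = X.shape
    H = W_hh.shape[0]
    dW_ih = np.zeros_like(W_ih)
    dW_hh = np.zeros_like(W_hh)
    dpre = np.empty((B, T, 4 * H), dtype=X.dtype)
    dh_next = np.zeros((B, H), dtype=X.dtype)
    dc_next = np.zeros((B, H), dtype=X.dtype)
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dgates = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dW_hh += h_prev.T @ dgates
        dh_next = dgates @ W_hh.T
        dpre[:, t] = dgates
    dW_ih = X.reshape(B * T, -1).T @ dpre.reshape(B * T, 4 * H)
    db = dpre.sum(axis=(0, 1))  # shared by b_ih and b_hh
    dX = dpre @ W_ih.T
    return dX, dW_ih, dW_hh, db


class BiLSTMClassifier:
    """Binary classifier over (batch, window, n_features) matrices."""

    PRUNABLE = "fc1_W"  #: name of the large dense layer subject to pruning

    def __init__(self, n_features=19, window=21, hidden=128, n_layers=2,
                 fc_dim=128, activation="relu", seed=0, dtype=np.float32):
        if activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.n_features = n_features
        self.window = window
        self.hidden = hidden
        self.n_layers = n_layers
        self.fc_dim = fc_dim
        self.activation = activation
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        k = 1.0 / np.sqrt(hidden)
        in_dim = n_features
        for layer in range(n_layers):
            for d in ("f", "b"):
                p = f"l{layer}{d}_"
                self.params[p + "W_ih"] = self._u(rng, k, (in_dim, 4 * hidden))
                self.params[p + "W_hh"] = self._u(rng, k, (hidden, 4 * hidden))
                self.params[p + "b_ih"] = self._u(rng, k, (4 * hidden,))
                self.params[p + "b_hh"] = self._u(rng, k, (4 * hidden,))
            in_dim = 2 * hidden
        flat = window * 2 * hidden
        kf = 1.0 / np.sqrt(flat)
        self.params["fc1_W"] = self._u(rng, kf, (flat, fc_dim))
        self.params["fc1_b"] = self._u(rng, kf, (fc_dim,))
        kf2 = 1.0 / np.sqrt(fc_dim)
        self.params["fc2_W"] = self._u(rng, kf2, (fc_dim, 1))
        self.params["fc2_b"] = self._u(rng, kf2, (1,))
        self.prune_mask: np.ndarray | None = None

    def _u(self, rng, k, shape):
        return rng.uniform(-k, k, size=shape).astype(self.dtype)

    # -- forward / backward -------------------------------------------------

    def _fc1_weight(self):
        W = self.params["fc1_W"]
        return W if self.prune_mask is None else W * self.prune_mask

    def forward(self, X):
        """Logits for a batch; returns (logits, cache)."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        caches = []
        inp = X
        for layer in range(self.n_layers):
            p_f, p_b = f"l{layer}f_", f"l{layer}b_"
            Hf, cf = _lstm_forward(inp, *(self.params[p_f + n] for n in
                                          ("W_ih", "W_hh", "b_ih", "b_hh")))
            rev = inp[:, ::-1]
            Hb, cb = _lstm_forward(rev, *(self.params[p_b + n] for n in
                                          ("W_ih", "W_hh", "b_ih", "b_hh")))
            out = np.concatenate([Hf, Hb[:, ::-1]], axis=2)
            caches.append((inp, rev, cf, cb))
            inp = out
        B = X.shape[0]
        flat = inp.reshape(B, -1)
        W1 = self._fc1_weight()
        a1 = flat @ W1 + self.params["fc1_b"]
        r = np.maximum(a1, 0.0) if self.activation == "relu" else a1
        z = (r @ self.params["fc2_W"] + self.params["fc2_b"])[:, 0]
        return z, (caches, flat, a1, r)

    def backward(self, dz, cache):
        """Gradients of all parameters given d(loss)/d(logits)."""
        caches, flat, a1, r = cache
        grads: dict[str, np.ndarray] = {}
        dz = dz[:, None].astype(self.dtype)
        grads["fc2_W"] = r.T @ dz
        grads["fc2_b"] = dz.sum(axis=0)
        dr = dz @ self.params["fc2_W"].T
        da1 = dr * (a1 > 0) if self.activation == "relu" else dr
        W1 = self._fc1_weight()
        grads["fc1_W"] = flat.T @ da1
        if self.prune_mask is not None:
            grads["fc1_W"] *= self.prune_mask
        grads["fc1_b"] = da1.sum(axis=0)
        dflat = da1 @ W1.T
        B = flat.shape[0]
        dout = dflat.reshape(B, self.window, 2 * self.hidden)
        for layer in range(self.n_layers - 1, -1, -1):
            inp, rev, cf, cb = caches[layer]
            p_f, p_b = f"l{layer}f_", f"l{layer}b_"
            dHf = dout[:, :, :self.hidden]
            dHb = dout[:, ::-1, self.hidden:]
            dXf, dWi, dWh, db = _lstm_backward(
                np.ascontiguousarray(dHf), inp,
                self.params[p_f + "W_ih"], self.params[p_f + "W_hh"], cf)
            grads[p_f + "W_ih"], grads[p_f + "W_hh"] = dWi, dWh
            grads[p_f + "b_ih"] = grads[p_f + "b_hh"] = db
            dXb, dWi, dWh, db = _lstm_backward(
                np.ascontiguousarray(dHb), rev,
                self.params[p_b + "W_ih"], self.params[p_b + "W_hh"], cb)
            grads[p_b + "W_ih"], grads[p_b + "W_hh"] = dWi, dWh
            grads[p_b + "b_ih"] = grads[p_b + "b_hh"] = db
            dout = dXf + dXb[:, ::-1]
        return grads

    def predict_proba(self, X):
        z, _ = self.forward(X)
        return _sigmoid(z.astype(np.float64))
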