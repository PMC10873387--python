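"""Transformer-encoder classifier (post-layer-norm) with manual backprop.

Per-row linear embedding of the 19 features to ``d_model``, fixed sinusoidal
positional encoding over the 21 window positions, a stack of standard
encoder layers (multi-head self-attention + position-wise feed-forward,
each with a residual connection followed by layer normalization), then the
same flatten -> dense -> dense -> sigmoid head as the BiLSTM.  The head's
large dense layer is the pruning target, mirroring the BiLSTM.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _sinusoidal_pe(T, d, dtype):
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(dtype)


def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _layernorm_backward(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    dxhat = dy * g
    d = xhat.shape[-1]
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


def _split_heads(x, n_heads):
    B, T, d = x.shape
    return x.reshape(B, T, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, h, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dh)


class TransformerClassifier:
    """Binary classifier over (batch, window, n_features) matrices."""

    PRUNABLE = "fc1_W"

    def __init__(self, n_features=19, window=21, d_model=64, n_layers=4,
                 n_heads=8, d_ff=256, fc_dim=128, activation="relu",
                 seed=0, dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.n_features = n_features
        self.window = window
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.fc_dim = fc_dim
        self.activation = activation
        self.dtype = np.dtype(dtype)
        self.pe = _sinusoidal_pe(window, d_model, self.dtype)
        rng = np.random.default_rng(seed)
        P: dict[str, np.ndarray] = {}

        def lin(name, fan_in, shape):
            k = 1.0 / np.sqrt(fan_in)
            P[name + "_W"] = rng.uniform(-k, k, shape).astype(self.dtype)
            P[name + "_b"] = rng.uniform(-k, k, shape[-1:]).astype(self.dtype)

        lin("emb", n_features, (n_features, d_model))
        for l in range(n_layers):
            for nm in ("q", "k", "v", "o"):
                lin(f"l{l}_{nm}", d_model, (d_model, d_model))
            lin(f"l{l}_ff1", d_model, (d_model, d_ff))
            lin(f"l{l}_ff2", d_ff, (d_ff, d_model))
            for ln in ("ln1", "ln2"):
                P[f"l{l}_{ln}_g"] = np.ones(d_model, dtype=self.dtype)
                P[f"l{l}_{ln}_b"] = np.zeros(d_model, dtype=self.dtype)
        lin("fc1", window * d_model, (window * d_model, fc_dim))
        lin("fc2", fc_dim, (fc_dim, 1))
        self.params = P
        self.prune_mask: np.ndarray | None = None

    def _fc1_weight(self):
        W = self.params["fc1_W"]
        return W if self.prune_mask is None else W * self.prune_mask

    def forward(self, X):
        P = self.params
        X = np.ascontiguousarray(X, dtype=self.dtype)
        x = X @ P["emb_W"] + P["emb_b"] + self.pe
        caches = []
        dh = self.d_model // self.n_heads
        scale = 1.0 / np.sqrt(dh)
        for l in range(self.n_layers):
            q = _split_heads(x @ P[f"l{l}_q_W"] + P[f"l{l}_q_b"], self.n_heads)
            k = _split_heads(x @ P[f"l{l}_k_W"] + P[f"l{l}_k_b"], self.n_heads)
            v = _split_heads(x @ P[f"l{l}_v_W"] + P[f"l{l}_v_b"], self.n_heads)
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale
            scores -= scores.max(axis=-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(axis=-1, keepdims=True)
            ctx = _merge_heads(att @ v)
            mha = ctx @ P[f"l{l}_o_W"] + P[f"l{l}_o_b"]
            y1, ln1c = _layernorm_forward(x + mha, P[f"l{l}_ln1_g"], P[f"l{l}_ln1_b"])
            a = y1 @ P[f"l{l}_ff1_W"] + P[f"l{l}_ff1_b"]
            h = np.maximum(a, 0.0)
            ff = h @ P[f"l{l}_ff2_W"] + P[f"l{l}_ff2_b"]
            y2, ln2c = _layernorm_forward(y1 + ff, P[f"l{l}_ln2_g"], P[f"l{l}_ln2_b"])
            caches.append((x, q, k, v, att, ctx, ln1c, y1, a, h, ln2c))
            x = y2
        B = X.shape[0]
        flat = x.reshape(B, -1)
        W1 = self._fc1_weight()
        a1 = flat @ W1 + P["fc1_b"]
        r = np.maximum(a1, 0.0) if self.activation == "relu" else a1
        z = (r @ P["fc2_W"] + P["fc2_b"])[:, 0]
        return z, (X, caches, flat, a1, r)

    def backward(self, dz, cache):
        P = self.params
        X, caches, flat, a1, r = cache
        G: dict[str, np.ndarray] = {}
        dz = dz[:, None].astype(self.dtype)
        G["fc2_W"] = r.T @ dz
        G["fc2_b"] = dz.sum(axis=0)
        dr = dz @ P["fc2_W"].T
        da1 = dr * (a1 > 0) if self.activation == "relu" else dr
        G["fc1_W"] = flat.T @ da1
        if self.prune_mask is not None:
            G["fc1_W"] *= self.prune_mask
        G["fc1_b"] = da1.sum(axis=0)
        dx = (da1 @ self._fc1_weight().T).reshape(X.shape[0], self.window, self.d_model)
        dh_ = self.d_model // self.n_heads
        scale = 1.0 / np.sqrt(dh_)
        for l in range(self.n_layers - 1, -1, -1):
            x, q, k, v, att, ctx, ln1c, y1, a, h, ln2c = caches[l]
            dy2 = dx
            dres2, G[f"l{l}_ln2_g"], G[f"l{l}_ln2_b"] = _layernorm_backward(
                dy2, P[f"l{l}_ln2_g"], ln2c)
            dff = dres2
            BT = dff.shape[0] * dff.shape[1]
            G[f"l{l}_ff2_W"] = h.reshape(BT, -1).T @ dff.reshape(BT, -1)
            G[f"l{l}_ff2_b"] = dff.sum(axis=(0, 1))
            dh2 = (dff @ P[f"l{l}_ff2_W"].T) * (a > 0)
            G[f"l{l}_ff1_W"] = y1.reshape(BT, -1).T @ dh2.reshape(BT, -1)
            G[f"l{l}_ff1_b"] = dh2.sum(axis=(0, 1))
            dy1 = dres2 + dh2 @ P[f"l{l}_ff1_W"].T
            dres1, G[f"l{l}_ln1_g"], G[f"l{l}_ln1_b"] = _layernorm_backward(
                dy1, P[f"l{l}_ln1_g"], ln1c)
            dmha = dres1
            G[f"l{l}_o_W"] = ctx.reshape(BT, -1).T @ dmha.reshape(BT, -1)
            G[f"l{l}_o_b"] = dmha.sum(axis=(0, 1))
            dctx = _split_heads(dmha @ P[f"l{l}_o_W"].T, self.n_heads)
            datt = dctx @ v.transpose(0, 1, 3, 2)
            dv = att.transpose(0, 1, 3, 2) @ dctx
            dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
            dq = (dscores @ k) * scale
            dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale
            dx_attn = dres1.copy()
            for nm, dproj in (("q", dq), ("k", dk), ("v", dv)):
                dflat_ = _merge_heads(dproj)
                G[f"l{l}_{nm}_W"] = x.reshape(BT, -1).T @ dflat_.reshape(BT, -1)
                G[f"l{l}_{nm}_b"] = dflat_.sum(axis=(0, 1))
                dx_attn += dflat_ @ P[f"l{l}_{nm}_W"].T
            dx = dx_attn
        BT = X.shape[0] * self.window
        G["emb_W"] = X.reshape(BT, -1).T @ dx.reshape(BT, -1)
        G["emb_b"] = dx.sum(axis=(0, 1))
        return G

    def predict_proba(self, X):
        z, _ = self.forward(X)
        return _sigmoid(z.astype(np.float64))
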