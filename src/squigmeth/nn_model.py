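"""Per-read methylation classifier: build, train, prune, predict, checkpoint.

The default architecture is a two-layer bidirectional LSTM of hidden size
128 over the 21x19 feature matrix, whose 21 concatenated timestep outputs
(21 x 128 x 2 = 5376 values) feed a dense layer to 128 and a final dense
layer to a single sigmoid probability.  With two bias vectors per recurrent
direction this totals 1,236,225 trainable parameters; magnitude pruning of
95% of the 5376x128 dense weight matrix leaves 582,503 nonzero parameters,
trading a negligible accuracy cost for a large CPU-inference speedup.

A Transformer-encoder variant (4 layers, 8 heads) is available through the
same interface.  Everything runs on plain numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._nn.bilstm import BiLSTMClassifier
from ._nn.transformer import TransformerClassifier
from ._nn.optim import Adam
from .features import COL_REF_ONEHOT, N_FEATURES, WINDOW

CHECKPOINT_VERSION = 1


class ModelConfigError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Architecture hyperparameters."""

    arch: str = "bilstm"
    window: int = WINDOW
    n_features: int = N_FEATURES
    lstm_hidden: int = 128
    lstm_layers: int = 2
    fc_dim: int = 128
    transformer_layers: int = 4
    transformer_heads: int = 8
    transformer_dmodel: int = 64
    transformer_dff: int = 256
    prune_fraction: float = 0.95
    activation: str = "relu"

    def __post_init__(self):
        if self.arch not in ("bilstm", "transformer"):
            raise ModelConfigError(f"unknown architecture {self.arch!r}")
        if self.window % 2 == 0 or self.window < 1:
            raise ModelConfigError("window must be odd and positive")
        if not (0.0 <= self.prune_fraction < 1.0):
            raise ModelConfigError("prune_fraction must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization settings: Adam at 5e-5 with L2 coefficient 1e-5,
    binary cross-entropy, at most ``max_epochs`` epochs with early stopping
    on validation accuracy."""

    learning_rate: float = 5e-5
    l2_coefficient: float = 1e-5
    max_epochs: int = 10
    batch_size: int = 64
    dual_view: bool = True
    val_fraction: float = 0.1
    # validation accuracy on a desk-scale split is noisy (SE ~0.5%), so a
    # few flat epochs are tolerated before stopping
    patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ModelConfigError("learning_rate must be positive")


@dataclass
class TrainingLabelRule:
    """Site-level ground-truth labeling for training matrices: a site is a
    positive example source iff every ground-truth replicate shows >= 90%
    methylation at >= 10x coverage, negative iff every replicate shows
    < 10%; anything else is excluded."""

    min_coverage: int = 10
    positive_threshold: float = 0.90
    negative_threshold: float = 0.10

    def __post_init__(self):
        if not self.negative_threshold < self.positive_threshold:
            raise ModelConfigError("negative threshold must be below positive")

    def label(self, coverages, frequencies) -> Optional[int]:
        cov = np.asarray(coverages, dtype=float)
        freq = np.asarray(frequencies, dtype=float)
        if (cov < self.min_coverage).any():
            return None
        if (freq >= self.positive_threshold).all():
            return 1
        if (freq < self.negative_threshold).all():
            return 0
        return None


def build_model(spec: ModelSpec, seed: int = 0):
    if spec.arch == "bilstm":
        return BiLSTMClassifier(n_features=spec.n_features, window=spec.window,
                                hidden=spec.lstm_hidden, n_layers=spec.lstm_layers,
                                fc_dim=spec.fc_dim, activation=spec.activation,
                                seed=seed)
    return TransformerClassifier(n_features=spec.n_features, window=spec.window,
                                 d_model=spec.transformer_dmodel,
                                 n_layers=spec.transformer_layers,
                                 n_heads=spec.transformer_heads,
                                 d_ff=spec.transformer_dff, fc_dim=spec.fc_dim,
                                 activation=spec.activation, seed=seed)


def param_count(model, nonzero_only: bool = False) -> int:
    """Total (or nonzero) scalar trainable parameters of the model."""
    if nonzero_only:
        total = 0
        for name, w in model.params.items():
            if name == model.PRUNABLE and model.prune_mask is not None:
                total += int(np.count_nonzero(w * model.prune_mask))
            else:
                total += int(np.count_nonzero(w))
        return total
    return sum(int(w.size) for w in model.params.values())


def prune_model(model, fraction: float = 0.95):
    """Zero the ``round(fraction * n)`` smallest-magnitude entries of the
    large dense layer's weight matrix, permanently (masked for inference and
    any further training).  Biases and all other layers are untouched."""
    if not (0.0 <= fraction < 1.0):
        raise ModelConfigError(f"prune fraction must be in [0, 1), got {fraction}")
    W = model.params[model.PRUNABLE]
    n_remove = int(round(fraction * W.size))
    mask = np.ones(W.size, dtype=model.dtype)
    if n_remove:
        order = np.argsort(np.abs(W.ravel()), kind="stable")
        mask[order[:n_remove]] = 0.0
    model.prune_mask = mask.reshape(W.shape)
    return model


def dual_view_matrices(X: np.ndarray) -> np.ndarray:
    """The reference-free twin of a batch: reference one-hot forced to N."""
    X2 = np.array(X, copy=True)
    X2[..., COL_REF_ONEHOT] = 0.0
    X2[..., COL_REF_ONEHOT.stop - 1] = 1.0
    return X2


def _bce_loss_and_grad(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy from logits, and d(loss)/d(logits)."""
    z = z.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    return loss, ((p - y) / z.size)


def predict(model, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Methylation probabilities in [0, 1], one per matrix, batch-order
    invariant."""
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != (model.window, model.n_features):
        raise ValueError(f"expected (*, {model.window}, {model.n_features}) "
                         f"matrices, got {X.shape}")
    out = np.empty(X.shape[0], dtype=np.float64)
    for lo in range(0, X.shape[0], batch_size):
        out[lo:lo + batch_size] = model.predict_proba(X[lo:lo + batch_size])
    return out


def train(model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[dict]:
    """Fit the classifier; returns per-epoch history.

    Matrices are split into train/validation by a seeded shuffle; when
    ``dual_view`` is set each training matrix is also used with its
    reference features replaced by N, teaching the model to work on
    unmapped reads.  Training stops when validation accuracy has not
    improved for ``patience`` epochs (or at ``max_epochs``), and the best
    epoch's weights are restored.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class; refusing to train")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(cfg.val_fraction * X.shape[0])))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_val, y_val = X[val_idx], y[val_idx]
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    if cfg.dual_view:
        X_tr = np.concatenate([X_tr, dual_view_matrices(X_tr)], axis=0)
        y_tr = np.concatenate([y_tr, y_tr])

    opt = Adam(model.params, lr=cfg.learning_rate, l2=cfg.l2_coefficient)
    history: list[dict] = []
    best_acc, best_params, since_best = -1.0, None, 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(X_tr.shape[0])
        losses = []
        for lo in range(0, order.size, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            z, cache = model.forward(X_tr[idx])
            loss, dz = _bce_loss_and_grad(z, y_tr[idx])
            grads = model.backward(dz, cache)
            opt.step(grads)
            losses.append(loss)
        val_prob = predict(model, X_val)
        val_acc = float(np.mean((val_prob >= 0.5) == (y_val == 1)))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = {k: v.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    if best_params is not None:
        for k in model.params:
            model.params[k][...] = best_params[k]
    return history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, spec: ModelSpec, path: str | Path) -> None:
    """Versioned container: architecture spec + weights + pruning mask."""
    meta = {"version": CHECKPOINT_VERSION, "spec": asdict(spec)}
    arrays = {f"param/{k}": v for k, v in model.params.items()}
    if model.prune_mask is not None:
        arrays["prune_mask"] = model.prune_mask
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path: str | Path):
    """Returns ``(model, spec)`` rebuilt from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ModelConfigError(f"unsupported checkpoint version: {meta.get('version')}")
        spec = ModelSpec(**meta["spec"])
        model = build_model(spec)
        for k in model.params:
            model.params[k] = data[f"param/{k}"]
        if "prune_mask" in data:
            model.prune_mask = data["prune_mask"]
    return model, spec
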