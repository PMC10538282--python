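"""The methylation classifier: dilated convolutions + Transformer encoder.

Architecture (per forward pass on a batch B x L x d of encoded fragments):

1. three parallel 1D convolutions along the token axis with dilation rates
   1, 2 and 3 (same-length padding, ReLU), capturing local context at
   three receptive-field scales;
2. channel concatenation to width ``3 * conv_filters``;
3. additive fixed sinusoidal positional encoding — token order matters for
   DNA, and self-attention alone is permutation-equivariant;
4. ``n_encoder_layers`` Transformer encoder blocks (multi-head
   self-attention -> Add & Norm -> position-wise feed-forward -> Add & Norm);
5. mean pooling over positions (or flattening);
6. a dense head 128 -> 64 -> 32 with dropout after each layer, ending in a
   2-unit softmax.

Training minimises categorical cross-entropy with Adam, early-stops on
validation loss, and is bit-reproducible for a fixed seed (pure NumPy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from ._nn import (
    Adam,
    Conv1dDilated,
    Dense,
    Dropout,
    ReLU,
    TransformerEncoderLayer,
    sinusoidal_positional_encoding,
    softmax_cross_entropy,
)
from .errors import ValidationError


@dataclass
class ModelConfig:
    input_len: int = 39
    input_dim: int = 300
    conv_filters: int = 64
    kernel_size: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    n_heads: int = 4
    n_encoder_layers: int = 1
    ffn_dim: Optional[int] = None  # default 4x the post-concat width
    fc_dims: tuple[int, ...] = (128, 64, 32)
    dropout_rate: float = 0.2
    pooling: str = "mean"
    positional_encoding: bool = True
    normalize_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pooling not in ("mean", "flatten"):
            raise ValidationError(f"pooling must be 'mean' or 'flatten', got {self.pooling!r}")
        width = len(self.dilation_rates) * self.conv_filters
        if width % self.n_heads:
            raise ValidationError(
                f"model width {width} (= {len(self.dilation_rates)} branches x "
                f"{self.conv_filters} filters) must be divisible by n_heads = {self.n_heads}"
            )
        if self.ffn_dim is None:
            self.ffn_dim = 4 * width

    @property
    def width(self) -> int:
        return len(self.dilation_rates) * self.conv_filters


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 30
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    class_weighting: str = "off"  # "off" | "balanced"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError(f"threshold must be inside (0, 1), got {self.threshold}")
        if self.class_weighting not in ("off", "balanced"):
            raise ValidationError("class_weighting must be 'off' or 'balanced'")


class MethylationClassifier:
    """Forward/backward network over encoded fragment batches."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.convs = [
            Conv1dDilated(c.input_dim, c.conv_filters, c.kernel_size, r, rng)
            for r in c.dilation_rates
        ]
        self.conv_act = [ReLU() for _ in c.dilation_rates]
        self.pe = (
            sinusoidal_positional_encoding(c.input_len, c.width)
            if c.positional_encoding
            else None
        )
        self.encoder = [
            TransformerEncoderLayer(c.width, c.n_heads, c.ffn_dim, c.dropout_rate, rng)
            for _ in range(c.n_encoder_layers)
        ]
        # per-channel input standardisation statistics; set by train()
        self.input_mean: Optional[np.ndarray] = None
        self.input_std: Optional[np.ndarray] = None
        head_in = c.width if c.pooling == "mean" else c.width * c.input_len
        self.head: list = []
        d_prev = head_in
        for d_fc in c.fc_dims:
            self.head += [Dense(d_prev, d_fc, rng), ReLU(), Dropout(c.dropout_rate, rng)]
            d_prev = d_fc
        self.out = Dense(d_prev, 2, rng)

    # -- plumbing ---------------------------------------------------------

    def layers(self):
        out = list(self.convs) + list(self.conv_act)
        for enc in self.encoder:
            out += enc.sublayers() + [enc]
        out += self.head + [self.out]
        return out

    def param_layers(self):
        seen, out = set(), []
        for layer in self.layers():
            if layer.params and id(layer) not in seen:
                seen.add(id(layer))
                out.append(layer)
        return out

    def n_parameters(self) -> int:
        return sum(v.size for l in self.param_layers() for v in l.params.values())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (B, 2) from encoded fragments (B, L, d)."""
        if x.ndim != 3 or x.shape[1:] != (self.config.input_len, self.config.input_dim):
            raise ValidationError(
                f"expected input (B, {self.config.input_len}, "
                f"{self.config.input_dim}), got {x.shape}"
            )
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_std
        h = np.concatenate(
            [act.forward(conv.forward(x, train), train)
             for conv, act in zip(self.convs, self.conv_act)],
            axis=-1,
        )
        if self.pe is not None:
            h = h + self.pe[None]
        for enc in self.encoder:
            h = enc.forward(h, train)
        if self.config.pooling == "mean":
            z = h.mean(axis=1)
        else:
            z = h.reshape(h.shape[0], -1)
        self._h_shape = h.shape
        for layer in self.head:
            z = layer.forward(z, train)
        return self.out.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.out.backward(dlogits)
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        B, L, D = self._h_shape
        if self.config.pooling == "mean":
            dh = np.repeat(dz[:, None, :], L, axis=1) / L
        else:
            dh = dz.reshape(B, L, D)
        for enc in reversed(self.encoder):
            dh = enc.backward(dh)
        F = self.config.conv_filters
        for b, (conv, act) in enumerate(zip(self.convs, self.conv_act)):
            conv.backward(act.backward(dh[:, :, b * F : (b + 1) * F]))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probability per sample, in [0, 1]."""
        probs = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            z = logits - logits.max(axis=-1, keepdims=True)
            e = np.exp(z)
            probs.append((e / e.sum(axis=-1, keepdims=True))[:, 1])
        return np.concatenate(probs) if probs else np.zeros(0)

    # -- persistence ------------------------------------------------------

    def save(self, path_prefix: str | Path) -> None:
        """Weights to ``<prefix>.npz`` with a JSON config sidecar."""
        prefix = Path(path_prefix)
        arrays = {}
        for li, layer in enumerate(self.param_layers()):
            for k, v in layer.params.items():
                arrays[f"{li}:{k}"] = v
        if self.input_mean is not None:
            arrays["input_mean"] = self.input_mean
            arrays["input_std"] = self.input_std
        np.savez(str(prefix) + ".npz", **arrays)
        cfg = asdict(self.config)
        cfg["dilation_rates"] = list(cfg["dilation_rates"])
        cfg["fc_dims"] = list(cfg["fc_dims"])
        Path(str(prefix) + ".json").write_text(json.dumps(cfg), encoding="utf-8")

    @classmethod
    def load(cls, path_prefix: str | Path) -> "MethylationClassifier":
        prefix = Path(path_prefix)
        cfg = json.loads(Path(str(prefix) + ".json").read_text(encoding="utf-8"))
        cfg["dilation_rates"] = tuple(cfg["dilation_rates"])
        cfg["fc_dims"] = tuple(cfg["fc_dims"])
        model = cls(ModelConfig(**cfg))
        with np.load(str(prefix) + ".npz") as data:
            for li, layer in enumerate(model.param_layers()):
                for k in layer.params:
                    layer.params[k] = data[f"{li}:{k}"].astype(np.float64)
            if "input_mean" in data:
                model.input_mean = data["input_mean"].astype(np.float64)
                model.input_std = data["input_std"].astype(np.float64)
        return model


def build_model(config: ModelConfig) -> MethylationClassifier:
    return MethylationClassifier(config)


def _sample_weights(y: np.ndarray, mode: str) -> Optional[np.ndarray]:
    if mode == "off":
        return None
    counts = np.bincount(y, minlength=2)
    return (y.size / (2.0 * counts))[y]


def train(
    model: MethylationClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[MethylationClassifier, dict]:
    """Fit with Adam on categorical cross-entropy; early-stop on val loss.

    ``train_set`` / ``val_set`` are ``(X, y)`` with X of shape (n, L, d) and
    integer labels.  Returns the model (weights restored to the best
    validation epoch) and a history dict with per-epoch train/val loss and
    accuracy.  Raises on a single-class training set or a non-finite loss.
    """
    X, y = train_set
    Xv, yv = val_set
    if X.shape[0] == 0 or Xv.shape[0] == 0:
        raise ValidationError("training and validation sets must be nonempty")
    y = np.asarray(y, dtype=np.int64)
    yv = np.asarray(yv, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")

    if model.config.normalize_input and model.input_mean is None:
        # per-channel standardisation from the training fold only
        model.input_mean = X.mean(axis=(0, 1))
        model.input_std = X.std(axis=(0, 1)) + 1e-8

    rng = np.random.default_rng(config.seed)
    weights = _sample_weights(y, config.class_weighting)
    optimizer = Adam(model.param_layers(), lr=config.learning_rate)
    history: dict = {"epoch": [], "train_loss": [], "val_loss": [],
                     "train_acc": [], "val_acc": []}
    best_val = np.inf
    best_params = None
    patience_left = config.early_stop_patience

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(X.shape[0])
        epoch_loss, n_correct = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            optimizer.zero_grad()
            logits = model.forward(X[idx], train=True)
            w = None if weights is None else weights[idx]
            loss, dlogits, probs = softmax_cross_entropy(logits, y[idx], w)
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * idx.size
            n_correct += int((probs.argmax(axis=1) == y[idx]).sum())

        val_probs = model.predict_proba(Xv)
        val_loss = _binary_ce(yv, val_probs)
        if not np.isfinite(val_loss):
            raise ValidationError(f"non-finite validation loss at epoch {epoch}")
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / X.shape[0])
        history["val_loss"].append(val_loss)
        history["train_acc"].append(n_correct / X.shape[0])
        history["val_acc"].append(
            float(((val_probs >= config.threshold).astype(int) == yv).mean())
        )

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [
                {k: v.copy() for k, v in l.params.items()}
                for l in model.param_layers()
            ]
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_params is not None:
        for layer, saved in zip(model.param_layers(), best_params):
            for k in layer.params:
                layer.params[k] = saved[k]
    return model, history


def _binary_ce(y: np.ndarray, p_pos: np.ndarray) -> float:
    p = np.clip(np.where(y == 1, p_pos, 1.0 - p_pos), 1e-12, None)
    return float(-np.mean(np.log(p)))


def predict(
    model: MethylationClassifier,
    samples: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, calls); call = 1 iff prob >= threshold (ties -> 1)."""
    probs = model.predict_proba(samples)
    return probs, (probs >= threshold).astype(np.int64)


def save_history(history: dict, path: str | Path) -> None:
    """Training curves as CSV (epoch, train_loss, val_loss, train_acc, val_acc)."""
    import csv

    cols = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for row in zip(*(history[c] for c in cols)):
            writer.writerow(row)
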