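"""Minimal NumPy neural-network layers with explicit backpropagation.

Each layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``; parameter
gradients accumulate in ``grads`` (zeroed by the optimizer step).  All
arithmetic is float64, which keeps finite-difference gradient checks tight.

Shapes follow the (batch, positions, channels) convention.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis; He-initialised."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv1dDilated(Layer):
    """1D convolution along the position axis with same-length padding.

    Weight shape (k, c_in, c_out); effective receptive field spans
    ``(k-1)*dilation + 1`` positions.  ``k`` must be odd so 'same' padding
    is symmetric.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.k = kernel_size
        self.dilation = dilation
        fan_in = kernel_size * c_in
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel_size, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.pad = dilation * (kernel_size // 2)

    def forward(self, x, train=False):
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        self._xp, self._L = xp, L
        y = np.broadcast_to(self.params["b"], (B, L, self.params["b"].size)).copy()
        for j in range(self.k):
            sl = slice(j * self.dilation, j * self.dilation + L)
            y += xp[:, sl, :] @ self.params["W"][j]
        return y

    def backward(self, dy):
        L = self._L
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            sl = slice(j * self.dilation, j * self.dilation + L)
            self.grads["W"][j] += np.einsum("blc,bld->cd", self._xp[:, sl, :], dy)
            dxp[:, sl, :] += dy @ self.params["W"][j].T
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dxp[:, self.pad : self.pad + L, :]


class LayerNorm(Layer):
    """Normalisation over the channel axis with learned gain and bias."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(d), "beta": np.zeros(d)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        return (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv


def _softmax_last(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.h = n_heads
        self.dh = d_model // n_heads
        scale = np.sqrt(1.0 / d_model)
        self.params = {
            name: rng.normal(0.0, scale, size=(d_model, d_model))
            for name in ("Wq", "Wk", "Wv", "Wo")
        }
        for name in ("bq", "bk", "bv", "bo"):
            self.params[name] = np.zeros(d_model)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _split(self, x):
        B, L, D = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)

    def forward(self, x, train=False):
        p = self.params
        self._x = x
        self._Q = self._split(x @ p["Wq"] + p["bq"])
        self._K = self._split(x @ p["Wk"] + p["bk"])
        self._V = self._split(x @ p["Wv"] + p["bv"])
        scores = self._Q @ self._K.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        self._A = _softmax_last(scores)               # (B, h, L, L)
        self._O = self._merge(self._A @ self._V)      # (B, L, D)
        return self._O @ p["Wo"] + p["bo"]

    def backward(self, dy):
        p = self.params
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])

        self.grads["Wo"] += self._O.reshape(-1, dy.shape[-1]).T @ dy2
        self.grads["bo"] += dy2.sum(axis=0)
        dO = self._split(dy @ p["Wo"].T)              # (B, h, L, dh)

        dA = dO @ self._V.transpose(0, 1, 3, 2)       # (B, h, L, L)
        dV = self._A.transpose(0, 1, 3, 2) @ dO
        dS = self._A * (dA - (dA * self._A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.dh)
        dQ = dS @ self._K
        dK = dS.transpose(0, 1, 3, 2) @ self._Q

        dx = np.zeros_like(x)
        for name, dproj in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            d2 = self._merge(dproj).reshape(-1, dy.shape[-1])
            self.grads[name] += x2.T @ d2
            self.grads["b" + name[1]] += d2.sum(axis=0)
            dx += d2.reshape(x.shape) @ p[name].T
        return dx


class TransformerEncoderLayer(Layer):
    """MHA -> Add & Norm -> position-wise feed-forward -> Add & Norm."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn1 = Dense(d_model, ffn_dim, rng)
        self.ffn_act = ReLU()
        self.ffn2 = Dense(ffn_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def sublayers(self):
        return [self.mha, self.norm1, self.ffn1, self.ffn2, self.norm2]

    def forward(self, x, train=False):
        h = self.norm1.forward(x + self.drop1.forward(self.mha.forward(x, train), train))
        f = self.ffn2.forward(self.ffn_act.forward(self.ffn1.forward(h)))
        return self.norm2.forward(h + self.drop2.forward(f, train))

    def backward(self, dy):
        dh_plus = self.norm2.backward(dy)
        df = self.drop2.backward(dh_plus)
        dh = dh_plus + self.ffn1.backward(
            self.ffn_act.backward(self.ffn2.backward(df))
        )
        dx_plus = self.norm1.backward(dh)
        da = self.drop1.backward(dx_plus)
        return dx_plus + self.mha.backward(da)


def sinusoidal_positional_encoding(length: int, d_model: int) -> np.ndarray:
    """The fixed sin/cos position table, shape (length, d_model)."""
    pe = np.zeros((length, d_model))
    pos = np.arange(length)[:, None]
    i = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, i / d_model)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d_model // 2])
    return pe


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Categorical cross-entropy on integer labels.

    Returns (loss, dlogits, probs); the loss is the weighted mean and
    dlogits is its exact gradient.
    """
    probs = _softmax_last(logits)
    n = logits.shape[0]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    logp = np.log(np.clip(probs[np.arange(n), y], 1e-300, None))
    loss = float(-(w * logp).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits, probs


class Adam:
    """Adam over a list of layers' parameter dicts."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for k, g in layer.grads.items():
                m = self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                v = self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer in self.layers:
            for k in layer.grads:
                layer.grads[k][...] = 0.0
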