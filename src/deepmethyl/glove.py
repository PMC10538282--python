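"""Global-vector (GloVe) embeddings over the k-mer vocabulary.

The embedding is fit in two stages.  First a global co-occurrence matrix X is
accumulated: X[i, j] counts how often token j appears within the context
window after token i, mirrored so that X is symmetric.  Then per-token
vectors are found by minimising the weighted least-squares energy

    J = sum_{i,j : X_ij > 0} f(X_ij) * (V_i . Vt_j + b_i + bt_j - log X_ij)^2

where f is a truncated power weighting, f(x) = (x / T_X)^alpha for
x < T_X and 1 otherwise, with alpha = 0.75.  The sum is restricted to
nonzero counts (f(0) = 0 and log 0 is undefined), the standard GloVe
convention.  Optimisation is per-pair stochastic gradient descent with
AdaGrad per-parameter step sizes, seeded and fully reproducible.

The exported per-token vector is the main vector V_i by default; the
context vector Vt_j exists only to help solve for V_i, though the common
V + Vt variant is available via :class:`GloveConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ParseError, ValidationError
from .kmer import KmerVocabulary, TokenizedCorpus


@dataclass
class CooccurrenceMatrix:
    """Symmetric nonnegative co-occurrence counts over a vocabulary."""

    X: np.ndarray
    vocab: KmerVocabulary
    window: int

    def __post_init__(self) -> None:
        n = len(self.vocab)
        if self.X.shape != (n, n):
            raise ValidationError(
                f"co-occurrence matrix shape {self.X.shape} != ({n}, {n})"
            )
        if (self.X < 0).any():
            raise ValidationError("co-occurrence counts must be nonnegative")
        if not np.allclose(self.X, self.X.T):
            raise ValidationError("co-occurrence matrix must be symmetric")

    def count(self, token_i: str, token_j: str) -> float:
        return float(self.X[self.vocab.index[token_i], self.vocab.index[token_j]])


def build_cooccurrence(
    corpus: TokenizedCorpus,
    window: int = 1,
    distance_weighting: bool = False,
) -> CooccurrenceMatrix:
    """Accumulate the global co-occurrence matrix from a tokenized corpus.

    For every ordered pair (token at position p, token at position p+s) with
    1 <= s <= ``window`` inside one document, the directed count is
    incremented (by 1/s when ``distance_weighting`` is on).  The matrix is
    then symmetrised by mirroring: X = D + D.T where D holds the directed
    counts, so X[i, j] is the forward count of i->j plus that of j->i.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if not corpus.documents:
        raise ValidationError("cannot build co-occurrence from an empty corpus")
    n = len(corpus.vocab)
    directed = np.zeros((n, n), dtype=np.float64)
    for doc in corpus.documents:
        for s in range(1, window + 1):
            if s >= len(doc):
                break
            w = 1.0 / s if distance_weighting else 1.0
            np.add.at(directed, (doc[:-s], doc[s:]), w)
    return CooccurrenceMatrix(X=directed + directed.T, vocab=corpus.vocab, window=window)


def glove_weight(x, T_X: float = 100.0, alpha: float = 0.75):
    """Truncated power weighting f(x): (x/T_X)^alpha below T_X, else 1.

    Accepts scalars or arrays; raises on negative input.  f is
    non-decreasing and continuous, with f(0) = 0 and f(x >= T_X) = 1.
    """
    arr = np.asarray(x, dtype=np.float64)
    if (arr < 0).any():
        raise ValidationError("co-occurrence counts must be nonnegative")
    out = np.where(arr < T_X, (arr / T_X) ** alpha, 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class GloveConfig:
    """Hyperparameters for the embedding fit.

    d : embedding length (300 at full scale).
    T_X, alpha : weighting truncation and exponent; alpha is fixed at the
        empirical 0.75, T_X defaults to the conventional 100.
    lr, epochs : AdaGrad initial step size and pass count over the pairs.
    export : "main" exports V_i; "sum" exports V_i + Vt_i.
    """

    d: int = 300
    T_X: float = 100.0
    alpha: float = 0.75
    lr: float = 0.05
    epochs: int = 50
    seed: int = 0
    export: str = "main"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.T_X <= 0:
            raise ValidationError(f"T_X must be > 0, got {self.T_X}")
        if self.d < 1:
            raise ValidationError(f"d must be >= 1, got {self.d}")
        if self.export not in ("main", "sum"):
            raise ValidationError(f"export must be 'main' or 'sum', got {self.export!r}")


@dataclass
class GloveParams:
    """Main and context vectors with their bias terms."""

    V: np.ndarray        # (N, d) main word vectors
    V_tilde: np.ndarray  # (N, d) context vectors
    b: np.ndarray        # (N,) main biases
    b_tilde: np.ndarray  # (N,) context biases

    @property
    def d(self) -> int:
        return self.V.shape[1]

    @classmethod
    def init(cls, n: int, d: int, rng: np.random.Generator) -> "GloveParams":
        # uniform in (-0.5/d, 0.5/d): standard GloVe initialisation
        scale = 0.5 / d
        return cls(
            V=rng.uniform(-scale, scale, size=(n, d)),
            V_tilde=rng.uniform(-scale, scale, size=(n, d)),
            b=rng.uniform(-scale, scale, size=n),
            b_tilde=rng.uniform(-scale, scale, size=n),
        )


def _check_shapes(params: GloveParams, X: np.ndarray) -> None:
    n = X.shape[0]
    if X.shape != (n, n):
        raise ValidationError(f"X must be square, got {X.shape}")
    if params.V.shape[0] != n or params.V_tilde.shape != params.V.shape:
        raise ValidationError(
            f"parameter rows {params.V.shape} do not match vocabulary size {n}"
        )
    if params.b.shape != (n,) or params.b_tilde.shape != (n,):
        raise ValidationError("bias vectors do not match vocabulary size")


def glove_loss(params: GloveParams, X: np.ndarray, config: GloveConfig) -> float:
    """The energy J evaluated over the nonzero entries of X."""
    _check_shapes(params, X)
    i, j = np.nonzero(X)
    if i.size == 0:
        return 0.0
    x = X[i, j]
    resid = (
        np.einsum("pd,pd->p", params.V[i], params.V_tilde[j])
        + params.b[i]
        + params.b_tilde[j]
        - np.log(x)
    )
    return float(np.sum(glove_weight(x, config.T_X, config.alpha) * resid**2))


def glove_grad(
    params: GloveParams, X: np.ndarray, config: GloveConfig
) -> GloveParams:
    """Analytic gradient of J with respect to every parameter block."""
    _check_shapes(params, X)
    i, j = np.nonzero(X)
    dV = np.zeros_like(params.V)
    dVt = np.zeros_like(params.V_tilde)
    db = np.zeros_like(params.b)
    dbt = np.zeros_like(params.b_tilde)
    if i.size:
        x = X[i, j]
        resid = (
            np.einsum("pd,pd->p", params.V[i], params.V_tilde[j])
            + params.b[i]
            + params.b_tilde[j]
            - np.log(x)
        )
        coef = 2.0 * glove_weight(x, config.T_X, config.alpha) * resid
        np.add.at(dV, i, coef[:, None] * params.V_tilde[j])
        np.add.at(dVt, j, coef[:, None] * params.V[i])
        np.add.at(db, i, coef)
        np.add.at(dbt, j, coef)
    return GloveParams(V=dV, V_tilde=dVt, b=db, b_tilde=dbt)


@dataclass
class GloveEmbedding:
    """Fitted per-token vectors plus fit metadata."""

    tokens: list[str]
    vectors: np.ndarray  # (N, d)
    loss_history: list[float] = field(default_factory=list)
    config: Optional[GloveConfig] = None
    params: Optional[GloveParams] = None

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.tokens):
            raise ValidationError("vector table rows must match token count")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.index[token]]
        except KeyError:
            raise ValidationError(f"token {token!r} not in embedding") from None

    def __contains__(self, token: str) -> bool:
        return token in self.index


def fit_glove(X: CooccurrenceMatrix, config: GloveConfig) -> GloveEmbedding:
    """Fit GloVe vectors by seeded per-pair SGD with AdaGrad step sizes.

    Every nonzero cell (i, j) of the symmetric matrix is a training pair;
    pairs are visited in a freshly shuffled order each epoch.  The full
    energy J is recorded after every epoch (``loss_history[0]`` is the
    pre-training value).  A non-finite loss raises, naming the epoch.
    """
    n = len(X.vocab)
    rng = np.random.default_rng(config.seed)
    params = GloveParams.init(n, config.d, rng)

    ii, jj = np.nonzero(X.X)
    xs = X.X[ii, jj]
    logx = np.log(xs)
    fw = np.atleast_1d(glove_weight(xs, config.T_X, config.alpha))

    # AdaGrad accumulators (init 1.0, as in the reference implementation)
    gV = np.ones_like(params.V)
    gVt = np.ones_like(params.V_tilde)
    gb = np.ones_like(params.b)
    gbt = np.ones_like(params.b_tilde)

    history = [glove_loss(params, X.X, config)]
    for epoch in range(config.epochs):
        for p in rng.permutation(ii.size):
            i, j = ii[p], jj[p]
            vi, vj = params.V[i], params.V_tilde[j]
            resid = vi @ vj + params.b[i] + params.b_tilde[j] - logx[p]
            coef = 2.0 * fw[p] * resid
            dvi = coef * vj
            dvj = coef * vi
            gV[i] += dvi**2
            gVt[j] += dvj**2
            gb[i] += coef**2
            gbt[j] += coef**2
            params.V[i] -= config.lr * dvi / np.sqrt(gV[i])
            params.V_tilde[j] -= config.lr * dvj / np.sqrt(gVt[j])
            params.b[i] -= config.lr * coef / np.sqrt(gb[i])
            params.b_tilde[j] -= config.lr * coef / np.sqrt(gbt[j])
        loss = glove_loss(params, X.X, config)
        if not np.isfinite(loss):
            raise ValidationError(f"non-finite GloVe loss at epoch {epoch + 1}")
        history.append(loss)

    vectors = params.V + params.V_tilde if config.export == "sum" else params.V.copy()
    return GloveEmbedding(
        tokens=list(X.vocab.tokens),
        vectors=vectors,
        loss_history=history,
        config=config,
        params=params,
    )


def save_embedding(embedding: GloveEmbedding, path: str | Path) -> None:
    """GloVe text format: one ``token v1 ... vd`` line per token."""
    with open(path, "w", encoding="utf-8") as fh:
        for token, vec in zip(embedding.tokens, embedding.vectors):
            fh.write(token + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def load_embedding(path: str | Path) -> GloveEmbedding:
    """Read an embedding table written by :func:`save_embedding`."""
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    d: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'token v1 ... vd'")
            vec = np.array([float(v) for v in parts[1:]], dtype=np.float64)
            if d is None:
                d = vec.size
            elif vec.size != d:
                raise ParseError(
                    f"{path}:{lineno}: dimension {vec.size} != {d} of first line"
                )
            tokens.append(parts[0])
            rows.append(vec)
    if not tokens:
        raise ParseError(f"{path}: empty embedding file")
    return GloveEmbedding(tokens=tokens, vectors=np.vstack(rows))
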