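"""Numeric encoding of tokenized fragments.

Two encoders share one output contract — an (L-k+1) x d matrix per fragment
(39 x 300 at the defaults) — so the downstream classifier sees the same
sequence length either way:

* GloVe: row t is the fitted word vector of token t.
* one-hot: row t is the indicator vector of token t's vocabulary index
  (d = |vocab|).  One-hot is defined at the k-mer level, not the base
  level, precisely so the two encodings are interchangeable inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .glove import GloveEmbedding
from .kmer import KmerVocabulary, tokenize
from .sequence_io import FragmentDataset

logger = logging.getLogger(__name__)


@dataclass
class EncodedSample:
    """One fragment as a real (L-k+1) x d matrix."""

    matrix: np.ndarray
    encoding: str  # "glove" or "onehot"
    source_id: str


def encode_glove(
    tokens: Sequence[str],
    embedding: GloveEmbedding,
    source_id: str = "",
    unknown: str = "error",
) -> EncodedSample:
    """Stack the embedding vectors of ``tokens`` in order.

    Unknown tokens raise by default; ``unknown="zero"`` maps them to the
    zero vector with a logged count (silent substitution would corrupt
    evaluation, so it is opt-in).
    """
    if unknown not in ("error", "zero"):
        raise ValidationError(f"unknown-token policy must be 'error' or 'zero'")
    rows = np.zeros((len(tokens), embedding.d), dtype=np.float64)
    n_unknown = 0
    for t, tok in enumerate(tokens):
        if tok in embedding:
            rows[t] = embedding.vector(tok)
        elif unknown == "zero":
            n_unknown += 1
        else:
            raise ValidationError(f"token {tok!r} not in embedding")
    if n_unknown:
        logger.info("encode_glove: %d unknown tokens mapped to zero", n_unknown)
    return EncodedSample(matrix=rows, encoding="glove", source_id=source_id)


def encode_onehot(
    tokens: Sequence[str], vocab: KmerVocabulary, source_id: str = ""
) -> EncodedSample:
    """Indicator-vector encoding over the vocabulary index."""
    ids = vocab.encode(tokens)
    rows = np.zeros((len(tokens), len(vocab)), dtype=np.float64)
    rows[np.arange(len(tokens)), ids] = 1.0
    return EncodedSample(matrix=rows, encoding="onehot", source_id=source_id)


def encode_dataset(
    dataset: FragmentDataset,
    k: int,
    embedding: Optional[GloveEmbedding] = None,
    vocab: Optional[KmerVocabulary] = None,
    encoding: str = "glove",
    unknown: str = "error",
) -> tuple[list[str], np.ndarray, Optional[np.ndarray]]:
    """Encode every fragment of a dataset, preserving record order.

    Returns ``(ids, X, y)`` where X has shape (n_records, L-k+1, d) and y is
    the label vector (or None if any record is unlabeled).
    """
    if encoding == "glove":
        if embedding is None:
            raise ValidationError("glove encoding requires an embedding")
        samples = [
            encode_glove(tokenize(r.seq, k), embedding, r.id, unknown=unknown)
            for r in dataset
        ]
    elif encoding == "onehot":
        if vocab is None:
            raise ValidationError("onehot encoding requires a vocabulary")
        samples = [encode_onehot(tokenize(r.seq, k), vocab, r.id) for r in dataset]
    else:
        raise ValidationError(f"encoding must be 'glove' or 'onehot', got {encoding!r}")
    X = np.stack([s.matrix for s in samples])
    labels = dataset.labels()
    y = None if labels is None else np.asarray(labels, dtype=np.int64)
    return [r.id for r in dataset], X, y


def save_encoded(
    path_prefix: str | Path,
    ids: Sequence[str],
    X: np.ndarray,
    y: Optional[np.ndarray],
    encoding: str,
) -> None:
    """Persist an encoded batch as ``<prefix>.npy`` + a JSON sidecar."""
    prefix = Path(path_prefix)
    np.save(str(prefix) + ".npy", X.astype(np.float32))
    sidecar = {
        "shape": list(X.shape),
        "encoding": encoding,
        "ids": list(ids),
        "labels": None if y is None else [int(v) for v in y],
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_encoded(
    path_prefix: str | Path,
) -> tuple[list[str], np.ndarray, Optional[np.ndarray], str]:
    prefix = Path(path_prefix)
    X = np.load(str(prefix) + ".npy").astype(np.float64)
    sidecar = json.loads(Path(str(prefix) + ".json").read_text(encoding="utf-8"))
    if list(X.shape) != sidecar["shape"]:
        raise ValidationError(f"{prefix}: tensor shape does not match sidecar")
    y = sidecar["labels"]
    return (
        sidecar["ids"],
        X,
        None if y is None else np.asarray(y, dtype=np.int64),
        sidecar["encoding"],
    )
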