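"""Overlapping k-mer tokenization and vocabulary handling.

A fragment of length L is read 5'->3' by a sliding window of width k and
stride 1, producing L-k+1 overlapping tokens (39 for a 41-bp fragment at
k=3).  k must be at least 3 so that every base has both a left and a right
neighbour inside some token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .sequence_io import FragmentDataset


def tokenize(seq: str, k: int = 3) -> list[str]:
    """Return the L-k+1 overlapping k-mers of ``seq`` in 5'->3' order."""
    if k < 3:
        raise ValidationError(f"k must be >= 3, got {k}")
    if len(seq) < k:
        raise ValidationError(f"sequence length {len(seq)} < k = {k}")
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


@dataclass
class KmerVocabulary:
    """Ordered k-mer vocabulary with a token <-> integer-id bijection."""

    k: int
    tokens: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("vocabulary tokens must be distinct")
        if any(len(t) != self.k for t in self.tokens):
            raise ValidationError(f"all tokens must have length k = {self.k}")
        if len(self.tokens) > 4**self.k:
            raise ValidationError(f"more than 4^{self.k} tokens")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Map a token sequence to integer ids (raises on unknown tokens)."""
        try:
            return np.array([self.index[t] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"token {exc.args[0]!r} not in vocabulary") from None

    def save(self, path: str | Path) -> None:
        """One token per line; the line number (0-based) is the id."""
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        tokens = Path(path).read_text(encoding="utf-8").split()
        if not tokens:
            raise ValidationError(f"{path}: empty vocabulary file")
        return cls(k=len(tokens[0]), tokens=tokens)

    @classmethod
    def full(cls, k: int) -> "KmerVocabulary":
        """The complete 4^k vocabulary in lexicographic order."""
        from itertools import product

        return cls(k=k, tokens=["".join(p) for p in product("ACGT", repeat=k)])


@dataclass
class TokenizedCorpus:
    """Fragments as sequences of vocabulary token ids."""

    documents: list[np.ndarray]
    vocab: KmerVocabulary


def build_vocab(corpus: Iterable[str], k: int = 3) -> KmerVocabulary:
    """Build the vocabulary of every k-mer observed in ``corpus``.

    Tokens are ordered by first occurrence, so the result is deterministic
    for a fixed corpus order.  ``corpus`` is an iterable of fragment strings
    (or a :class:`FragmentDataset`).
    """
    if isinstance(corpus, FragmentDataset):
        corpus = corpus.sequences()
    tokens: dict[str, None] = {}
    n_docs = 0
    for seq in corpus:
        n_docs += 1
        for tok in tokenize(seq, k):
            tokens.setdefault(tok, None)
    if n_docs == 0:
        raise ValidationError("cannot build a vocabulary from an empty corpus")
    return KmerVocabulary(k=k, tokens=list(tokens))


def tokenize_corpus(
    corpus: Iterable[str], vocab: KmerVocabulary
) -> TokenizedCorpus:
    """Tokenize fragments and map them to vocabulary ids."""
    if isinstance(corpus, FragmentDataset):
        corpus = corpus.sequences()
    docs = [vocab.encode(tokenize(seq, vocab.k)) for seq in corpus]
    return TokenizedCorpus(documents=docs, vocab=vocab)
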