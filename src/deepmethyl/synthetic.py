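"""Synthetic labeled fragment datasets with a planted, tunable signal.

Real 5mC benchmarks pair a few tens of thousands of methylated 41-bp
fragments with roughly 10-15x as many unmethylated ones.  This module
emulates that structure with a fully controllable signal: negatives are
i.i.d. background sequence (uniform A/C/G/T by default) with the candidate
base forced at the centre; positives are the same background with a short
motif planted at a random offset in a configurable window, with probability
``planting_prob`` and optional per-position mutation noise.  The planted
motif makes the positive class provably learnable (a literal substring
detector already separates the classes at ``planting_prob = 1``), so
end-to-end classifier tests have a known-fair target.

Class-imbalance presets mirror the negative:positive ratios 1:10, 1:12 and
1:15 used in published benchmark sweeps, 1:12 being the most common.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .sequence_io import FragmentDataset, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Recipe for one labeled fragment dataset.

    motif_offset_range : inclusive (lo, hi) start offsets of the motif
        relative to the centre index delta; the default plants in the right
        flank, clear of the centre base.  The centre base is forced back to
        ``center_base`` after planting regardless.
    planting_prob : probability that a positive actually carries the motif.
    motif_mutation_prob : per-position chance that a planted motif base is
        substituted by a random different base (difficulty knob).
    background : base composition, mapping A/C/G/T to probabilities.
    """

    n_pos: int
    n_neg: int
    delta: int = 20
    center_base: str = "C"
    motif: str = "ACGTACGT"
    motif_offset_range: Optional[tuple[int, int]] = None
    planting_prob: float = 1.0
    motif_mutation_prob: float = 0.0
    background: Optional[dict[str, float]] = None
    seed: int = 0

    @classmethod
    def from_ratio(cls, n_pos: int, ratio: int, **kwargs) -> "SyntheticSpec":
        """Negative count as ``n_pos * ratio`` (the 1:ratio presets)."""
        return cls(n_pos=n_pos, n_neg=n_pos * ratio, **kwargs)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must be positive")
        if self.delta < 1:
            raise ValidationError(f"delta must be >= 1, got {self.delta}")
        if self.center_base not in "ACGT":
            raise ValidationError(f"center_base must be A/C/G/T, got {self.center_base!r}")
        if not (0.0 <= self.planting_prob <= 1.0):
            raise ValidationError("planting_prob must be in [0, 1]")
        if not (0.0 <= self.motif_mutation_prob <= 1.0):
            raise ValidationError("motif_mutation_prob must be in [0, 1]")
        if set(self.motif) - set("ACGT"):
            raise ValidationError("motif must be over A/C/G/T")
        length = 2 * self.delta + 1
        if len(self.motif) > length:
            raise ValidationError("motif longer than the fragment")
        if self.motif_offset_range is None:
            # right flank, clear of the centre: fits whenever possible
            lo = min(3, self.delta - len(self.motif))
            hi = self.delta - len(self.motif)
            if lo > hi or lo < -self.delta:
                lo, hi = -self.delta, self.delta + 1 - len(self.motif)
            self.motif_offset_range = (lo, hi)
        lo, hi = self.motif_offset_range
        if lo > hi:
            raise ValidationError(f"empty motif offset range {self.motif_offset_range}")
        for off in (lo, hi):
            start = self.delta + off
            if start < 0 or start + len(self.motif) > length:
                raise ValidationError(
                    f"motif at offset {off} falls outside the {length}-bp fragment"
                )
        if self.background is None:
            self.background = {b: 0.25 for b in "ACGT"}
        probs = np.array([self.background.get(b, 0.0) for b in "ACGT"])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("background composition must sum to 1")

    @property
    def length(self) -> int:
        return 2 * self.delta + 1


def _random_fragments(
    rng: np.random.Generator, n: int, length: int, probs: np.ndarray
) -> np.ndarray:
    """(n, length) array of single characters drawn from the composition."""
    return _BASES[rng.choice(4, size=(n, length), p=probs)]


def generate(spec: SyntheticSpec) -> FragmentDataset:
    """Draw the dataset described by ``spec``; deterministic per seed.

    Positives come first (ids ``pos_<i>``), then negatives (``neg_<i>``);
    use :func:`stratified_split` for shuffled folds.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.background[b] for b in "ACGT"])
    L = spec.length
    m = len(spec.motif)
    motif_arr = np.array(list(spec.motif))
    lo, hi = spec.motif_offset_range

    pos = _random_fragments(rng, spec.n_pos, L, probs)
    planted = rng.random(spec.n_pos) < spec.planting_prob
    offsets = rng.integers(lo, hi + 1, size=spec.n_pos)
    for r in np.nonzero(planted)[0]:
        start = spec.delta + int(offsets[r])
        planted_motif = motif_arr.copy()
        if spec.motif_mutation_prob > 0:
            mutate = rng.random(m) < spec.motif_mutation_prob
            for q in np.nonzero(mutate)[0]:
                choices = [b for b in "ACGT" if b != planted_motif[q]]
                planted_motif[q] = choices[rng.integers(3)]
        pos[r, start : start + m] = planted_motif
    pos[:, spec.delta] = spec.center_base

    neg = _random_fragments(rng, spec.n_neg, L, probs)
    neg[:, spec.delta] = spec.center_base

    records = [
        SequenceRecord(id=f"pos_{i}", seq="".join(row), label=1)
        for i, row in enumerate(pos)
    ] + [
        SequenceRecord(id=f"neg_{i}", seq="".join(row), label=0)
        for i, row in enumerate(neg)
    ]
    return FragmentDataset(records=records, delta=spec.delta, provenance="synthetic")


def stratified_split(
    dataset: FragmentDataset, test_fraction: float, seed: int = 0
) -> tuple[FragmentDataset, FragmentDataset]:
    """Per-class split: round(count * fraction) records go to the test fold.

    The folds are disjoint and exhaustive; each class is shuffled with the
    given seed before splitting.  A class with fewer than 2 members raises.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = dataset.labels()
    if labels is None:
        raise ValidationError("stratified_split requires labeled records")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.nonzero(y == cls)[0]
        if members.size < 2:
            raise ValidationError(
                f"class {cls} has {members.size} member(s); need at least 2"
            )
        members = rng.permutation(members)
        n_test = int(round(members.size * test_fraction))
        test_idx.extend(members[:n_test])
        train_idx.extend(members[n_test:])
    train_idx.sort()
    test_idx.sort()
    mk = lambda idx, tag: FragmentDataset(
        records=[dataset.records[i] for i in idx],
        delta=dataset.delta,
        provenance=f"{dataset.provenance}:{tag}",
    )
    return mk(train_idx, "train"), mk(test_idx, "test")
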