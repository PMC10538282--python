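"""Reading, writing and windowing of fixed-length DNA fragments.

The unit of data throughout the package is a fragment of length ``2*delta + 1``
centred on a candidate methylation site (41 bp at the default flank
``delta = 20``, with the candidate cytosine at the 0-based centre index
``delta``).  Fragments travel as :class:`FragmentDataset` and are stored on
disk either as FASTA or as a tab-separated table with columns
``id``, ``sequence``, ``label``.

Processing is single-strand: no reverse-complement scanning is performed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA fragment with an identifier and optional label."""

    id: str
    seq: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )
        bad = set(self.seq) - DNA_ALPHABET_N
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r} in sequence"
            )


@dataclass
class FragmentDataset:
    """An ordered collection of equal-length fragments sharing one flank size.

    Invariants: every record has length ``2*delta + 1`` and record ids are
    unique.  Enforced at construction.
    """

    records: list[SequenceRecord]
    delta: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValidationError(f"delta must be >= 1, got {self.delta}")
        expected = 2 * self.delta + 1
        bad = [r.id for r in self.records if len(r.seq) != expected]
        if bad:
            raise ValidationError(
                f"records with length != 2*delta+1 = {expected}: {bad[:10]}"
                + ("..." if len(bad) > 10 else "")
            )
        seen: set[str] = set()
        dup = []
        for r in self.records:
            if r.id in seen:
                dup.append(r.id)
            seen.add(r.id)
        if dup:
            raise ValidationError(f"duplicate record ids: {dup[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def length(self) -> int:
        """Fragment length ``2*delta + 1``."""
        return 2 * self.delta + 1

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def labels(self) -> Optional[list[int]]:
        """Labels in record order, or ``None`` if any record is unlabeled."""
        if any(r.label is None for r in self.records):
            return None
        return [r.label for r in self.records]  # type: ignore[misc]


def _delta_from_length(length: int) -> int:
    if length < 3 or length % 2 == 0:
        raise ValidationError(
            f"fragment length must be odd and >= 3 (2*delta+1), got {length}"
        )
    return (length - 1) // 2


def read_fragments(path: str | Path, format: Optional[str] = None) -> FragmentDataset:
    """Read a fragment dataset from a FASTA or TSV file.

    ``format`` is ``"fasta"`` or ``"tsv"``; if omitted it is inferred from the
    file suffix.  TSV files must carry a header with columns
    ``id``, ``sequence``, ``label`` (``label`` may be empty for unlabeled
    records).  The flank size ``delta`` is inferred from the (common) record
    length; records preserve file order.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fasta" if suffix in (".fa", ".fasta", ".fna") else "tsv"
    if format == "fasta":
        records = _read_fasta(path)
    elif format == "tsv":
        records = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'tsv')")
    if not records:
        raise ParseError(f"{path}: no records found")
    delta = _delta_from_length(len(records[0].seq))
    return FragmentDataset(records=records, delta=delta, provenance=str(path))


def _read_fasta(path: Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def _read_tsv(path: Path) -> list[SequenceRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "sequence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: TSV header must contain columns 'id' and 'sequence' "
                f"(and optionally 'label'); got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            raw_label = (row.get("label") or "").strip()
            if raw_label == "":
                label: Optional[int] = None
            elif raw_label in ("0", "1"):
                label = int(raw_label)
            else:
                raise ValidationError(
                    f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}"
                )
            seq = (row.get("sequence") or "").strip().upper()
            if not seq:
                raise ParseError(f"{path}:{lineno}: empty sequence field")
            records.append(SequenceRecord(id=row["id"], seq=seq, label=label))
    return records


def write_fragments(dataset: FragmentDataset, path: str | Path) -> None:
    """Write a dataset as the standard fragment TSV (id, sequence, label)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "sequence", "label"])
        for rec in dataset:
            writer.writerow([rec.id, rec.seq, "" if rec.label is None else rec.label])


def extract_windows(
    seq: str,
    delta: int,
    center_base: str,
    source_id: str = "seq",
    drop_n: bool = True,
) -> FragmentDataset:
    """Extract every full-length window centred on ``center_base``.

    One record is emitted per occurrence of ``center_base`` at a 0-based
    position ``p`` with ``delta <= p <= len(seq) - 1 - delta``; the window is
    ``seq[p-delta : p+delta+1]`` (inclusive flanks, length ``2*delta + 1``).
    Record ids encode the source position as ``{source_id}:{p}``.

    Windows containing ``N`` are dropped with a logged count (the k-mer
    vocabulary is defined over A/C/G/T only).  An empty or windowless input
    yields an empty dataset, not an error.
    """
    if delta < 1:
        raise ValidationError(f"delta must be >= 1, got {delta}")
    if center_base not in DNA_ALPHABET:
        raise ValidationError(f"center_base must be one of A,C,G,T, got {center_base!r}")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET_N
    if bad:
        raise ValidationError(f"illegal characters in sequence: {sorted(bad)!r}")

    records = []
    n_dropped = 0
    for p in range(delta, len(seq) - delta):
        if seq[p] != center_base:
            continue
        window = seq[p - delta : p + delta + 1]
        if drop_n and "N" in window:
            n_dropped += 1
            continue
        records.append(SequenceRecord(id=f"{source_id}:{p}", seq=window))
    if n_dropped:
        logger.info("extract_windows: dropped %d windows containing 'N'", n_dropped)
    return FragmentDataset(records=records, delta=delta, provenance=f"windows:{source_id}")


def write_predictions(
    dataset: FragmentDataset,
    probs: Sequence[float],
    calls: Sequence[int],
    path: str | Path,
) -> None:
    """Write per-record predictions as TSV (id, sequence, prob_positive, call).

    ``probs`` and ``calls`` must align 1:1 with the records; probabilities
    must lie in [0, 1] and calls in {0, 1}.  Probabilities are printed with 6
    decimal places, which a read-back reproduces exactly.
    """
    if len(probs) != len(dataset) or len(calls) != len(dataset):
        raise ValidationError(
            f"probs ({len(probs)}) and calls ({len(calls)}) must match "
            f"record count ({len(dataset)})"
        )
    for rec, p, c in zip(dataset, probs, calls):
        if not (0.0 <= float(p) <= 1.0):
            raise ValidationError(f"record {rec.id!r}: probability {p} outside [0, 1]")
        if c not in (0, 1):
            raise ValidationError(f"record {rec.id!r}: call must be 0 or 1, got {c!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "sequence", "prob_positive", "call"])
        for rec, p, c in zip(dataset, probs, calls):
            writer.writerow([rec.id, rec.seq, f"{float(p):.6f}", int(c)])


def read_predictions(path: str | Path) -> tuple[list[str], list[float], list[int]]:
    """Read back a predictions TSV; returns (ids, probs, calls)."""
    ids, probs, calls = [], [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                ids.append(row["id"])
                probs.append(float(row["prob_positive"]))
                calls.append(int(row["call"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed prediction row") from exc
    return ids, probs, calls
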