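"""Protein sequence I/O, validation, and labeled-dataset handling.

Sequences are plain strings over the 20-letter standard amino-acid
alphabet.  Anything else (B, X, Z, U, O, gaps, stops) is rejected by
:func:`validate_sequence`, mirroring the hygiene rule used to curate
antioxidant-protein training data: ambiguous entries are excluded rather
than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinSequence:
    """A named residue string over the standard 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be a non-empty token")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Verdict:
    """Outcome of sequence validation: accepted, or rejected with a reason."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass
class LabeledDataset:
    """Sequences plus a per-sequence class label in {positive, negative}."""

    sequences: list[ProteinSequence]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")
        bad = {l for l in self.labels} - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate id {dup[0]}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            [self.sequences[i] for i in idx], [self.labels[i] for i in idx]
        )

    def class_counts(self) -> dict[str, int]:
        return {
            POSITIVE: self.labels.count(POSITIVE),
            NEGATIVE: self.labels.count(NEGATIVE),
        }

    @classmethod
    def from_fasta_pair(
        cls, positive_path: str | Path, negative_path: str | Path
    ) -> "LabeledDataset":
        pos = read_fasta(positive_path)
        neg = read_fasta(negative_path)
        return cls(pos + neg, [POSITIVE] * len(pos) + [NEGATIVE] * len(neg))


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into ProteinSequence records.

    Residues are uppercased; record order is preserved.  Raises on an
    empty file or duplicate ids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    return seqs


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def validate_sequence(seq: ProteinSequence, min_length: int = 1) -> Verdict:
    """Accept iff every residue is standard and the length clears min_length.

    The reason names the first offending character (1-based position) or
    the failing length, whichever applies first.
    """
    for pos, ch in enumerate(seq.residues, start=1):
        if ch not in ALPHABET_SET:
            return Verdict(False, f"nonstandard letter {ch} at position {pos}")
    if len(seq) < min_length:
        return Verdict(False, f"length {len(seq)} < {min_length}")
    return Verdict(True)


def split_dataset(
    data: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split.

    Each class is split independently so the test set receives
    round(test_fraction x class size) members (ties round up, toward the
    test set).  Deterministic under the seed; train and test partition the
    input by id.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = data.class_counts()
    for cls, n in counts.items():
        if n < 2:
            raise ValueError(f"class {cls!r} has {n} member(s); need at least 2")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in (POSITIVE, NEGATIVE):
        cls_idx = np.array([i for i, l in enumerate(data.labels) if l == cls])
        # round-half-up so a .5 tie lands in the test set
        n_test = int(np.floor(test_fraction * len(cls_idx) + 0.5))
        n_test = min(max(n_test, 1), len(cls_idx) - 1)
        perm = rng.permutation(len(cls_idx))
        test_idx.extend(cls_idx[perm[:n_test]])
        train_idx.extend(cls_idx[perm[n_test:]])
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read an id,label CSV; labels are case-insensitive positive/negative."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: need columns id,label")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        lab = str(row["label"]).strip().lower()
        if lab not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {row['label']!r} for id {row['id']!r}")
        out[str(row["id"])] = lab
    return out
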