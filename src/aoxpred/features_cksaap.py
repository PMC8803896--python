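"""Composition of k-spaced amino-acid pairs (CKSAAP) and combined encoding.

A k-spaced pair is an ordered pair of residues separated by exactly k
intervening positions: residue i at position p, residue j at p+k+1.  A
sequence of length N has N-k-1 such pairs, so each of the 400 ordered
pair frequencies is n_ij / (N-k-1) and the 400-vector sums to 1 whenever
N >= k+2.  k=0 reduces to dipeptide composition; the antioxidant
pipeline default is k=3 (3-spaced residue pairs).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .feature_matrix import FeatureMatrix
from .features_188d import (
    GroupingTable,
    TransitionDenominator,
    extract_188d,
    feature_names_188d,
)
from .sequence_io import ALPHABET, LabeledDataset, ProteinSequence

_RESIDUE_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: ordered pair labels, row-major over the alphabetical alphabet: AA, AC, ... YY
PAIR_LABELS = tuple(a + b for a in ALPHABET for b in ALPHABET)


def cksaap(seq: ProteinSequence, k: int) -> np.ndarray:
    """400-vector of k-spaced ordered pair frequencies.

    Requires N >= k+2 so at least one pair exists.
    """
    if k < 0:
        raise ValueError("gap k must be non-negative")
    N = len(seq)
    if N < k + 2:
        raise ValueError(
            f"sequence {seq.id!r} has length {N}; k={k} needs length >= {k + 2}"
        )
    idx = np.array([_RESIDUE_INDEX[c] for c in seq.residues], dtype=np.intp)
    pair_codes = idx[: N - k - 1] * 20 + idx[k + 1 :]
    return np.bincount(pair_codes, minlength=400) / (N - k - 1)


def cksaap_feature_names(k: int) -> list[str]:
    return [f"cksaap.k{k}.{p}" for p in PAIR_LABELS]


def extract_combined(
    seq: ProteinSequence,
    ks: Sequence[int] = (3,),
    tables: dict[str, GroupingTable] | None = None,
    transition_denominator: TransitionDenominator = "L",
    include_188d: bool = True,
) -> np.ndarray:
    """188D descriptor followed by one CKSAAP block per gap, ascending."""
    blocks = []
    if include_188d:
        blocks.append(extract_188d(seq, tables, transition_denominator))
    for k in sorted(ks):
        blocks.append(cksaap(seq, k))
    if not blocks:
        raise ValueError("feature spec selects no features")
    return np.concatenate(blocks)


def combined_feature_names(
    ks: Sequence[int] = (3,), include_188d: bool = True
) -> list[str]:
    names = feature_names_188d() if include_188d else []
    for k in sorted(ks):
        names += cksaap_feature_names(k)
    return names


def encode_dataset(
    data: LabeledDataset,
    ks: Sequence[int] = (3,),
    tables: dict[str, GroupingTable] | None = None,
    transition_denominator: TransitionDenominator = "L",
    include_188d: bool = True,
) -> FeatureMatrix:
    """Encode every sequence; rows keep dataset order, columns are named."""
    rows = [
        extract_combined(s, ks, tables, transition_denominator, include_188d)
        for s in data.sequences
    ]
    X = pd.DataFrame(rows, index=pd.Index(data.ids, name="id"),
                     columns=combined_feature_names(ks, include_188d))
    y = pd.Series([1 if l == "positive" else 0 for l in data.labels],
                  index=X.index, name="label")
    return FeatureMatrix(X, y)


def encode_sequences(
    seqs: Sequence[ProteinSequence],
    ks: Sequence[int] = (3,),
    tables: dict[str, GroupingTable] | None = None,
    transition_denominator: TransitionDenominator = "L",
    include_188d: bool = True,
) -> FeatureMatrix:
    """Encode unlabeled sequences (e.g. a screening set)."""
    rows = [
        extract_combined(s, ks, tables, transition_denominator, include_188d)
        for s in seqs
    ]
    X = pd.DataFrame(rows, index=pd.Index([s.id for s in seqs], name="id"),
                     columns=combined_feature_names(ks, include_188d))
    return FeatureMatrix(X)
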