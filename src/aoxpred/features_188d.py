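"""The 188-dimensional physicochemical descriptor.

The descriptor concatenates:

* 20 amino-acid composition features — the frequency n_a / L of each
  residue a, in fixed alphabetical order ``ACDEFGHIKLMNPQRSTVWY``;
* for each of 8 physicochemical properties, a 21-feature CTD block.
  Each property partitions the 20 residues into three groups (a fixed
  lookup table shipped with the package).  The block holds:

  - **content** (3): the fraction of residues falling in each group;
  - **distribution** (15): for each group, the 1-based positions of the
    first and of the 25%/50%/75%/100%-quantile occurrences of that
    group's residues (ceiling rank), each divided by the sequence
    length L; all five are 0 when the group is absent;
  - **transition** (3): counts of adjacent residue pairs whose members
    lie in groups (I,II), (I,III), (II,III) — either order — divided by
    L (a ``transition_denominator="L-1"`` switch selects the more common
    convention).

20 + 8 x 21 = 188 features, all in [0, 1].  The "secondary structure"
property is a residue grouping like the others, not a structure
prediction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from math import ceil
from typing import Literal, Sequence

import numpy as np

from .sequence_io import ALPHABET, ProteinSequence

_RESIDUE_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: property order of the descriptor blocks (fixed; feature names carry it)
PROPERTY_ORDER = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "surface_tension",
    "secondary_structure",
    "solvent_accessibility",
)

_DIST_POINTS = ("first", "p25", "p50", "p75", "p100")
_TRANS_PAIRS = ((0, 1), (0, 2), (1, 2))

TransitionDenominator = Literal["L", "L-1"]


@dataclass(frozen=True)
class GroupingTable:
    """One physicochemical property's 3-way partition of the alphabet."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.groups)
        if len(joined) != 20 or set(joined) != set(ALPHABET):
            raise ValueError(
                f"{self.name}: groups must partition the 20-letter alphabet"
            )

    def group_of(self, residue: str) -> int:
        """0-based group index of a residue."""
        for g, members in enumerate(self.groups):
            if residue in members:
                return g
        raise KeyError(residue)

    def group_map(self) -> np.ndarray:
        """Array mapping residue index (alphabetical) -> group index."""
        out = np.empty(20, dtype=np.intp)
        for g, members in enumerate(self.groups):
            for r in members:
                out[_RESIDUE_INDEX[r]] = g
        return out


def load_grouping_tables(path: str | None = None) -> dict[str, GroupingTable]:
    """Load the 8 shipped grouping tables (or a user override TSV)."""
    if path is None:
        source = resources.files("aoxpred").joinpath("data/grouping_tables.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    tables: dict[str, GroupingTable] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        tables[row["property"]] = GroupingTable(
            row["property"], (row["group1"], row["group2"], row["group3"])
        )
    return tables


GROUPING_TABLES: dict[str, GroupingTable] = load_grouping_tables()


def _encode(seq: ProteinSequence) -> np.ndarray:
    try:
        return np.array([_RESIDUE_INDEX[c] for c in seq.residues], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"sequence {seq.id!r} contains nonstandard residue {exc.args[0]!r}"
        ) from exc


def aac(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies, alphabetical order."""
    idx = _encode(seq)
    return np.bincount(idx, minlength=20) / len(idx)


def ctd_property(
    seq: ProteinSequence,
    table: GroupingTable,
    transition_denominator: TransitionDenominator = "L",
) -> np.ndarray:
    """21 content/distribution/transition features for one property."""
    idx = _encode(seq)
    L = len(idx)
    groups = table.group_map()[idx]

    counts = np.bincount(groups, minlength=3)
    content = counts / L

    dist = np.zeros((3, 5))
    for g in range(3):
        positions = np.flatnonzero(groups == g) + 1  # 1-based
        n = positions.size
        if n == 0:
            continue
        ranks = [1, ceil(0.25 * n), ceil(0.50 * n), ceil(0.75 * n), n]
        dist[g] = positions[np.array(ranks) - 1] / L

    trans = np.zeros(3)
    if L > 1:
        a, b = groups[:-1], groups[1:]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        denom = L if transition_denominator == "L" else L - 1
        for t, (g1, g2) in enumerate(_TRANS_PAIRS):
            trans[t] = np.count_nonzero((lo == g1) & (hi == g2)) / denom

    return np.concatenate([content, dist.ravel(), trans])


def feature_names_188d() -> list[str]:
    """Stable, self-describing names for the 188 columns."""
    names = [f"aac.{a}" for a in ALPHABET]
    for prop in PROPERTY_ORDER:
        names += [f"{prop}.content.g{g}" for g in (1, 2, 3)]
        for g in (1, 2, 3):
            names += [f"{prop}.dist.g{g}.{p}" for p in _DIST_POINTS]
        names += [f"{prop}.trans.g{g1+1}g{g2+1}" for g1, g2 in _TRANS_PAIRS]
    return names


def extract_188d(
    seq: ProteinSequence,
    tables: dict[str, GroupingTable] | None = None,
    transition_denominator: TransitionDenominator = "L",
) -> np.ndarray:
    """Full 188-dimensional descriptor for one sequence."""
    tables = GROUPING_TABLES if tables is None else tables
    blocks = [aac(seq)]
    for prop in PROPERTY_ORDER:
        blocks.append(ctd_property(seq, tables[prop], transition_denominator))
    return np.concatenate(blocks)
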