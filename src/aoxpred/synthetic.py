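"""Synthetic labeled protein datasets with a planted, tunable signal.

Real antioxidant/non-antioxidant training data cannot be bundled, so
this module generates stand-in datasets in which the class signal is
known by construction and analytically checkable:

* negatives are drawn i.i.d. uniform over the 20 standard residues;
* positives are drawn from a delta-tilted mixture: with probability
  ``effect`` a residue comes uniformly from a designated group (default
  the hydrophobicity group III, CVLIMFW), otherwise from the background.
  The expected group-content excess in positives over negatives is then
  effect * (1 - |group|/20);
* optionally, a designated 3-spaced residue pair is planted in
  positives at a stated per-sequence rate, giving the CKSAAP encoder a
  detectable pair signal.

The default class imbalance (710 positives : 1552 negatives, ~1:2.19)
mirrors a realistic curated antioxidant corpus so the undersampling
stage is exercised at scale.  A natural amino-acid-frequency background
is available for realism; the uniform default keeps the tilt exactly
checkable.  The generator plants statistical structure only — it does
not simulate antioxidant biology — so downstream results demonstrate
pipeline correctness and sensitivity, not real-data performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .sequence_io import (
    ALPHABET,
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    ProteinSequence,
    write_fasta,
)

#: Swiss-Prot-like background residue frequencies (order ACDEFGHIKLMNPQRSTVWY)
NATURAL_FREQUENCIES = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0664,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
NATURAL_FREQUENCIES = NATURAL_FREQUENCIES / NATURAL_FREQUENCIES.sum()

DEFAULT_EFFECT_GROUP = "CVLIMFW"  # hydrophobicity group III
DEFAULT_PLANTED_PAIR = ("W", "W")
PLANTED_PAIR_GAP = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror a realistic curated corpus."""

    n_pos: int = 710
    n_neg: int = 1552
    length_range: tuple[int, int] = (50, 200)
    effect: float = 0.15  # probability mass shifted toward effect_group
    effect_group: str = DEFAULT_EFFECT_GROUP
    pair_effect: float = 0.0  # mean planted 3-spaced pairs per positive
    planted_pair: tuple[str, str] = DEFAULT_PLANTED_PAIR
    background: Literal["uniform", "natural"] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 6 or hi < lo:
            raise ValueError("length_range must satisfy 6 <= min <= max")
        if not 0 <= self.effect < 1:
            raise ValueError("effect must be in [0, 1)")
        if self.pair_effect < 0:
            raise ValueError("pair_effect must be >= 0")
        if not set(self.effect_group) <= set(ALPHABET):
            raise ValueError("effect_group must use standard residues")
        for r in self.planted_pair:
            if r not in ALPHABET:
                raise ValueError("planted_pair must use standard residues")


def _background_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.background == "uniform":
        return np.full(20, 1 / 20)
    return NATURAL_FREQUENCIES.copy()


def _positive_probs(spec: SyntheticSpec) -> np.ndarray:
    """Mixture: (1-effect) * background + effect * uniform-over-group."""
    base = _background_probs(spec)
    group = np.zeros(20)
    for r in spec.effect_group:
        group[ALPHABET.index(r)] = 1 / len(spec.effect_group)
    return (1 - spec.effect) * base + spec.effect * group


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled dataset; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(ALPHABET))
    lo, hi = spec.length_range
    neg_p = _background_probs(spec)
    pos_p = _positive_probs(spec)

    seqs: list[ProteinSequence] = []
    labels: list[str] = []
    for i in range(spec.n_pos):
        L = int(rng.integers(lo, hi + 1))
        residues = rng.choice(letters, size=L, p=pos_p)
        if spec.pair_effect > 0:
            gap = PLANTED_PAIR_GAP
            for _ in range(int(rng.poisson(spec.pair_effect))):
                p = int(rng.integers(0, L - gap - 1))
                residues[p] = spec.planted_pair[0]
                residues[p + gap + 1] = spec.planted_pair[1]
        seqs.append(ProteinSequence(f"pos_{i + 1}", "".join(residues)))
        labels.append(POSITIVE)
    for i in range(spec.n_neg):
        L = int(rng.integers(lo, hi + 1))
        residues = rng.choice(letters, size=L, p=neg_p)
        seqs.append(ProteinSequence(f"neg_{i + 1}", "".join(residues)))
        labels.append(NEGATIVE)
    return LabeledDataset(seqs, labels)


def write_dataset(
    data: LabeledDataset, spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write positive.fasta / negative.fasta plus a provenance JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = [s for s, l in zip(data.sequences, data.labels) if l == POSITIVE]
    neg = [s for s, l in zip(data.sequences, data.labels) if l == NEGATIVE]
    pos_path = out_dir / "positive.fasta"
    neg_path = out_dir / "negative.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    (out_dir / "spec.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return pos_path, neg_path


@dataclass(frozen=True)
class WorkedExample:
    """A hand-computable sequence with frozen expected feature values."""

    sequence: ProteinSequence
    ks: tuple[int, ...]
    expected: dict[str, float]


def worked_example() -> list[WorkedExample]:
    """Tiny fixtures whose encodings were computed by hand.

    Expected values are keyed by the pipeline's feature names; features
    not listed for a fixture are not asserted by it.
    """
    return [
        WorkedExample(
            ProteinSequence("homopoly_A", "AAAAA"),
            ks=(3,),
            expected={"aac.A": 1.0, "cksaap.k3.AA": 1.0},
        ),
        WorkedExample(
            # k=1 pairs: A_A (pos 1,3), A_A (3,5), C_C (2,4); denominator 5-2=3
            ProteinSequence("alternating_AC", "ACACA"),
            ks=(1,),
            expected={"cksaap.k1.AA": 2 / 3, "cksaap.k1.CC": 1 / 3},
        ),
        WorkedExample(
            # all residues in hydrophobicity group I (RKEDQN)
            ProteinSequence("homopoly_R", "RRRRR"),
            ks=(3,),
            expected={
                "aac.R": 1.0,
                "hydrophobicity.content.g1": 1.0,
                "hydrophobicity.content.g2": 0.0,
                "hydrophobicity.content.g3": 0.0,
                "hydrophobicity.dist.g1.first": 1 / 5,
                "hydrophobicity.dist.g1.p25": 2 / 5,
                "hydrophobicity.dist.g1.p50": 3 / 5,
                "hydrophobicity.dist.g1.p75": 4 / 5,
                "hydrophobicity.dist.g1.p100": 1.0,
                "hydrophobicity.dist.g2.first": 0.0,
                "hydrophobicity.trans.g1g2": 0.0,
                "cksaap.k3.RR": 1.0,
            },
        ),
        WorkedExample(
            # R in group I, G in group II; one I<->II adjacency, L=2
            ProteinSequence("pair_RG", "RG"),
            ks=(),
            expected={
                "hydrophobicity.content.g1": 0.5,
                "hydrophobicity.content.g2": 0.5,
                "hydrophobicity.content.g3": 0.0,
                "hydrophobicity.trans.g1g2": 0.5,
                "hydrophobicity.trans.g1g3": 0.0,
                "hydrophobicity.trans.g2g3": 0.0,
            },
        ),
        WorkedExample(
            ProteinSequence("counts_AACD", "AACD"),
            ks=(),
            expected={"aac.A": 0.5, "aac.C": 0.25, "aac.D": 0.25, "aac.E": 0.0},
        ),
    ]
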