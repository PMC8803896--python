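"""Class rebalancing by random undersampling of the majority class (RUS).

Antioxidant-protein training sets are imbalanced (roughly one positive
per two negatives); discarding a uniform random subset of the majority
class sharpens the minority-class signal without synthesizing samples.
Only random undersampling is implemented; the operation is a strategy
interface (`row_undersample_indices`) so instance-selection variants
can be plugged in.  Sampling only touches rows, so it applies equally
to raw sequence datasets and encoded feature matrices, and runs before
feature selection in the default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import overload

import numpy as np

from .feature_matrix import FeatureMatrix
from .sequence_io import LabeledDataset, NEGATIVE, POSITIVE


@dataclass(frozen=True)
class SamplingConfig:
    """target_ratio = majority/minority count after sampling (default 1:1)."""

    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be > 0")


def row_undersample_indices(
    labels01: np.ndarray, config: SamplingConfig
) -> np.ndarray:
    """Row indices to keep, in original order.

    The minority class is untouched; the majority class is subsampled
    without replacement down to round(target_ratio x minority count).
    If the majority is already at or below target, all rows are kept.
    """
    labels01 = np.asarray(labels01)
    n_pos = int((labels01 == 1).sum())
    n_neg = int((labels01 == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if n_pos <= n_neg:
        minority, majority, n_min, n_maj = 1, 0, n_pos, n_neg
    else:
        minority, majority, n_min, n_maj = 0, 1, n_neg, n_pos

    target = int(np.floor(config.target_ratio * n_min + 0.5))
    if target == 0:
        raise ValueError("target_ratio implies zero majority samples")
    if n_maj <= target:
        return np.arange(len(labels01))

    maj_idx = np.flatnonzero(labels01 == majority)
    rng = np.random.default_rng(config.seed)
    kept_maj = rng.choice(maj_idx, size=target, replace=False)
    keep = np.concatenate([np.flatnonzero(labels01 == minority), kept_maj])
    return np.sort(keep)


@overload
def random_undersample(
    data: LabeledDataset, config: SamplingConfig
) -> LabeledDataset: ...
@overload
def random_undersample(
    data: FeatureMatrix, config: SamplingConfig
) -> FeatureMatrix: ...


def random_undersample(data, config: SamplingConfig = SamplingConfig()):
    """Undersample a LabeledDataset or labeled FeatureMatrix."""
    if isinstance(data, LabeledDataset):
        labels01 = np.array([1 if l == POSITIVE else 0 for l in data.labels])
        keep = row_undersample_indices(labels01, config)
        return data.subset(keep)
    if isinstance(data, FeatureMatrix):
        if data.y is None:
            raise ValueError("feature matrix must be labeled")
        keep = row_undersample_indices(data.y.to_numpy(), config)
        return data.subset_rows(keep)
    raise TypeError(f"cannot undersample {type(data).__name__}")
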