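"""The FeatureMatrix: named feature columns x sample rows, optional labels.

This is the lingua franca between pipeline stages.  On disk it is a CSV
with an ``id`` first column, one named column per feature, and (when
labeled) a ``label`` column with values positive/negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sequence_io import NEGATIVE, POSITIVE


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # index = sample ids, columns = feature names
    y: pd.Series | None = None  # 1 = positive, 0 = negative, aligned to X

    def __post_init__(self) -> None:
        if self.X.index.has_duplicates:
            raise ValueError("duplicate sample ids in feature matrix")
        if self.y is not None:
            if not self.y.index.equals(self.X.index):
                raise ValueError("labels not aligned with feature rows")
            bad = set(self.y.unique()) - {0, 1}
            if bad:
                raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_rows(self, indices: Iterable[int]) -> "FeatureMatrix":
        idx = list(indices)
        y = None if self.y is None else self.y.iloc[idx]
        return FeatureMatrix(self.X.iloc[idx], y)

    def subset_features(self, names: list[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureMatrix(self.X[names], self.y)

    def class_counts(self) -> dict[str, int]:
        if self.y is None:
            raise ValueError("feature matrix is unlabeled")
        return {
            POSITIVE: int((self.y == 1).sum()),
            NEGATIVE: int((self.y == 0).sum()),
        }

    def to_csv(self, path: str | Path) -> None:
        df = self.X.copy()
        if self.y is not None:
            df["label"] = np.where(self.y == 1, POSITIVE, NEGATIVE)
        df.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        y = None
        if "label" in df.columns:
            lab = df.pop("label").astype(str).str.strip().str.lower()
            bad = set(lab.unique()) - {POSITIVE, NEGATIVE}
            if bad:
                raise ValueError(f"unknown labels: {sorted(bad)}")
            y = (lab == POSITIVE).astype(int)
        return cls(df, y)
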