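"""Max-Relevance-Max-Distance (MRMD) feature ranking and subset selection.

Each feature i gets a score MR_i + MD_i:

* MR_i (max-relevance) is the absolute Pearson correlation between the
  feature column and the binary class vector (positive = 1).
* MD_i (max-distance) is the mean distance between feature i's column
  and every other feature column, using Euclidean distance, cosine
  distance (1 - cosine similarity), Tanimoto distance
  (1 - x.y / (|x|^2 + |y|^2 - x.y)), or the mean of the three.

Columns are min-max scaled to [0, 1] before distance computation so the
Euclidean term is not dominated by large-magnitude features and MR and
MD are added on comparable scales (a switch disables this for
comparison with unscaled variants).

Features are ranked by descending score; prefix subsets of the ranking
are then scored by stratified cross-validated accuracy, and the
smallest prefix attaining the maximum accuracy is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .feature_matrix import FeatureMatrix

DistanceMethod = Literal["euclidean", "cosine", "tanimoto", "mean"]


@dataclass
class MRMDRanking:
    """Per-feature relevance/distance/score table, sorted by rank."""

    table: pd.DataFrame  # columns: name, mr, md, score, rank
    distance_method: str

    @property
    def ordered_names(self) -> list[str]:
        return list(self.table["name"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class SubsetSelection:
    ranking: MRMDRanking
    sizes: list[int]
    accuracies: list[float]
    chosen_size: int
    chosen_features: list[str] = field(repr=False)


def _require_labels(matrix: FeatureMatrix) -> np.ndarray:
    if matrix.y is None:
        raise ValueError("MRMD needs a labeled feature matrix")
    y = matrix.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def max_relevance(matrix: FeatureMatrix) -> np.ndarray:
    """|Pearson correlation| of each feature with the class vector.

    Zero-variance features get MR = 0.
    """
    y = _require_labels(matrix)
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.X.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def _pairwise_distances(X: np.ndarray, method: str) -> np.ndarray:
    """Feature-to-feature distance matrix over scaled columns."""
    G = X.T @ X  # gram matrix of columns
    sq = np.diag(G).copy()
    norms = np.sqrt(sq)
    zero = norms == 0

    d_eu = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        cos_sim = G / (norms[:, None] * norms[None, :])
        tani_sim = G / (sq[:, None] + sq[None, :] - G)
    # zero vectors: similarity 0 against non-zero peers, identical to each other
    for sim in (cos_sim, tani_sim):
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        sim[np.ix_(zero, zero)] = 1.0
    d_cos = 1.0 - cos_sim
    d_tan = 1.0 - tani_sim

    if method == "euclidean":
        return d_eu
    if method == "cosine":
        return d_cos
    if method == "tanimoto":
        return d_tan
    if method == "mean":
        return (d_eu + d_cos + d_tan) / 3.0
    raise ValueError(f"unknown distance method {method!r}")


def max_distance(
    matrix: FeatureMatrix, method: DistanceMethod = "mean", scale: bool = True
) -> np.ndarray:
    """Mean distance from each feature column to every other column."""
    X = matrix.X.to_numpy(dtype=float)
    n_feat = X.shape[1]
    if n_feat < 2:
        return np.zeros(n_feat)
    if scale:
        X = _minmax_scale(X)
    D = _pairwise_distances(X, method)
    np.fill_diagonal(D, 0.0)
    return D.sum(axis=1) / (n_feat - 1)


def rank_features(
    matrix: FeatureMatrix, method: DistanceMethod = "mean", scale: bool = True
) -> MRMDRanking:
    """Score = MR + MD, descending; ties broken by MR then column order."""
    mr = max_relevance(matrix)
    md = max_distance(matrix, method, scale)
    score = mr + md
    names = matrix.feature_names
    order = sorted(range(len(names)), key=lambda i: (-score[i], -mr[i], i))
    table = pd.DataFrame(
        {
            "name": [names[i] for i in order],
            "mr": mr[order],
            "md": md[order],
            "score": score[order],
            "rank": np.arange(1, len(names) + 1),
        }
    )
    return MRMDRanking(table, method)


def default_step(n_features: int) -> int:
    """Prefix-size increment: exhaustive below 100 features, else 5."""
    return 1 if n_features < 100 else 5


def select_subset(
    ranking: MRMDRanking,
    matrix: FeatureMatrix,
    folds: int = 5,
    seed: int = 0,
    step: int | None = None,
    n_trees: int = 100,
) -> SubsetSelection:
    """Pick the smallest ranking prefix with maximal CV accuracy.

    Prefixes of sizes step, 2*step, ... (and always the full set) are
    scored by pooled out-of-fold accuracy of the pipeline's random
    forest under stratified k-fold CV with a fixed seed.
    """
    y = _require_labels(matrix)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if matrix.n_samples < folds:
        raise ValueError("fewer samples than folds")
    n_feat = len(ranking.ordered_names)
    if step is None:
        step = default_step(n_feat)
    if step < 1:
        raise ValueError("step must be positive")

    sizes = list(range(step, n_feat + 1, step))
    if not sizes or sizes[-1] != n_feat:
        sizes.append(n_feat)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(matrix.X, y))
    X_ordered = matrix.X[ranking.ordered_names].to_numpy(dtype=float)

    accuracies: list[float] = []
    for size in sizes:
        Xs = X_ordered[:, :size]
        correct = 0
        for train_idx, test_idx in splits:
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            clf.fit(Xs[train_idx], y[train_idx])
            correct += int((clf.predict(Xs[test_idx]) == y[test_idx]).sum())
        accuracies.append(correct / len(y))

    best = max(accuracies)
    chosen_size = min(s for s, a in zip(sizes, accuracies) if a == best)
    return SubsetSelection(
        ranking=ranking,
        sizes=sizes,
        accuracies=accuracies,
        chosen_size=chosen_size,
        chosen_features=ranking.ordered_names[:chosen_size],
    )
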