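"""Random-forest classification and the binary evaluation suite.

The classifier is an ensemble of decision trees; a sequence's score is
the fraction of trees voting positive, and the label is positive when
the score clears the decision threshold (default 0.5, ties positive —
the convention that maximizes sensitivity).

Metrics follow the standard confusion-matrix definitions:

    SN  = TP / (TP + FN)                      (sensitivity / recall)
    SP  = TN / (TN + FP)                      (specificity)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

with any zero denominator mapped to 0 and flagged.  AUC is the area
under the ROC curve (x = 1-SP, y = SN over all score thresholds),
identical to the tie-corrected Mann-Whitney pairwise statistic.

Cross-validation is stratified k-fold (default 5); metrics are computed
once on the pooled out-of-fold scores rather than averaged per fold,
which avoids the small-fold bias of averaging MCC and AUC (a per-fold
report is available for comparison).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .feature_matrix import FeatureMatrix
from .sequence_io import NEGATIVE, POSITIVE

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    counts: ConfusionCounts
    degenerate: list[str] = field(default_factory=list)  # zero-denominator flags

    def to_dict(self) -> dict[str, Any]:
        return {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "counts": asdict(self.counts),
            "degenerate": self.degenerate,
        }

    def to_json(self, path: str | Path, config: dict | None = None) -> None:
        payload = self.to_dict()
        if config is not None:
            payload["config"] = config
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, list[str]]:
    """SN, SP, ACC, MCC from counts; zero denominators give 0 and a flag."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sn = ratio(tp, tp + fn, "sn")
    sp = ratio(tn, tn + fp, "sp")
    acc = ratio(tp + tn, counts.total, "acc")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc, flags


def roc_auc(scores: Sequence[float], labels01: Sequence[int]) -> float:
    """Area under the ROC curve; requires both classes."""
    y = np.asarray(labels01)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def metrics_report(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full report from labels and scores (label = positive iff score >= threshold)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    sn, sp, acc, mcc, flags = confusion_metrics(counts)
    return MetricsReport(sn, sp, acc, mcc, roc_auc(scores, y_true), counts, flags)


@dataclass
class TrainedModel:
    """A fitted forest plus the feature-name contract and provenance."""

    classifier: RandomForestClassifier
    feature_names: list[str]
    n_trees: int
    seed: int
    threshold: float = 0.5
    provenance: dict[str, Any] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "classifier": self.classifier,
                "feature_names": self.feature_names,
                "n_trees": self.n_trees,
                "seed": self.seed,
                "threshold": self.threshold,
                "provenance": self.provenance,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        version = blob.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {version!r} != {MODEL_FORMAT_VERSION}"
            )
        return cls(
            classifier=blob["classifier"],
            feature_names=blob["feature_names"],
            n_trees=blob["n_trees"],
            seed=blob["seed"],
            threshold=blob["threshold"],
            provenance=blob["provenance"],
        )


def _require_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def train(
    matrix: FeatureMatrix,
    n_trees: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
    provenance: dict[str, Any] | None = None,
) -> TrainedModel:
    """Fit the random forest; deterministic under a fixed seed."""
    if matrix.y is None:
        raise ValueError("training needs a labeled feature matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    y = matrix.y.to_numpy()
    _require_two_classes(y)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(matrix.X.to_numpy(dtype=float), y)
    return TrainedModel(
        classifier=clf,
        feature_names=matrix.feature_names,
        n_trees=n_trees,
        seed=seed,
        threshold=threshold,
        provenance=provenance or {},
    )


def predict_score(model: TrainedModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Scores and labels for a probe matrix, sorted descending by score.

    The matrix's feature names must match the model's contract exactly
    (order-insensitive; columns are realigned).
    """
    have = set(matrix.feature_names)
    want = set(model.feature_names)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(
            f"feature-name mismatch: missing {missing[:5]}, extra {extra[:5]}"
        )
    X = matrix.X[model.feature_names].to_numpy(dtype=float)
    pos_col = int(np.flatnonzero(model.classifier.classes_ == 1)[0])
    scores = model.classifier.predict_proba(X)[:, pos_col]
    out = pd.DataFrame(
        {
            "id": matrix.X.index,
            "score": scores,
            "label": np.where(scores >= model.threshold, POSITIVE, NEGATIVE),
        }
    )
    return out.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )


def cross_validate(
    matrix: FeatureMatrix,
    folds: int = 5,
    n_trees: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
    per_fold: bool = False,
) -> MetricsReport | tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold CV; one report on the pooled out-of-fold scores."""
    if matrix.y is None:
        raise ValueError("cross-validation needs labels")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = matrix.y.to_numpy()
    _require_two_classes(y)
    if min(np.bincount(y)) < folds:
        raise ValueError("smallest class has fewer members than folds")

    X = matrix.X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_scores = np.empty(len(y), dtype=float)
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        fold_scores = clf.predict_proba(X[test_idx])[:, pos_col]
        oof_scores[test_idx] = fold_scores
        if per_fold:
            fold_reports.append(metrics_report(y[test_idx], fold_scores, threshold))

    pooled = metrics_report(y, oof_scores, threshold)
    if per_fold:
        return pooled, fold_reports
    return pooled
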