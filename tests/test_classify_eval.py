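"""Random-forest training, scoring, and the metric suite."""

import math

import numpy as np
import pandas as pd
import pytest

from aoxpred.classify_eval import (
    ConfusionCounts,
    TrainedModel,
    confusion_metrics,
    cross_validate,
    metrics_report,
    predict_score,
    roc_auc,
    train,
)
from aoxpred.feature_matrix import FeatureMatrix
from conftest import brute_auc, brute_confusion_metrics


def make_matrix(X, y=None, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names,
                      index=pd.Index([f"s{i}" for i in range(len(X))], name="id"))
    ys = None if y is None else pd.Series(np.asarray(y), index=df.index)
    return FeatureMatrix(df, ys)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        sn, sp, acc, mcc, flags = confusion_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (sn, sp, acc, mcc) == (1, 1, 1, 1) and not flags

    def test_chance_performance(self):
        sn, sp, acc, mcc, _ = confusion_metrics(ConfusionCounts(5, 5, 5, 5))
        assert (sn, sp, acc, mcc) == (0.5, 0.5, 0.5, 0.0)

    def test_hand_evaluated_mcc(self):
        """TP=9, FN=1, TN=8, FP=2: MCC = (72-2)/sqrt(10*11*10*9) = 70/sqrt(9900)."""
        _, _, _, mcc, _ = confusion_metrics(ConfusionCounts(tp=9, fp=2, tn=8, fn=1))
        assert mcc == pytest.approx(70 / math.sqrt(9900), abs=1e-12)

    def test_zero_denominator_convention(self):
        sn, sp, acc, mcc, flags = confusion_metrics(ConfusionCounts(0, 0, 10, 0))
        assert sn == 0.0 and mcc == 0.0
        assert "sn" in flags and "mcc" in flags

    def test_fuzzed_against_independent_rederivation(self, rng):
        """SN/SP/ACC/MCC recomputed from raw (label, prediction) pairs."""
        for _ in range(200):
            n = int(rng.integers(1, 60))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            counts = ConfusionCounts.from_predictions(y, p)
            assert counts.total == n
            sn, sp, acc, mcc, _ = confusion_metrics(counts)
            sn_o, sp_o, acc_o, mcc_o = brute_confusion_metrics(list(zip(y, p)))
            assert (sn, sp, acc) == pytest.approx((sn_o, sp_o, acc_o), abs=1e-12)
            assert mcc == pytest.approx(mcc_o, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_uninformative_scores(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_counted_pairs(self):
        """Four samples, one discordant of four pos/neg pairs: AUC 0.75."""
        assert roc_auc([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.4, 0.6], [1, 1])

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc(scores, y) == pytest.approx(brute_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(3 * s), y), abs=1e-12)


class TestMetricsReport:
    def test_accuracy_identity(self, rng):
        """ACC = (SN*P + SP*N) / (P + N) holds for every report."""
        for _ in range(20):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            scores = rng.random(n)
            rep = metrics_report(y, scores)
            P, N = int((y == 1).sum()), int((y == 0).sum())
            assert rep.acc == pytest.approx((rep.sn * P + rep.sp * N) / (P + N),
                                            abs=1e-12)

    def test_threshold_tie_is_positive(self):
        rep = metrics_report(np.array([1, 0]), np.array([0.5, 0.2]), threshold=0.5)
        assert rep.counts.tp == 1 and rep.counts.fn == 0


def _separable(n=40, n_feat=4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.random((n, n_feat))
    X[:, 0] = y + 0.1 * rng.random(n)
    return make_matrix(X, y)


class TestTrainPredict:
    def test_memorizes_separable_data(self):
        m = _separable()
        model = train(m, n_trees=25, seed=0)
        report = predict_score(model, FeatureMatrix(m.X))
        scored = report.set_index("id").loc[list(m.X.index)]
        y_pred = (scored["label"] == "positive").astype(int).to_numpy()
        assert (y_pred == m.y.to_numpy()).all()

    def test_deterministic_under_seed(self):
        m = _separable()
        probe = FeatureMatrix(m.X.iloc[:10])
        s1 = predict_score(train(m, 50, seed=4), probe)["score"]
        s2 = predict_score(train(m, 50, seed=4), probe)["score"]
        assert (s1 == s2).all()

    def test_single_tree_accepted(self):
        model = train(_separable(), n_trees=1, seed=0)
        assert model.n_trees == 1

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError, match="both classes"):
            train(make_matrix(X, np.ones(10, dtype=int)), 10, 0)

    def test_feature_name_mismatch_rejected(self):
        m = _separable()
        model = train(m, 10, 0)
        probe = FeatureMatrix(m.X.rename(columns={"f0": "other"}))
        with pytest.raises(ValueError, match="feature-name mismatch"):
            predict_score(model, probe)

    def test_report_sorted_descending(self):
        m = _separable()
        report = predict_score(train(m, 20, 0), FeatureMatrix(m.X))
        assert (np.diff(report["score"]) <= 0).all()

    def test_save_load_roundtrip(self, tmp_path):
        m = _separable()
        model = train(m, 15, seed=3, provenance={"features": "combined:3"})
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedModel.load(path)
        probe = FeatureMatrix(m.X)
        pd.testing.assert_frame_equal(
            predict_score(model, probe), predict_score(loaded, probe)
        )
        assert loaded.provenance["features"] == "combined:3"

    def test_version_mismatch_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ValueError, match="format version"):
            TrainedModel.load(path)


class TestCrossValidate:
    def test_separable_data_scores_high(self):
        rep = cross_validate(_separable(n=60), folds=5, n_trees=30, seed=0)
        assert rep.acc > 0.9 and rep.auc > 0.95

    def test_pooled_counts_cover_all_samples(self):
        m = _separable(n=50)
        rep = cross_validate(m, folds=5, n_trees=10, seed=1)
        assert rep.counts.total == 50

    def test_bitwise_reproducible(self):
        m = _separable(n=40)
        a = cross_validate(m, folds=4, n_trees=20, seed=5)
        b = cross_validate(m, folds=4, n_trees=20, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_per_fold_reports(self):
        m = _separable(n=40)
        pooled, folds = cross_validate(m, folds=4, n_trees=10, seed=2, per_fold=True)
        assert len(folds) == 4
        assert sum(r.counts.total for r in folds) == pooled.counts.total

    def test_class_smaller_than_folds_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 2))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer members than folds"):
            cross_validate(make_matrix(X, y), folds=5, n_trees=5, seed=0)
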