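"""Aggregation rule, weighted one-vs-rest metrics, and run evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, recall_score, roc_auc_score

from dlanet.errors import CoverageError, ParameterError
from dlanet.evaluation import (
    aggregate_image_label,
    binarize_detection,
    binary_report,
    confusion,
    evaluate_run,
    roc_auc_binary,
    summarize_folds,
    weighted_metrics,
)
from dlanet.zones import ZONE_NAMES


def zl(*values):
    return dict(zip(ZONE_NAMES, values))


class TestAggregation:
    def test_worked_example(self):
        assert aggregate_image_label(zl(1, 0, 0, 2, 1, 0)) == 2

    def test_all_clear(self):
        assert aggregate_image_label(zl(0, 0, 0, 0, 0, 0)) == 0

    def test_missing_zone(self):
        with pytest.raises(CoverageError):
            aggregate_image_label({"RUZ": 1})

    def test_binarize(self):
        assert binarize_detection(0) == "negative"
        assert binarize_detection(3) == "positive"
        with pytest.raises(ParameterError):
            binarize_detection(4)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = [0, 0, 1, 2, 2, 2]
        cm = confusion(y, y, 3)
        assert np.array_equal(cm, np.diag([2, 1, 3]))

    def test_hand_counted(self):
        cm = confusion([0, 0, 1], [0, 1, 1], 2)
        assert np.array_equal(cm, [[1, 1], [0, 1]])

    def test_total_conservation(self, rng):
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        assert confusion(y_true, y_pred, 4).sum() == 100

    def test_validation(self):
        with pytest.raises(ParameterError):
            confusion([0, 1], [0], 2)
        with pytest.raises(ParameterError):
            confusion([0, 5], [0, 1], 4)


class TestWeightedMetrics:
    def test_perfect_predictions_all_ones(self, rng):
        y = rng.integers(0, 4, 60)
        cm = confusion(y, y, 4)
        probs = np.eye(4)[y] * 0.94 + 0.02
        report = weighted_metrics(cm, probabilities=probs, y_true=y)
        for name in ("acc", "sen", "spe", "f1", "auc"):
            assert getattr(report, name) == pytest.approx(1.0)

    def test_cat2_sensitivity_from_printed_counts(self):
        # 20 true cat-2 images: 9 predicted cat-2, 5 as cat-1, 6 as cat-3
        cm = np.zeros((4, 4), dtype=int)
        cm[2, 2], cm[2, 1], cm[2, 3] = 9, 5, 6
        cm[0, 0], cm[1, 1], cm[3, 3] = 40, 20, 11
        cm[3, 2] = 1  # 11 of 12 cat-3 correct, 1 as cat-2
        report = weighted_metrics(cm)
        assert report.per_class[2]["sen"] == pytest.approx(0.45)
        assert report.per_class[3]["sen"] == pytest.approx(11 / 12)

    def test_two_class_toy_by_hand(self):
        # rows = true, cols = predicted: TP1=20, FN1=10, FP1=5, TN1=50
        cm = np.array([[50, 5], [10, 20]])
        report = weighted_metrics(cm)
        pc1 = report.per_class[1]
        assert pc1["sen"] == pytest.approx(20 / 30)
        assert pc1["spe"] == pytest.approx(50 / 55)
        assert pc1["f1"] == pytest.approx(40 / (40 + 5 + 10))
        assert pc1["acc"] == pytest.approx(70 / 85)
        pc0 = report.per_class[0]
        assert pc0["sen"] == pytest.approx(50 / 55)
        # binary one-vs-rest accuracy coincides for both classes -> ACC == weighted value
        assert report.acc == pytest.approx(70 / 85)

    def test_weighted_recall_equals_multiclass_accuracy(self, rng):
        for _ in range(200):
            cm = rng.integers(0, 30, (4, 4))
            if cm.sum() == 0:
                continue
            report = weighted_metrics(cm)
            assert report.sen == pytest.approx(np.trace(cm) / cm.sum())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=9, max_size=9))
    def test_weighted_metrics_agree_with_sklearn(self, entries):
        cm = np.array(entries).reshape(3, 3)
        if cm.sum() == 0 or (cm.sum(axis=1) == 0).any():
            return
        y_true = np.repeat(np.arange(3), cm.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(3), cm[i]) for i in range(3)])
        report = weighted_metrics(cm)
        assert report.sen == pytest.approx(recall_score(y_true, y_pred, average="weighted"))
        assert report.f1 == pytest.approx(f1_score(y_true, y_pred, average="weighted"))

    def test_zero_zero_cells_defined_as_zero(self, caplog):
        import logging

        cm = np.array([[5, 0], [0, 0]])  # class 1 absent
        with caplog.at_level(logging.WARNING, logger="dlanet.evaluation"):
            report = weighted_metrics(cm)
        assert "0/0" in caplog.text and "zero-support" in caplog.text
        assert report.per_class[1]["sen"] == 0.0
        assert report.sen == pytest.approx(1.0)  # zero-support class has weight 0


class TestAuc:
    def test_rank_auc_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 80)
        scores = rng.random(80)
        assert roc_auc_binary(y, scores) == pytest.approx(roc_auc_score(y, scores))
        # with heavy ties too
        coarse = np.round(scores, 1)
        assert roc_auc_binary(y, coarse) == pytest.approx(roc_auc_score(y, coarse))

    def test_uniform_random_scores_near_half(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 4000)
        auc = roc_auc_binary(y, rng.random(4000))
        assert 0.45 < auc < 0.55

    def test_bounds(self, rng):
        y = np.array([0, 0, 1, 1])
        assert roc_auc_binary(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert roc_auc_binary(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0


def make_predictions(manifest, pred_labels_by_zone, sharpness=0.9):
    """Build one prediction frame per zone with near-one-hot probabilities."""
    frames = {}
    for zone in ZONE_NAMES:
        preds = np.asarray(pred_labels_by_zone[zone], dtype=int)
        probs = np.full((len(preds), 4), (1 - sharpness) / 3)
        probs[np.arange(len(preds)), preds] = sharpness
        frame = pd.DataFrame({"image_id": manifest["image_id"], "zone_name": zone})
        for c in range(4):
            frame[f"p{c}"] = probs[:, c]
        frame["predicted"] = preds
        frames[zone] = frame
    return frames


class TestEvaluateRun:
    def _manifest(self, zone_labels):
        rows = []
        for i, labels in enumerate(zone_labels):
            rows.append({"image_id": f"im{i}", **dict(zip(ZONE_NAMES, labels)),
                         "image_label": max(labels)})
        return pd.DataFrame(rows)

    def test_perfect_zone_predictions_give_perfect_image_metrics(self):
        manifest = self._manifest([(1, 0, 0, 2, 1, 0), (0, 0, 0, 0, 0, 0), (3, 1, 0, 0, 2, 1)])
        preds = make_predictions(manifest, {z: manifest[z] for z in ZONE_NAMES})
        zone_reports, image_report = evaluate_run(preds, manifest)
        assert image_report.acc == pytest.approx(1.0)
        for rep in zone_reports.values():
            assert rep.sen == pytest.approx(1.0)

    def test_single_overpredicting_zone_breaks_image_label(self):
        # five zones correct, one over-predicts the max: the image label is wrong
        manifest = self._manifest([(1, 0, 0, 2, 1, 0)])
        wrong = {z: manifest[z] for z in ZONE_NAMES}
        wrong["RLZ"] = [3]  # true 0, predicted 3 > true image label 2
        _, image_report = evaluate_run(make_predictions(manifest, wrong), manifest)
        assert image_report.sen == pytest.approx(0.0)

    def test_image_id_mismatch_raises(self):
        manifest = self._manifest([(0, 0, 0, 0, 0, 0), (1, 1, 1, 1, 1, 1)])
        preds = make_predictions(manifest, {z: manifest[z] for z in ZONE_NAMES})
        preds["LLZ"] = preds["LLZ"].iloc[:1]
        with pytest.raises(CoverageError):
            evaluate_run(preds, manifest)

    def test_binary_report_detection_identity(self):
        # binary ACC == SEN == weighted values (one-vs-rest coincide for K=2)
        rep = binary_report([0, 0, 1, 2, 3, 0], [0, 1, 1, 2, 0, 0])
        assert rep.acc == pytest.approx(rep.sen)

    def test_summarize_folds_sd_as_percent(self):
        a = binary_report([0, 1], [0, 1])
        b = binary_report([0, 1], [0, 0])
        summary = summarize_folds([a, b])
        assert summary["acc"]["mean"] == pytest.approx((1.0 + 0.5) / 2)
        assert summary["acc"]["sd_pct"] == pytest.approx(25.0)
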