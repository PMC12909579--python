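"""Metric implementations against hand computations, published per-class
tables, and sklearn as an independent oracle."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import matthews_corrcoef as sk_mcc

from stageopt.metrics import (
    ConfusionMatrix,
    accuracy_error,
    aggregate,
    classification_report,
    confusion_matrix,
    mcc_binary,
    mcc_from_marginals,
    mcc_multiclass,
    per_class_metrics,
    reconstruct_marginals,
)

SUPPORTS = (384, 336, 300, 300)

# printed per-class rows of the best tier-2 LightGBM and XGBoost models and
# the best tier-1 CNN (precision, recall per class on the 1320-sample split)
LGBM_PREC = (0.878173, 0.880645, 0.880795, 0.94586)
LGBM_REC = (0.901042, 0.8125, 0.886667, 0.99)
XGB_PREC = (0.844059, 0.852349, 0.824503, 0.917722)
XGB_REC = (0.888021, 0.755952, 0.83, 0.966667)


def random_cm(rng, k=4, high=30):
    return ConfusionMatrix(
        rng.integers(0, high, size=(k, k)), tuple(range(k))
    )


class TestConfusionMatrix:
    def test_by_hand(self):
        cm = confusion_matrix([0, 0, 1], [1, 0, 1], [0, 1])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_identity_diagonal(self):
        cm = confusion_matrix([0, 1], [0, 1], [0, 1])
        assert cm.counts.tolist() == [[1, 0], [0, 1]]

    def test_empty(self):
        cm = confusion_matrix([], [], [0, 1])
        assert cm.counts.sum() == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix([0], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            confusion_matrix([0], [2], [0, 1])

    def test_matches_sklearn(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred, [0, 1, 2, 3])
        assert np.array_equal(
            cm.counts, sk_confusion(y_true, y_pred, labels=[0, 1, 2, 3])
        )


class TestPerClassMetrics:
    @pytest.mark.parametrize(
        "precision,recall,f1",
        [
            (0.424501, 0.776042, 0.548803),  # best CNN, class 0
            (0.878173, 0.901042, 0.889460),  # best CNN-LightGBM, class 0
        ],
    )
    def test_f1_identity_on_published_values(self, precision, recall, f1):
        assert 2 * precision * recall / (precision + recall) == pytest.approx(
            f1, abs=5e-6
        )

    def test_zero_division_convention(self):
        cm = ConfusionMatrix(np.array([[0, 0], [2, 0]]), (0, 1))
        per = per_class_metrics(cm)
        assert per["precision"][0] == 0.0  # TP=0, FP=0
        assert per["recall"][1] == 0.0
        assert per["f1"][1] == 0.0

    def test_against_hand_computation(self):
        cm = ConfusionMatrix(np.array([[5, 2], [1, 4]]), (0, 1))
        per = per_class_metrics(cm)
        assert per["precision"][0] == pytest.approx(5 / 6)
        assert per["recall"][0] == pytest.approx(5 / 7)
        assert per["support"].tolist() == [7, 5]


class TestAccuracyError:
    def test_reconstructed_diagonal(self):
        counts = np.diag([346, 273, 266, 297])
        counts[0, 1] = 1320 - counts.trace()  # park the rest off-diagonal
        cm = ConfusionMatrix(counts, (0, 1, 2, 3))
        acc, err = accuracy_error(cm)
        assert acc == pytest.approx(0.895455, abs=5e-6)
        assert err == pytest.approx(1 - acc)

    def test_perfect_and_worst(self):
        perfect = ConfusionMatrix(np.diag([3, 4]), (0, 1))
        assert accuracy_error(perfect) == (1.0, 0.0)
        worst = ConfusionMatrix(np.array([[0, 5], [5, 0]]), (0, 1))
        assert accuracy_error(worst) == (0.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_error(ConfusionMatrix(np.zeros((2, 2), int), (0, 1)))


class TestMCC:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected", [(1, 1, 0, 0, 1), (0, 0, 1, 1, -1), (5, 5, 5, 5, 0)]
    )
    def test_binary_reference_points(self, tp, tn, fp, fn, expected):
        assert mcc_binary(tp, tn, fp, fn) == pytest.approx(expected)

    def test_binary_zero_denominator(self):
        assert mcc_binary(3, 0, 0, 0) == 0.0

    def test_multiclass_equals_binary_exhaustively(self):
        # all 2x2 matrices with entries <= 6
        for tp, fn, fp, tn in itertools.product(range(7), repeat=4):
            if tp + fn + fp + tn == 0:
                continue
            cm = ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), (0, 1))
            assert mcc_multiclass(cm) == pytest.approx(
                mcc_binary(tp, tn, fp, fn), abs=1e-12
            )

    def test_perfect_and_independent(self):
        assert mcc_multiclass(
            ConfusionMatrix(np.diag([384, 336, 300, 300]), (0, 1, 2, 3))
        ) == pytest.approx(1.0)
        # identical rows: prediction independent of truth
        cm = ConfusionMatrix(np.tile([10, 5, 3, 2], (4, 1)), (0, 1, 2, 3))
        assert mcc_multiclass(cm) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_labels(self, rng):
        for _ in range(25):
            y_true = rng.integers(0, 4, 300)
            y_pred = rng.integers(0, 4, 300)
            cm = confusion_matrix(y_true, y_pred, [0, 1, 2, 3])
            assert mcc_multiclass(cm) == pytest.approx(
                sk_mcc(y_true, y_pred), abs=1e-12
            )

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(200):
            val = mcc_multiclass(random_cm(rng))
            assert -1.0 <= val <= 1.0


class TestAggregate:
    def test_published_macro_weighted(self):
        macro, weighted = aggregate(LGBM_PREC, SUPPORTS)
        assert macro == pytest.approx(0.896368, abs=5e-6)
        assert weighted == pytest.approx(0.894781, abs=5e-6)

    def test_constant_vector(self):
        macro, weighted = aggregate([0.7] * 4, SUPPORTS)
        assert macro == pytest.approx(0.7)
        assert weighted == pytest.approx(0.7)

    def test_positive_supports_required(self):
        with pytest.raises(ValueError):
            aggregate([0.5, 0.5], [10, 0])


class TestReconstruction:
    def test_lgbm_marginals(self):
        diag, cols = reconstruct_marginals(LGBM_PREC, LGBM_REC, SUPPORTS)
        assert diag.tolist() == [346, 273, 266, 297]
        assert cols.tolist() == [394, 310, 302, 314]
        assert cols.sum() == 1320

    def test_xgb_marginals(self):
        diag, cols = reconstruct_marginals(XGB_PREC, XGB_REC, SUPPORTS)
        assert diag.tolist() == [341, 254, 249, 290]
        assert cols.tolist() == [404, 298, 302, 316]

    def test_perfect_prediction(self):
        diag, cols = reconstruct_marginals([1, 1], [1, 1], [10, 20])
        assert diag.tolist() == [10, 20] and cols.tolist() == [10, 20]

    def test_conservation_violation_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_marginals([0.2, 0.2], [1.0, 1.0], [50, 50])

    def test_roundtrip_recovers_marginals(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, size=(4, 4))
            counts += np.diag(rng.integers(5, 40, size=4))  # avoid zero rates
            cm = ConfusionMatrix(counts, (0, 1, 2, 3))
            per = per_class_metrics(cm)
            diag, cols = reconstruct_marginals(
                per["precision"], per["recall"], per["support"]
            )
            assert np.array_equal(diag, np.diag(cm.counts))
            assert np.array_equal(cols, cm.counts.sum(axis=0))

    def test_published_mcc_values(self):
        diag, cols = reconstruct_marginals(LGBM_PREC, LGBM_REC, SUPPORTS)
        assert mcc_from_marginals(diag, SUPPORTS, cols) == pytest.approx(
            0.860430, abs=5e-5
        )
        diag, cols = reconstruct_marginals(XGB_PREC, XGB_REC, SUPPORTS)
        assert mcc_from_marginals(diag, SUPPORTS, cols) == pytest.approx(
            0.812047, abs=5e-5
        )


class TestClassificationReport:
    def test_perfect_prediction(self):
        y = np.repeat([0, 1, 2, 3], [384, 336, 300, 300])
        report = classification_report(y, y, [0, 1, 2, 3])
        assert report.accuracy == 1.0 and report.mcc == pytest.approx(1.0)
        assert report.error_rate == 0.0

    def test_constant_prediction(self):
        y = np.repeat([0, 1, 2, 3], [40, 30, 20, 10])
        report = classification_report(y, np.zeros_like(y), [0, 1, 2, 3])
        assert report.weighted_avg["recall"] == pytest.approx(0.4)

    def test_identities_on_random_matrices(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 4, 300)
            y_pred = rng.integers(0, 4, 300)
            r = classification_report(y_true, y_pred, [0, 1, 2, 3])
            assert r.error_rate + r.accuracy == pytest.approx(1.0)
            assert r.weighted_avg["recall"] == pytest.approx(r.accuracy)
            assert -1.0 <= r.mcc <= 1.0

    def test_serialization(self, tmp_path, rng):
        y = rng.integers(0, 4, 100)
        r = classification_report(y, y, [0, 1, 2, 3])
        path = tmp_path / "report.json"
        r.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert set(data) == {
            "per_class", "accuracy", "error_rate", "mcc",
            "macro_avg", "weighted_avg",
        }

    def test_csv_table_layout(self, tmp_path, rng):
        import pandas as pd

        y = rng.integers(0, 4, 120)
        p = rng.integers(0, 4, 120)
        r = classification_report(y, p, [0, 1, 2, 3])
        path = tmp_path / "report.csv"
        r.to_csv(path)
        table = pd.read_csv(path, index_col=0)
        assert list(table.index) == ["precision", "recall", "f1", "support"]
        assert table.loc["recall", "weighted_avg"] == pytest.approx(
            r.accuracy, abs=5e-7
        )
        assert int(table.loc["support", "0"]) == (y == 0).sum()
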