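"""Confusion metrics, ROC/AUC against a pair-count oracle, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgmtnet.evaluation import (ConfusionCounts, aggregate_folds,
                                classification_metrics, confusion_counts,
                                evaluate_segmentation, roc_auc)


def mann_whitney_auc(scores, labels):
    """Brute-force pair counting: fraction of positive/negative pairs
    correctly ordered, ties counted 1/2 (the oracle)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels)
    pos = s[t == 1]
    neg = s[t == 0]
    wins = sum(float(p > n) + 0.5 * float(p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_direct_tally(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1])
        assert c.FP == 0 and c.FN == 0

    def test_all_predicted_positive(self):
        c = confusion_counts([1, 0, 0, 0], [1, 1, 1, 1])
        assert c.TN == 0 and c.FP == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=5, TN=5))
        assert all(v == 1.0 for v in m.values())

    def test_printed_formula_example(self):
        m = classification_metrics(ConfusionCounts(TP=3, TN=4, FP=1, FN=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["recall"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.45 / 1.35)

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning):
            m = classification_metrics(ConfusionCounts(TN=3, FN=2))
        assert m["precision"] == 0.0 and m["f1"] == 0.0

    def test_accuracy_identity(self, rng):
        # accuracy == (recall*P + specificity*N) / (P+N)
        for _ in range(25):
            tp, tn, fp, fn = rng.integers(0, 20, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            c = ConfusionCounts(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn))
            m = classification_metrics(c)
            P, N = tp + fn, tn + fp
            spec = tn / N
            assert m["accuracy"] == pytest.approx(
                (m["recall"] * P + spec * N) / (P + N))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_three_of_four_pairs(self):
        curve, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_label_inversion_symmetry(self, rng):
        s = rng.random(30)
        t = (rng.random(30) > 0.4).astype(int)
        _, auc = roc_auc(s, t)
        _, auc_inv = roc_auc(s, 1 - t)
        assert auc_inv == pytest.approx(1 - auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.5], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 200), st.integers(0, 10_000), st.booleans())
    def test_trapezoid_equals_pair_counting(self, n, seed, with_ties):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = rng.random(n)
        if with_ties:
            scores = np.round(scores, 1)  # force score ties
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                    abs=1e-10)


class TestEvaluateSegmentation:
    def test_exact_match(self):
        m = np.zeros((8, 8))
        m[2:5, 2:5] = 1
        assert evaluate_segmentation(m, m) == pytest.approx(1.0)

    def test_half_overlap(self):
        truth = np.zeros(8)
        truth[:4] = 1
        pred = np.zeros(8)
        pred[2:6] = 0.9
        assert evaluate_segmentation(pred, truth) == pytest.approx(
            2 * 2 / (4 + 4), abs=1e-6)

    def test_both_empty_is_one(self):
        assert evaluate_segmentation(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_monotone_in_correct_pixels(self):
        truth = np.zeros(10)
        truth[:6] = 1
        pred_few = np.zeros(10)
        pred_few[:2] = 1
        pred_more = np.zeros(10)
        pred_more[:4] = 1
        assert (evaluate_segmentation(pred_more, truth)
                > evaluate_segmentation(pred_few, truth))

    def test_thresholding(self):
        truth = np.ones(4)
        pred = np.array([0.6, 0.7, 0.4, 0.2])
        assert evaluate_segmentation(pred, truth, threshold=0.5) == \
            pytest.approx(2 * 2 / (2 + 4), abs=1e-6)


def test_majority_vote_aggregates_slices_per_case():
    from mgmtnet.evaluation import majority_vote

    votes = majority_vote(["a", "a", "a", "b", "b"],
                          [0.9, 0.8, 0.2, 0.4, 0.45])
    assert votes == {"a": "methylated", "b": "unmethylated"}


def test_roc_points_csv(tmp_path):
    import pandas as pd

    curve, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    out = tmp_path / "roc.csv"
    curve.to_csv(out)
    df = pd.read_csv(out)
    assert list(df.columns) == ["threshold", "fpr", "tpr"]
    assert len(df) == len(curve.fpr)


def test_plot_roc_writes_figure(tmp_path):
    from mgmtnet.evaluation import plot_roc

    curve, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    out = tmp_path / "roc.png"
    plot_roc({"testing": (curve, auc)}, path=out)
    assert out.exists() and out.stat().st_size > 0


class TestAggregateFolds:
    def test_formatting(self):
        s, (m, sd) = aggregate_folds([0.8, 0.9])
        assert s == "0.850 ± 0.071"
        assert m == pytest.approx(0.85)
        assert sd == pytest.approx(np.std([0.8, 0.9], ddof=1))

    def test_constant_folds(self):
        s, (_, sd) = aggregate_folds([0.5] * 10)
        assert s == "0.500 ± 0.000" and sd == 0.0

    def test_permutation_invariant(self, rng):
        v = rng.random(10)
        assert aggregate_folds(v)[0] == aggregate_folds(v[::-1])[0]

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            aggregate_folds([0.5])
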