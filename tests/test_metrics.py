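"""Confusion-matrix metrics and rank-based AUC against independent oracles."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from mfscnet.metrics import (
    ConfusionCounts,
    auc_binary,
    auc_macro_ovr,
    classification_metrics,
    confusion_counts,
    evaluate_predictions,
)


def auc_pair_enumeration(scores, truth):
    """Brute-force oracle: count winning and tied positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos, neg = scores[truth], scores[~truth]
    losses = sum(1 for p in pos for n in neg if p < n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return 1.0 - (losses + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_predictions_have_no_errors(self):
        y = np.array(["a", "b", "a", "b"])
        c = confusion_counts(y, y, "a")
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 2)

    def test_all_positive_predictions(self):
        truth = np.array([1] * 5 + [0] * 5)
        c = confusion_counts(np.ones(10, dtype=int), truth, 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 5, 0, 0)

    def test_swapping_positive_class_transposes_counts(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 30)
        truth = rng.integers(0, 2, 30)
        a = confusion_counts(pred, truth, 1)
        b = confusion_counts(pred, truth, 0)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tn, b.fn, b.tp, b.fp)

    def test_length_mismatch_is_fatal(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1], 1)


class TestClassificationMetrics:
    def test_hand_worked_example(self):
        acc, prec, rec, f1 = classification_metrics(ConfusionCounts(3, 1, 4, 2))
        assert acc == 0.7
        assert prec == 0.75
        assert rec == 0.6
        assert np.isclose(f1, 2 / 3)

    def test_perfect_classifier_scores_one_everywhere(self):
        assert classification_metrics(ConfusionCounts(5, 0, 5, 0)) == (1, 1, 1, 1)

    def test_zero_denominators_fall_back_to_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            acc, prec, rec, f1 = classification_metrics(ConfusionCounts(0, 0, 4, 2))
        assert prec == 0.0 and f1 == 0.0
        assert any("convention" in m for m in caplog.messages)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=200)
    def test_formulas_hold_for_arbitrary_tallies(self, tp, fp, tn, fn):
        n = tp + fp + tn + fn
        if n == 0:
            return
        acc, prec, rec, f1 = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert acc == (tp + tn) / n
        assert prec == (tp / (tp + fp) if tp + fp else 0.0)
        assert rec == (tp / (tp + fn) if tp + fn else 0.0)
        assert 0 <= f1 <= 1


class TestAucBinary:
    def test_enumerated_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.2}: 3 winning pairs of 4
        scores = [0.9, 0.4, 0.5, 0.2]
        truth = [1, 1, 0, 0]
        assert auc_binary(scores, truth) == 0.75

    def test_all_tied_scores_give_half(self):
        assert auc_binary([0.3] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_perfect_separation_gives_one(self):
        assert auc_binary([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_truth_is_fatal(self):
        with pytest.raises(ValueError):
            auc_binary([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_matches_pair_enumeration_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        truth = np.zeros(n, dtype=int)
        truth[: int(rng.integers(1, n))] = 1
        rng.shuffle(truth)
        if truth.sum() in (0, n):
            return
        scores = np.round(rng.random(n), 2)  # rounding forces occasional ties
        got = auc_binary(scores, truth)
        assert np.isclose(got, auc_pair_enumeration(scores, truth))
        assert np.isclose(got, roc_auc_score(truth, scores))

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)  # continuous, tie-free
        truth = rng.integers(0, 2, 40)
        assert np.isclose(
            auc_binary(scores, truth) + auc_binary(-scores, truth), 1.0
        )

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=25)
        truth = (rng.random(25) < 0.4).astype(int)
        truth[0], truth[1] = 0, 1
        assert auc_binary(scores, truth) == auc_binary(np.exp(scores), truth)


class TestAucMacroOvr:
    def test_two_class_case_reduces_to_binary(self):
        rng = np.random.default_rng(7)
        scores = rng.random((30, 2))
        truth = rng.integers(0, 2, 30)
        got = auc_macro_ovr(scores, truth)
        a0 = auc_binary(scores[:, 0], truth == 0)
        a1 = auc_binary(scores[:, 1], truth == 1)
        assert np.isclose(got, (a0 + a1) / 2)

    def test_identical_columns_are_uninformative(self):
        col = np.linspace(0, 1, 12)
        scores = np.stack([col, col, col], axis=1)
        truth = np.array([0, 1, 2] * 4)
        assert auc_macro_ovr(scores, truth) == 0.5

    def test_three_class_matches_per_class_enumeration(self):
        rng = np.random.default_rng(8)
        scores = np.round(rng.random((40, 3)), 2)
        truth = rng.integers(0, 3, 40)
        expect = np.mean(
            [auc_pair_enumeration(scores[:, k], truth == k) for k in range(3)]
        )
        assert np.isclose(auc_macro_ovr(scores, truth), expect)

    def test_absent_class_excluded_with_warning(self, caplog):
        scores = np.random.default_rng(9).random((20, 3))
        truth = np.array([0, 1] * 10)  # class 2 never occurs
        with caplog.at_level(logging.WARNING):
            got = auc_macro_ovr(scores, truth, classes=[0, 1, 2])
        expect = (auc_binary(scores[:, 0], truth == 0)
                  + auc_binary(scores[:, 1], truth == 1)) / 2
        assert np.isclose(got, expect)
        assert any("absent" in m for m in caplog.messages)


class TestEvaluatePredictions:
    def test_binary_report_against_hand_counts(self):
        truth = np.array(["benign"] * 6 + ["malignant"] * 4)
        pred = np.array(["benign"] * 5 + ["malignant"] * 5)
        scores = np.stack([1 - np.linspace(0, 1, 10), np.linspace(0, 1, 10)], axis=1)
        rep = evaluate_predictions(truth, pred, scores)
        c = rep.per_class["malignant"]
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 1, 5, 0)
        assert rep.averaging == "binary"
        assert rep.accuracy == 0.9
        assert np.isclose(rep.auc, auc_binary(scores[:, 1], truth == "malignant"))

    def test_macro_report_averages_per_class_metrics(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 1, 1, 1, 2, 0])
        rep = evaluate_predictions(truth, pred)
        per = [classification_metrics(rep.per_class[k]) for k in (0, 1, 2)]
        assert rep.averaging == "macro"
        assert np.isclose(rep.accuracy, 4 / 6)  # overall fraction correct
        assert np.isclose(rep.precision, np.mean([m[1] for m in per]))
        assert np.isclose(rep.f1, np.mean([m[3] for m in per]))

    def test_report_serializes_to_json(self, tmp_path):
        truth = np.array([0, 1, 0, 1])
        rep = evaluate_predictions(truth, truth)
        rep.to_json(tmp_path / "r.json")
        import json

        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["accuracy"] == 1.0
        assert set(loaded["per_class"]) == {"0", "1"}
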