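"""Metric suite vs independent oracles (nested loops, rank statistics)."""

import warnings

import numpy as np
import pytest
from scipy.stats import rankdata

from saxlevel.evaluation import (
    accuracy,
    confusion_matrix,
    evaluate,
    merge_to_three_class,
    one_vs_rest_scores,
    sotd,
    weighted_auc,
)

K = 5


def brute_confusion(t, p):
    cm = np.zeros((K, K), dtype=np.int64)
    for a, b in zip(t, p):
        cm[a, b] += 1
    return cm


def brute_sotd(cm):
    total = 0
    for i in range(K):
        for j in range(K):
            if abs(i - j) >= 2:
                total += int(cm[i, j])
    return total


def mann_whitney_auc(pos_scores, neg_scores):
    """AUC as the normalized Mann-Whitney U statistic with tie correction."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(scores)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusionMatrix:
    def test_matches_brute_force_on_random_labels(self, rng):
        t = rng.integers(0, K, 200)
        p = rng.integers(0, K, 200)
        assert np.array_equal(confusion_matrix(t, p), brute_confusion(t, p))

    def test_perfect_prediction_is_diagonal(self, rng):
        t = rng.integers(0, K, 60)
        cm = confusion_matrix(t, t)
        assert np.array_equal(np.diag(np.diag(cm)), cm)
        assert np.array_equal(np.diag(cm), np.bincount(t, minlength=K))

    def test_empty_input_gives_zero_matrix(self):
        assert confusion_matrix([], []).sum() == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])


class TestOneVsRest:
    def test_perfect_diagonal_scores_one(self):
        cm = np.diag([3, 4, 5, 6, 7])
        for c in range(K):
            assert one_vs_rest_scores(cm, c) == (1.0, 1.0, 1.0)

    def test_direct_formula(self):
        # class 0: TP=3, FP=1, FN=1
        cm = np.zeros((K, K), int)
        cm[0, 0] = 3
        cm[1, 0] = 1
        cm[0, 1] = 1
        cm[1, 1] = 5
        p, r, f1 = one_vs_rest_scores(cm, 0)
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_absent_class_returns_zero_with_warning(self):
        cm = np.zeros((K, K), int)
        cm[1, 1] = 10
        with pytest.warns(RuntimeWarning):
            assert one_vs_rest_scores(cm, 0) == (0.0, 0.0, 0.0)

    def test_matches_formula_on_random_matrices(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 30, (K, K))
            c = int(rng.integers(0, K))
            tp = cm[c, c]
            fp = cm[:, c].sum() - tp
            fn = cm[c, :].sum() - tp
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, r, f1 = one_vs_rest_scores(cm, c)
            if tp + fp:
                assert abs(p - tp / (tp + fp)) < 1e-12
            if tp + fn:
                assert abs(r - tp / (tp + fn)) < 1e-12
            if p + r:
                assert abs(f1 - 2 * p * r / (p + r)) < 1e-12


class TestAccuracy:
    def test_trace_over_total(self):
        assert accuracy(np.ones((K, K), int)) == 5 / 25

    def test_perfect(self):
        assert accuracy(np.diag([1, 2, 3, 4, 5])) == 1.0

    def test_invariant_under_simultaneous_permutation(self, rng):
        cm = rng.integers(0, 20, (K, K))
        perm = rng.permutation(K)
        assert abs(accuracy(cm) - accuracy(cm[np.ix_(perm, perm)])) < 1e-15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((K, K), int))


class TestWeightedAuc:
    def test_perfect_ranking_is_one(self, rng):
        t = rng.integers(0, K, 40)
        probs = np.eye(K)[t] * 0.9 + 0.02
        probs /= probs.sum(axis=1, keepdims=True)
        assert weighted_auc(t, probs) == 1.0

    def test_uninformative_ranking_is_half(self, rng):
        t = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        probs = np.tile(np.full(K, 0.2), (len(t), 1))
        assert abs(weighted_auc(t, probs) - 0.5) < 1e-12

    def test_matches_rank_statistic_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(0, K, 50)
            if len(np.unique(t)) < 2:
                continue
            probs = rng.random((50, K))
            probs /= probs.sum(axis=1, keepdims=True)
            present, support = np.unique(t, return_counts=True)
            expected = np.average(
                [mann_whitney_auc(probs[t == c, c], probs[t != c, c]) for c in present],
                weights=support,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert abs(weighted_auc(t, probs) - expected) < 1e-9

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            weighted_auc([1, 1, 1], np.full((3, K), 0.2))

    def test_absent_class_warns(self):
        t = np.array([0, 0, 1, 1])
        probs = np.full((4, K), 0.2)
        with pytest.warns(RuntimeWarning, match="absent"):
            weighted_auc(t, probs)


class TestSotd:
    def test_diagonal_is_zero(self):
        assert sotd(np.diag([9, 9, 9, 9, 9])) == 0

    def test_tridiagonal_band_is_zero(self, rng):
        cm = np.zeros((K, K), int)
        for i in range(K):
            for j in range(max(0, i - 1), min(K, i + 2)):
                cm[i, j] = int(rng.integers(1, 10))
        assert sotd(cm) == 0

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            cm = rng.integers(0, 50, (K, K))
            assert sotd(cm) == brute_sotd(cm)

    def test_bounded_by_total(self, rng):
        cm = rng.integers(0, 50, (K, K))
        assert 0 <= sotd(cm) <= cm.sum()


class TestMergeToThreeClass:
    def test_perfect_merges_to_zero_error(self):
        _, err = merge_to_three_class(np.diag([5, 5, 5, 5, 5]))
        assert err == 0.0

    def test_intra_in_confusions_vanish(self):
        cm = np.zeros((K, K), int)
        cm[1, 2] = 7
        cm[2, 3] = 3
        cm[3, 1] = 2
        merged, err = merge_to_three_class(cm)
        assert err == 0.0
        assert merged[1, 1] == 12

    def test_matches_relabel_and_recount_oracle(self, rng):
        remap = np.array([0, 1, 1, 1, 2])
        for _ in range(100):
            cm = rng.integers(0, 30, (K, K))
            expected = np.zeros((3, 3), int)
            for i in range(K):
                for j in range(K):
                    expected[remap[i], remap[j]] += cm[i, j]
            merged, err = merge_to_three_class(cm)
            assert np.array_equal(merged, expected)
            assert abs(err - (1 - np.trace(expected) / expected.sum())) < 1e-12

    def test_merged_error_never_exceeds_five_class_error(self, rng):
        for _ in range(100):
            cm = rng.integers(0, 30, (K, K))
            _, merged_err = merge_to_three_class(cm)
            assert merged_err <= 1 - accuracy(cm) + 1e-12


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        t = rng.integers(0, K, 80)
        probs = np.eye(K)[t]
        report = evaluate(t, t, probs)
        assert all(v == 1.0 for v in report.f1.values())
        assert report.auc_weighted == 1.0
        assert report.accuracy == 1.0
        assert report.sotd == 0
        assert report.merged_error_rate == 0.0

    def test_totals_and_supports_conserved(self, rng):
        t = rng.integers(0, K, 123)
        p = rng.integers(0, K, 123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate(t, p)
        assert report.total == 123
        assert report.confusion.sum(axis=1).tolist() == np.bincount(t, minlength=K).tolist()

    def test_report_serializes(self, rng):
        import json

        t = rng.integers(0, K, 40)
        report = evaluate(t, t, np.eye(K)[t])
        parsed = json.loads(report.to_json())
        assert parsed["accuracy"] == 1.0
        assert "confusion" in parsed
        assert report.format_table("demo").startswith("== demo")
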