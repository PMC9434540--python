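"""Verification metrics: thresholding, confusion statistics, ROC/AUC,
bootstrap intervals, subgroup TPR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxreid.cohort import Cohort, ImageRecord
from cxreid.pairs import PairSample, PairSet
from cxreid.verification_eval import (ConfusionCounts, ScoredPairs,
                                      bootstrap_auc_ci, classify,
                                      confusion_metrics, roc_auc,
                                      round_half_up, subgroup_tpr)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise comparison oracle, ties counted half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def scored(scores, labels):
    pairs = PairSet([PairSample(f"a{i}", f"b{i}", int(l))
                     for i, l in enumerate(labels)])
    return ScoredPairs(pairs, np.asarray(scores, dtype=float))


class TestClassify:
    def test_threshold_at_half(self):
        out = classify(scored([0.2, 0.5, 0.9], [0, 1, 1]), 0.5)
        np.testing.assert_array_equal(out, [0, 1, 1])

    def test_tie_counts_positive(self):
        out = classify(scored([0.5, 0.5], [0, 1]), 0.5)
        np.testing.assert_array_equal(out, [1, 1])

    def test_monotone_transform_preserves_labels(self):
        s = np.array([0.1, 0.3, 0.6, 0.8])
        a = classify(scored(s, [0, 0, 1, 1]), 0.5)
        b = classify(scored(s ** 3 / (s ** 3 + (1 - s) ** 3), [0, 0, 1, 1]), 0.5)
        np.testing.assert_array_equal(a, b)


class TestConfusionMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fn=0, tn=20, fp=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominators_reported_as_missing(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert m["recall"] is None and m["precision"] is None and m["f1"] is None
        assert m["accuracy"] == 1.0

    def test_f1_is_harmonic_mean(self):
        m = confusion_metrics(ConfusionCounts(tp=30, fn=10, tn=40, fp=20))
        p, r = m["precision"], m["recall"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_known_small_case(self):
        got = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert got == brute_force_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_independent_library_estimate(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)   # force ties
        labels = np.zeros(n, dtype=int)
        labels[rng.integers(0, n)] = 1                        # >=1 positive
        labels[: max(1, n // 3)] = rng.integers(0, 2, size=max(1, n // 3))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestBootstrap:
    def test_perfect_separation_degenerates_to_unit_interval(self):
        lo, hi = bootstrap_auc_ci([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                                  n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_brackets_point_estimate_on_synthetic_scores(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=300)
        scores = np.clip(labels * 0.3 + rng.normal(0.5, 0.2, size=300), 0, 1)
        auc = roc_auc(scores, labels)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=500, seed=1)
        assert lo <= auc <= hi

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        a = bootstrap_auc_ci(scores, labels, n_boot=200, seed=3)
        b = bootstrap_auc_ci(scores, labels, n_boot=200, seed=3)
        assert a == b


def _cohort_for_subgroups():
    recs = [
        ImageRecord("q0", "pa", 0, 50, "M", "PA", frozenset({"No Finding"})),
        ImageRecord("q1", "pa", 1, 50, "M", "PA", frozenset({"No Finding"})),
        ImageRecord("q2", "pa", 2, 55, "M", "AP", frozenset({"Mass", "Nodule"})),
        ImageRecord("q3", "pb", 0, 60, "F", "PA", frozenset({"No Finding"})),
        ImageRecord("q4", "pb", 1, 66, "F", "PA", frozenset({"Effusion"})),
    ]
    return Cohort(recs)


class TestSubgroupTpr:
    def _scored(self):
        pairs = PairSet([
            PairSample("q0", "q1", 1),   # gap 0
            PairSample("q0", "q2", 1),   # gap 5, new Mass+Nodule, view change
            PairSample("q3", "q4", 1),   # gap 6, new Effusion
            PairSample("q0", "q3", 0),
        ])
        return ScoredPairs(pairs, np.array([0.9, 0.8, 0.2, 0.1]))

    def test_single_bin_equals_overall_recall(self):
        rep = subgroup_tpr(self._scored(), _cohort_for_subgroups(),
                           "age_gap_years", bins=[0, 100])
        assert rep["[0,100)"]["tpr"] == pytest.approx(2 / 3)
        assert rep["[0,100)"]["p"] == 3

    def test_age_gap_binning_counts(self):
        rep = subgroup_tpr(self._scored(), _cohort_for_subgroups(),
                           "age_gap_years", bins=[0, 1, 6, 13])
        assert rep["[0,1)"] == {"tpr": 1.0, "tp": 1, "p": 1}
        assert rep["[1,6)"] == {"tpr": 1.0, "tp": 1, "p": 1}
        assert rep["[6,13)"] == {"tpr": 0.0, "tp": 0, "p": 1}

    def test_multi_finding_pair_contributes_to_each_new_label(self):
        rep = subgroup_tpr(self._scored(), _cohort_for_subgroups(), "disease_change")
        assert rep["Mass"]["p"] == 1 and rep["Nodule"]["p"] == 1
        assert rep["Effusion"] == {"tpr": 0.0, "tp": 0, "p": 1}

    def test_view_change_partition(self):
        rep = subgroup_tpr(self._scored(), _cohort_for_subgroups(), "view_change")
        assert rep["changed"]["p"] == 1 and rep["same"]["p"] == 2


class TestRocCurve:
    def test_trapezoid_over_curve_equals_rank_auc(self):
        from cxreid.verification_eval import roc_curve_points
        rng = np.random.default_rng(9)
        scores = rng.choice(np.linspace(0, 1, 9), size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        pts = roc_curve_points(scores, labels)
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert area == pytest.approx(roc_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints(self):
        from cxreid.verification_eval import roc_curve_points
        pts = roc_curve_points([0.1, 0.9], [0, 1])
        assert (pts.iloc[0]["fpr"], pts.iloc[0]["tpr"]) == (0.0, 0.0)
        assert (pts.iloc[-1]["fpr"], pts.iloc[-1]["tpr"]) == (1.0, 1.0)


class TestRounding:
    def test_half_up_matches_printed_convention(self):
        assert round_half_up(0.95545) == 0.9555
        assert round_half_up(0.98222) == 0.9822
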