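"""Metrics, cross-validation and Mann-Whitney comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seqppi as sp
from seqppi.evaluation import PerformanceReport, cross_validate, compare_feature_sets


class TestPrecisionRecall:
    def test_hand_computed(self):
        p, r = sp.precision_recall(tp=8, fp=2, fn=2)
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(0.8)

    def test_undefined_flagged_as_none(self):
        p, r = sp.precision_recall(tp=0, fp=0, fn=3)
        assert p is None
        assert r == 0.0

    def test_written_2x2_table(self):
        # 2x2 table: predicted+/actual+ 6, predicted+/actual- 3, predicted-/actual+ 1
        p, r = sp.precision_recall(tp=6, fp=3, fn=1)
        assert p == pytest.approx(6 / 9)
        assert r == pytest.approx(6 / 7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sp.precision_recall(-1, 0, 0)


def brute_auc(scores, labels):
    """O(n^2) concordance count: positives beating negatives, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == "PPI"]
    neg = [s for s, l in zip(scores, labels) if l == "no-PPI"]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert sp.auc([0.9, 0.8, 0.2, 0.1], ["PPI", "PPI", "no-PPI", "no-PPI"]) == 1.0

    def test_pairwise_count_example(self):
        assert sp.auc([0.9, 0.8, 0.4, 0.3], ["PPI", "no-PPI", "PPI", "no-PPI"]) == 0.75

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            sp.auc([0.5, 0.6], ["PPI", "PPI"])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = np.where(rng.random(4000) < 0.5, "PPI", "no-PPI")
        assert sp.auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @settings(deadline=None, max_examples=60)
    @given(
        scores=st.lists(st.floats(0, 1, width=16), min_size=4, max_size=200),
        cut=st.integers(1, 10),
    )
    def test_matches_brute_force_concordance(self, scores, cut):
        n = len(scores)
        k = max(1, min(n - 1, n * cut // 11))
        labels = ["PPI"] * k + ["no-PPI"] * (n - k)
        assert sp.auc(scores, labels) == pytest.approx(brute_auc(scores, labels))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.random(500)
        y = rng.integers(0, 2, 500)
        labels = np.where(y == 1, "PPI", "no-PPI")
        assert sp.auc(scores, labels) == pytest.approx(roc_auc_score(y, scores))


class TestCrossValidate:
    def test_fold_sizes_and_conservation(self, fp_schema, planted_encoded):
        report = cross_validate(planted_encoded, fp_schema, k=10, n_bags=3, seed=0)
        assert report.n_folds == 10
        # pooled confusion covers every instance exactly once: with noise-free
        # planted data all metrics are defined and perfect
        assert report.auc == pytest.approx(1.0)
        assert report.precision_ppi == 1.0 and report.recall_ppi == 1.0

    def test_folds_of_2780_are_278(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.array(["PPI"] * 1390 + ["no-PPI"] * 1390)
        folds = list(
            StratifiedKFold(n_splits=10, shuffle=True, random_state=0).split(
                np.zeros(2780), labels
            )
        )
        assert all(len(test) == 278 for _, test in folds)

    def test_stratified_folds_balanced_within_one(self, fp_schema, planted_encoded):
        from sklearn.model_selection import StratifiedKFold

        labels = planted_encoded["label"].to_numpy()
        for _, test in StratifiedKFold(n_splits=10, shuffle=True, random_state=1).split(
            np.zeros(len(labels)), labels
        ):
            counts = pd.Series(labels[test]).value_counts()
            assert abs(counts["PPI"] - counts["no-PPI"]) <= 1

    def test_seed_determinism(self, fp_schema, planted_encoded):
        a = cross_validate(planted_encoded, fp_schema, k=5, n_bags=2, seed=4)
        b = cross_validate(planted_encoded, fp_schema, k=5, n_bags=2, seed=4)
        assert a == b

    def test_small_class_suggests_smaller_k(self, fp_schema, planted_encoded):
        # 15 positives but only 5 negatives: the minority class cannot stratify
        tiny = pd.concat(
            [planted_encoded.head(15), planted_encoded.tail(5)], ignore_index=True
        )
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(tiny, fp_schema, k=10)


def brute_mann_whitney_p(a, b):
    """Exact two-sided p by enumerating all label assignments (tie-free)."""
    combined = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a_vals, group_b_vals):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in group_a_vals
            for y in group_b_vals
        )

    observed = u_stat(a, b)
    n_ab = n_a * len(b)
    us = []
    for idx in itertools.combinations(range(len(combined)), n_a):
        ga = [combined[i] for i in idx]
        gb = [combined[i] for i in range(len(combined)) if i not in idx]
        us.append(u_stat(ga, gb))
    # symmetric null: two-sided p as the tail probability of |U - nm/2|
    dev = abs(observed - n_ab / 2)
    return sum(1 for u in us if abs(u - n_ab / 2) >= dev - 1e-12) / len(us)


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        _, p = sp.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_complete_separation_u_zero(self):
        u, _ = sp.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ((1.0, 2.0, 3.0), (4.0, 5.0, 6.0)),
            ((1.0, 5.0, 2.5), (3.0, 4.0)),
            ((10.0, 20.0, 30.0, 40.0), (15.0, 25.0)),
        ],
    )
    def test_small_groups_match_exact_enumeration(self, a, b):
        _, p = sp.mann_whitney_u(a, b)
        assert p == pytest.approx(brute_mann_whitney_p(a, b))

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.lists(st.floats(0, 1, width=16), min_size=2, max_size=12),
        b=st.lists(st.floats(0, 1, width=16), min_size=2, max_size=12),
    )
    def test_symmetry(self, a, b):
        u_ab, p_ab = sp.mann_whitney_u(a, b)
        u_ba, p_ba = sp.mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)


def _report(i, **metrics):
    defaults = dict(
        precision_ppi=0.8, recall_ppi=0.8, precision_no_ppi=0.8, recall_no_ppi=0.8,
        auc=0.85,
    )
    defaults.update(metrics)
    return PerformanceReport(dataset_id=f"d{i}", n_folds=10, seed=0, **defaults)


class TestCompareFeatureSets:
    def test_identical_sets_nonsignificant(self):
        rng = np.random.default_rng(0)
        values = rng.random(10) * 0.2 + 0.7
        reports = {
            tag: [_report(i, auc=v, precision_ppi=v, recall_ppi=v,
                          precision_no_ppi=v, recall_no_ppi=v)
                  for i, v in enumerate(values)]
            for tag in ("F", "Fp")
        }
        table = compare_feature_sets(reports)
        assert not table["significant"].any()

    def test_disjoint_ranges_significant(self):
        rng = np.random.default_rng(1)
        lo, hi = rng.random(12) * 0.1 + 0.5, rng.random(12) * 0.1 + 0.85
        reports = {
            "C": [_report(i, auc=v, precision_ppi=v, recall_ppi=v,
                          precision_no_ppi=v, recall_no_ppi=v) for i, v in enumerate(lo)],
            "F": [_report(i, auc=v, precision_ppi=v, recall_ppi=v,
                          precision_no_ppi=v, recall_no_ppi=v) for i, v in enumerate(hi)],
        }
        table = compare_feature_sets(reports)
        assert table["significant"].all()
        assert set(table["higher_median"]) == {"F"}

    def test_row_count_pairs_times_metrics_times_classes(self):
        reports = {tag: [_report(i) for i in range(5)] for tag in ("F", "Fp", "C")}
        table = compare_feature_sets(reports)
        assert len(table) == 3 * 3 * 2  # pairs x {precision, recall, AUC} x classes

    def test_single_schema_rejected(self):
        with pytest.raises(ValueError):
            compare_feature_sets({"F": [_report(0)]})
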