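"""Gain-ratio trees, bagging, combination and the 0.50 decision rule."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seqppi as sp
from seqppi.tree_learner import (
    Node,
    DecisionTree,
    dataset_to_matrix,
    level2_attributes,
    tree_synthesis,
    _added_errors,
)


# -- independent brute-force oracle for entropy / gain ratio -----------------

def brute_entropy(items):
    n = len(items)
    return -sum((c / n) * math.log2(c / n) for c in Counter(items).values())


def brute_gain_ratio(values, labels):
    n = len(labels)
    parent = brute_entropy(labels)
    groups = {}
    for v, l in zip(values, labels):
        groups.setdefault(v, []).append(l)
    cond = sum(len(g) / n * brute_entropy(g) for g in groups.values())
    gain = parent - cond
    split_info = brute_entropy(values)
    if gain <= 1e-12 or split_info <= 1e-12:
        return 0.0
    return gain / split_info


class TestClassEntropy:
    def test_balanced_binary_is_one_bit(self):
        assert sp.class_entropy((5, 5)) == pytest.approx(1.0)

    def test_pure_is_zero(self):
        assert sp.class_entropy((10, 0)) == 0.0

    def test_closed_form_3_1(self):
        assert sp.class_entropy((3, 1)) == pytest.approx(0.8112781244591328)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            sp.class_entropy((0, 0))


class TestGainRatio:
    def test_constant_attribute_is_zero(self):
        assert sp.gain_ratio(["x"] * 6, ["P", "N"] * 3) == 0.0

    def test_perfect_equiprobable_split_is_one(self):
        assert sp.gain_ratio(["x", "x", "y", "y"], ["P", "P", "N", "N"]) == pytest.approx(1.0)

    def test_eight_instance_worked_table(self):
        values = ["a", "a", "a", "b", "b", "b", "c", "c"]
        labels = ["P", "P", "N", "P", "N", "N", "N", "N"]
        assert sp.gain_ratio(values, labels) == pytest.approx(
            brute_gain_ratio(values, labels)
        )

    @settings(deadline=None, max_examples=200)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from("abcd"),
                st.sampled_from("ef"),
                st.sampled_from("ghi"),
                st.sampled_from("PN"),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_brute_force_on_small_tables(self, data):
        """Exhaustive-entropy oracle over datasets of <= 12 instances x 3 attributes."""
        labels = [row[-1] for row in data]
        for a in range(3):
            values = [row[a] for row in data]
            assert sp.gain_ratio(values, labels) == pytest.approx(
                brute_gain_ratio(values, labels), abs=1e-12
            )


class TestAddedErrors:
    def test_zero_errors_bound(self):
        # all-correct leaf of 10: N(1 - CF^(1/N))
        assert _added_errors(10, 0, 0.25) == pytest.approx(10 * (1 - 0.25 ** 0.1))

    def test_bound_positive_and_below_n(self):
        for n, e in [(10, 2), (50, 5), (100, 40)]:
            extra = _added_errors(n, e, 0.25)
            assert 0 < extra < n - e + 1


class TestGrowTree:
    def test_pure_input_single_leaf(self, fp_schema, planted_encoded):
        pure = planted_encoded[planted_encoded["label"] == "PPI"].reset_index(drop=True)
        tree = sp.grow_tree(pure, fp_schema)
        assert tree.root.is_leaf
        assert tree.root.proba_ppi == 1.0
        assert sp.root_attribute(tree) is None

    def test_planted_attribute_is_root(self, fp_schema, planted_encoded):
        tree = sp.grow_tree(planted_encoded, fp_schema)
        assert sp.root_attribute(tree) == "N~N"

    def test_noise_free_training_accuracy_is_one(self, fp_schema, planted_encoded):
        tree = sp.grow_tree(planted_encoded, fp_schema)
        X, y = dataset_to_matrix(planted_encoded, fp_schema)
        pred = tree.predict_proba(X) > 0.5
        assert (pred == (y == 1)).all()

    def test_depth_bounded_by_attribute_count(self, fp_schema, planted_encoded):
        tree = sp.grow_tree(planted_encoded, fp_schema, sp.TreeParams(prune=False))
        assert tree.depth() <= 20

    def test_empty_input_rejected(self, fp_schema, planted_encoded):
        with pytest.raises(ValueError, match="empty"):
            sp.grow_tree(planted_encoded.iloc[0:0], fp_schema)

    def test_deterministic(self, fp_schema, planted_encoded):
        import json

        a = sp.grow_tree(planted_encoded, fp_schema)
        b = sp.grow_tree(planted_encoded, fp_schema)
        assert json.dumps(sp.tree_learner._tree_to_dict(a)) == json.dumps(
            sp.tree_learner._tree_to_dict(b)
        )

    def test_unseen_value_routes_to_parent_distribution(self, fp_schema):
        # training uses only AA (PPI) and BB (no-PPI); a CC probe reaches the
        # fallback child and receives the root's 50/50 distribution
        rows = []
        for i in range(10):
            code = "AA" if i % 2 == 0 else "BB"
            label = "PPI" if code == "AA" else "no-PPI"
            rows.append((f"x{i}", f"y{i}", label) + (code,) * 20)
        train = pd.DataFrame(rows, columns=["id1", "id2", "label", *fp_schema.names])
        tree = sp.grow_tree(train, fp_schema, sp.TreeParams(prune=False, min_leaf=1))
        probe = pd.DataFrame(
            [("p", "q", "unlabeled") + ("CC",) * 20],
            columns=["id1", "id2", "label", *fp_schema.names],
        )
        X, _ = dataset_to_matrix(probe, fp_schema)
        assert tree.predict_proba(X)[0] == pytest.approx(0.5)


class TestBagging:
    def test_single_bag_equals_tree_on_bootstrap(self, fp_schema, planted_encoded):
        seed = 42
        bag = sp.bag_train(planted_encoded, fp_schema, n_bags=1, seed=seed)
        rng = np.random.default_rng(seed)
        sample = rng.integers(0, len(planted_encoded), size=len(planted_encoded))
        tree = sp.grow_tree(
            planted_encoded.iloc[sample].reset_index(drop=True), fp_schema, seed=seed
        )
        X, _ = dataset_to_matrix(planted_encoded, fp_schema)
        assert np.allclose(bag.predict_proba(X), tree.predict_proba(X))

    def test_pure_data_probability_one(self, fp_schema, planted_encoded):
        bag = sp.bag_train(planted_encoded, fp_schema, n_bags=5, seed=0)
        pos = planted_encoded[planted_encoded["label"] == "PPI"]
        X, _ = dataset_to_matrix(pos, fp_schema)
        assert np.allclose(bag.predict_proba(X), 1.0)

    def test_seed_determinism(self, fp_schema, planted_encoded):
        X, _ = dataset_to_matrix(planted_encoded, fp_schema)
        a = sp.bag_train(planted_encoded, fp_schema, n_bags=3, seed=5).predict_proba(X)
        b = sp.bag_train(planted_encoded, fp_schema, n_bags=3, seed=5).predict_proba(X)
        assert np.array_equal(a, b)

    def test_prediction_invariant_to_tree_order(self, fp_schema, planted_encoded):
        bag = sp.bag_train(planted_encoded, fp_schema, n_bags=4, seed=1)
        X, _ = dataset_to_matrix(planted_encoded.head(50), fp_schema)
        before = bag.predict_proba(X)
        bag.trees = bag.trees[::-1]
        assert np.allclose(before, bag.predict_proba(X))


def _leaf_tree(p_ppi: float, schema) -> DecisionTree:
    """Single-leaf tree emitting a fixed P(PPI), for combination arithmetic."""
    counts = np.array([round((1 - p_ppi) * 1000), round(p_ppi * 1000)], dtype=np.int64)
    return DecisionTree(
        root=Node(counts=counts),
        schema_tag=schema.schema_tag,
        attribute_names=schema.names,
        domain_sizes=tuple(len(a.domain) for a in schema.attributes),
        params=sp.TreeParams(),
        seed=0,
    )


def _leaf_bag(p_ppi: float, schema) -> sp.BaggedModel:
    return sp.BaggedModel(trees=[_leaf_tree(p_ppi, schema)], n_bags=1, seed=0,
                          schema_tag=schema.schema_tag)


class TestCombineAndClassify:
    def test_single_model_combine_is_identity(self, fp_schema, planted_encoded):
        bag = sp.bag_train(planted_encoded, fp_schema, n_bags=2, seed=0)
        model = sp.combine([bag])
        X, _ = dataset_to_matrix(planted_encoded.head(30), fp_schema)
        assert np.allclose(model.score(X), bag.predict_proba(X))

    def test_mean_of_two_models(self, fp_schema):
        model = sp.combine([_leaf_bag(0.2, fp_schema), _leaf_bag(0.8, fp_schema)])
        X = np.zeros((3, 20), dtype=np.int64)
        assert np.allclose(model.score(X), 0.5)

    def test_combine_invariant_to_model_order(self, fp_schema):
        bags = [_leaf_bag(p, fp_schema) for p in (0.1, 0.5, 0.9)]
        X = np.zeros((2, 20), dtype=np.int64)
        assert np.allclose(
            sp.combine(bags).score(X), sp.combine(bags[::-1]).score(X)
        )

    def test_empty_combine_rejected(self):
        with pytest.raises(ValueError):
            sp.combine([])

    def _probe(self, fp_schema):
        return pd.DataFrame(
            [("a", "b", "unlabeled") + ("AA",) * 20],
            columns=["id1", "id2", "label", *fp_schema.names],
        )

    def test_score_half_is_unclassified(self, fp_schema):
        model = sp.combine([_leaf_bag(0.2, fp_schema), _leaf_bag(0.8, fp_schema)])
        (pred,) = sp.classify(model, self._probe(fp_schema), fp_schema)
        assert pred.rounded_score == 0.5
        assert pred.label == "unclassified"

    def test_high_score_is_ppi(self, fp_schema):
        (pred,) = sp.classify(model := sp.combine([_leaf_bag(0.8, fp_schema)]),
                              self._probe(fp_schema), fp_schema)
        assert pred.label == "PPI"
        assert pred.score == pytest.approx(0.8)

    def test_low_score_is_no_ppi_with_interaction_score(self, fp_schema):
        (pred,) = sp.classify(sp.combine([_leaf_bag(0.2, fp_schema)]),
                              self._probe(fp_schema), fp_schema)
        assert pred.label == "no-PPI"
        # the reported score is the interaction score: 1 - (no-PPI confidence 0.8)
        assert pred.score == pytest.approx(0.2)

    def test_label_is_function_of_rounded_score(self, fp_schema):
        for p, expected in [(0.504, "unclassified"), (0.51, "PPI"), (0.49, "no-PPI")]:
            (pred,) = sp.classify(sp.combine([_leaf_bag(p, fp_schema)]),
                                  self._probe(fp_schema), fp_schema)
            assert pred.label == expected, p


class TestTreeInspection:
    def test_level2_bounded_by_root_domain(self, fp_schema, planted_encoded):
        tree = sp.grow_tree(planted_encoded, fp_schema)
        assert len(level2_attributes(tree)) <= 10  # symmetric domain size

    def test_single_leaf_empty_results(self, fp_schema, planted_encoded):
        pure = planted_encoded[planted_encoded["label"] == "PPI"].reset_index(drop=True)
        tree = sp.grow_tree(pure, fp_schema)
        assert sp.root_attribute(tree) is None
        assert level2_attributes(tree) == []

    def test_synthesis_table_one_row_per_tree(self, fp_schema, planted_encoded):
        bags = [sp.bag_train(planted_encoded, fp_schema, n_bags=3, seed=s) for s in (0, 1)]
        table = tree_synthesis(bags)
        assert len(table) == 6
        assert set(table["root"]) == {"N~N"}


class TestSerialization:
    def test_combined_model_roundtrip(self, tmp_path, fp_schema, planted_encoded):
        bags = [sp.bag_train(planted_encoded, fp_schema, n_bags=2, seed=s) for s in (0, 1)]
        model = sp.combine(bags)
        path = tmp_path / "model.json"
        sp.save_combined_model(model, path)
        back = sp.load_combined_model(path)
        X, _ = dataset_to_matrix(planted_encoded.head(40), fp_schema)
        assert np.array_equal(model.score(X), back.score(X))

    def test_version_checked(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="format"):
            sp.load_combined_model(path)
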