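"""Categorical decision tree: fitting, pruning, paths, evaluation."""

import numpy as np
import pytest

from spaqwinter import (
    ClassLabel,
    Leaf,
    Season,
    ValidationError,
    evaluate,
    extract_winter_paths,
    fit_tree,
    gini_impurity,
    predict_tree,
    prune_tree,
)
from spaqwinter.decision_tree import DecisionTree, Split, predict_matrix, tree_to_dict
from spaqwinter.kmodes import CategoricalMatrix
from spaqwinter.spaq_core import ANALYSIS_ITEMS, SEASON_ORDER

from conftest import four_path_tree, make_profile, other_leaf, winter_leaf

W, O = ClassLabel.WINTER_TYPE, ClassLabel.OTHER


def matrix_from_codes(codes):
    codes = np.asarray(codes)
    return CategoricalMatrix(
        tuple(f"r{i}" for i in range(len(codes))), ANALYSIS_ITEMS, codes
    )


def random_dataset(rng, n):
    codes = rng.integers(0, 5, size=(n, 4))
    labels = [W if rng.random() < 0.5 else O for _ in range(n)]
    return matrix_from_codes(codes), labels


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected", [((5, 5), 0.5), ((10, 0), 0.0), ((0, 0), 0.0), ((3, 1), 0.375)]
    )
    def test_closed_form(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)


class TestFit:
    def test_single_class_single_leaf(self):
        m = matrix_from_codes([[0, 0, 0, 0], [2, 2, 2, 2]])
        tree = fit_tree(m, [W, W])
        assert isinstance(tree.root, Leaf)
        assert tree.root.label is W

    def test_single_split_separable(self):
        # label determined by sleep_most == WINTER (column 2, code 0)
        codes = [[0, 0, 0, 0], [2, 2, 0, 2], [2, 2, 2, 2], [0, 0, 4, 0]]
        labels = [W, W, O, O]
        m = matrix_from_codes(codes)
        tree = fit_tree(m, labels)
        root = tree.root
        assert isinstance(root, Split)
        assert (root.item, root.category) == ("sleep_most", Season.WINTER)
        assert isinstance(root.equals, Leaf) and root.equals.label is W
        assert isinstance(root.rest, Leaf) and root.rest.label is O
        assert predict_matrix(tree, m) == labels

    def test_tied_leaf_goes_other(self):
        m = matrix_from_codes([[0, 0, 0, 0], [0, 0, 0, 0]])
        tree = fit_tree(m, [W, O])  # identical rows, split impossible
        assert isinstance(tree.root, Leaf)
        assert tree.root.label is O

    def test_resubstitution_exact_on_consistent_data(self):
        """With unlimited depth and labels that are a function of the profile,
        the unpruned tree reproduces every training label."""
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 5, size=(60, 4))
        labels = [W if (r[0] == 0 or (r[2] == 4 and r[3] == 0)) else O for r in codes]
        m = matrix_from_codes(codes)
        tree = fit_tree(m, labels, max_depth=8)
        assert predict_matrix(tree, m) == labels

    def test_chosen_split_maximizes_gini_decrease(self):
        """Exhaustively recompute all 20 (item, category) candidates at the
        root and check the fitted split is at least as good as each."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            m, labels = random_dataset(rng, 40)
            tree = fit_tree(m, labels)
            if isinstance(tree.root, Leaf):
                continue
            y = np.array([lab is W for lab in labels])

            def decrease(j, cat):
                mask = m.codes[:, j] == cat
                if mask.sum() in (0, len(y)):
                    return -1.0
                def g(v):
                    return gini_impurity((int(v.sum()), int(len(v) - v.sum())))
                return g(y) - mask.mean() * g(y[mask]) - (1 - mask.mean()) * g(y[~mask])

            j0 = ANALYSIS_ITEMS.index(tree.root.item)
            c0 = SEASON_ORDER.index(tree.root.category)
            best = decrease(j0, c0)
            for j in range(4):
                for cat in range(5):
                    assert best >= decrease(j, cat) - 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            fit_tree(matrix_from_codes([[0, 0, 0, 0]]), [W, O])


class TestPredict:
    def test_single_leaf(self):
        tree = DecisionTree(root=winter_leaf(5), n_training_rows=5)
        assert predict_tree(tree, make_profile()) is W

    def test_one_split_descent(self):
        tree = DecisionTree(
            root=Split("sleep_most", Season.WINTER, winter_leaf(3), other_leaf(3)),
            n_training_rows=6,
        )
        assert predict_tree(tree, make_profile(sleep_most=Season.WINTER)) is W
        assert predict_tree(tree, make_profile(sleep_most=Season.NONE)) is O


class TestPrune:
    def test_single_patient_winter_leaf_removed(self):
        tree = DecisionTree(
            root=Split("feel_worst", Season.WINTER, winter_leaf(1), other_leaf(9)),
            n_training_rows=10,
        )
        pruned = prune_tree(tree)
        assert extract_winter_paths(pruned) == []
        assert predict_tree(pruned, make_profile()) is O

    def test_four_described_paths_survive(self):
        """The reconstructed four-path tree keeps winter leaves 7/47/8/5 and
        drops the single-patient leaf; 67 patients stay winter-classified."""
        pruned = prune_tree(four_path_tree())
        paths = extract_winter_paths(pruned)
        assert sorted(p.n_patients for p in paths) == [5, 7, 8, 47]
        assert sum(p.n_patients for p in paths) == 67

    def test_all_other_tree_unchanged_behavior(self):
        tree = DecisionTree(
            root=Split("feel_worst", Season.SUMMER, other_leaf(4), other_leaf(6)),
            n_training_rows=10,
        )
        pruned = prune_tree(tree)
        assert isinstance(pruned.root, Leaf)
        assert pruned.root.label is O
        assert pruned.root.sample_count == 10

    def test_never_creates_winter_predictions(self):
        """Rows the full tree predicts OTHER stay OTHER after pruning."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            m, labels = random_dataset(rng, 30)
            tree = fit_tree(m, labels)
            pruned = prune_tree(tree)
            before = predict_matrix(tree, m)
            after = predict_matrix(pruned, m)
            for b, a in zip(before, after):
                if b is O:
                    assert a is O

    def test_sample_counts_preserved(self):
        tree = four_path_tree()
        pruned = prune_tree(tree)
        assert pruned.root.sample_count == tree.root.sample_count == 96


class TestPaths:
    def test_no_winter_leaves_empty(self):
        tree = DecisionTree(root=other_leaf(5), n_training_rows=5)
        assert extract_winter_paths(tree) == []

    def test_single_condition_path(self):
        tree = DecisionTree(
            root=Split("sleep_most", Season.WINTER, winter_leaf(3), other_leaf(3)),
            n_training_rows=6,
        )
        (path,) = extract_winter_paths(tree)
        assert path.conditions == (("sleep_most", Season.WINTER, True),)
        assert path.n_patients == 3

    def test_root_to_leaf_condition_order(self):
        pruned = prune_tree(four_path_tree())
        for path in extract_winter_paths(pruned):
            assert path.conditions[0][0] == "feel_worst"


class TestEvaluate:
    def test_study_confusion_counts(self):
        """67 winter hits, 26 other hits, 3 missed winter, 0 false winter."""
        predictions = [W] * 67 + [O] * 26 + [O] * 3
        truth = [W] * 67 + [O] * 26 + [W] * 3
        result = evaluate(predictions, truth)
        assert (result.confusion.tp, result.confusion.tn, result.confusion.fp,
                result.confusion.fn) == (67, 26, 0, 3)
        assert result.accuracy == pytest.approx(93 / 96)
        assert result.f1 == pytest.approx(134 / 137)

    def test_perfect(self):
        result = evaluate([W, O, W], [W, O, W])
        assert result.accuracy == 1.0 and result.f1 == 1.0

    def test_all_predicted_other(self):
        result = evaluate([O, O, O, O], [W, W, O, O])
        assert result.accuracy == 0.5
        assert result.precision == 1.0  # no positive predictions
        assert result.recall == 0.0
        assert result.f1 == 0.0

    def test_brute_force_recount(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            preds = [W if rng.random() < 0.5 else O for _ in range(n)]
            truth = [W if rng.random() < 0.5 else O for _ in range(n)]
            result = evaluate(preds, truth)
            acc = sum(p is t for p, t in zip(preds, truth)) / n
            assert result.accuracy == pytest.approx(acc)
            tp = sum(1 for p, t in zip(preds, truth) if p is W and t is W)
            denom = 2 * tp + result.confusion.fp + result.confusion.fn
            f1 = 2 * tp / denom if denom else 0.0
            assert result.f1 == pytest.approx(f1)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [])


class TestSerialization:
    def test_tree_document_round_trips_structure(self):
        doc = tree_to_dict(prune_tree(four_path_tree()))
        assert doc["root"]["kind"] == "split"
        assert doc["root"]["item"] == "feel_worst"
        assert doc["n_training_rows"] == 96

        def count_winter_leaves(node):
            if node["kind"] == "leaf":
                return int(node["label"] == ClassLabel.WINTER_TYPE.value)
            return count_winter_leaves(node["equals"]) + count_winter_leaves(node["rest"])

        assert count_winter_leaves(doc["root"]) == 4
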