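"""Categorical decision tree for winter-type classification.

A small CART-style tree fitted on the four season-profile items with
cluster-derived labels as targets.  Splits are binary one-category-vs-rest
equality tests ("sleep_most == none" vs "anything else"), chosen greedily
to maximize the Gini impurity decrease.  The tree is then simplified with a
bespoke structural pruning rule:

* every subtree all of whose leaves predict OTHER is collapsed, and
* every WINTER_TYPE leaf holding a single patient is dropped;

rows routed into removed regions are classified OTHER at prediction time,
so pruning can only trade winter-type hits for misses — it never creates a
new winter-type prediction.  The surviving winter leaves, read root to
leaf, are the candidate simplified classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .kmodes import CategoricalMatrix, N_CATEGORIES
from .spaq_core import SEASON_ORDER, Season, SeasonProfile, ValidationError


class ClassLabel(str, Enum):
    WINTER_TYPE = "winter-type"
    OTHER = "other"


@dataclass(frozen=True)
class Leaf:
    label: ClassLabel
    class_counts: dict[ClassLabel, int]

    @property
    def sample_count(self) -> int:
        return sum(self.class_counts.values())


@dataclass(frozen=True)
class Split:
    """Internal node: ``item == category`` goes left, everything else right."""

    item: str
    category: Season
    equals: "TreeNode"
    rest: "TreeNode"

    @property
    def sample_count(self) -> int:
        return self.equals.sample_count + self.rest.sample_count


TreeNode = Union[Leaf, Split]


@dataclass(frozen=True)
class DecisionTree:
    root: TreeNode
    criterion: str = "gini"
    max_depth: int = 4
    n_training_rows: int = 0


@dataclass(frozen=True)
class WinterPath:
    """Root-to-leaf conditions of one surviving winter-type rule.

    ``conditions`` is an ordered tuple of ``(item, category, equals)``
    triples; ``equals`` False means "any category but this one".
    """

    conditions: tuple[tuple[str, Season, bool], ...]
    n_patients: int


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity 1 − Σ p²; 0 for a pure node, 0.5 for a 50/50 binary node."""
    total = sum(class_counts)
    if total == 0:
        return 0.0
    return 1.0 - sum((c / total) ** 2 for c in class_counts)


def _counts(y: np.ndarray) -> tuple[int, int]:
    """(winter, other) counts of a boolean winter-indicator vector."""
    w = int(y.sum())
    return w, int(y.size - w)


def _leaf_from(y: np.ndarray) -> Leaf:
    w, o = _counts(y)
    # majority label; ties conservatively go to OTHER
    label = ClassLabel.WINTER_TYPE if w > o else ClassLabel.OTHER
    return Leaf(label=label, class_counts={ClassLabel.WINTER_TYPE: w, ClassLabel.OTHER: o})


def _best_split(
    codes: np.ndarray, y: np.ndarray, columns: tuple[str, ...], blocked: frozenset
) -> tuple[int, int, float] | None:
    """Best (column, category, decrease) by Gini gain; fixed-order tie-break.

    Candidates iterate items in column order and categories in season order;
    a later candidate replaces the incumbent only on strictly greater
    decrease, so ties resolve to the earliest candidate.
    """
    n = y.size
    parent = gini_impurity(_counts(y))
    best = None
    for j, item in enumerate(columns):
        for cat in range(N_CATEGORIES):
            if (item, cat) in blocked:
                continue
            mask = codes[:, j] == cat
            n_eq = int(mask.sum())
            if n_eq == 0 or n_eq == n:
                continue
            g_eq = gini_impurity(_counts(y[mask]))
            g_rest = gini_impurity(_counts(y[~mask]))
            decrease = parent - (n_eq / n) * g_eq - ((n - n_eq) / n) * g_rest
            if decrease > 1e-12 and (best is None or decrease > best[2] + 1e-12):
                best = (j, cat, decrease)
    return best


def _grow(
    codes: np.ndarray,
    y: np.ndarray,
    columns: tuple[str, ...],
    depth: int,
    max_depth: int,
    min_leaf: int,
    blocked: frozenset,
) -> TreeNode:
    w, o = _counts(y)
    if w == 0 or o == 0 or depth >= max_depth:
        return _leaf_from(y)
    found = _best_split(codes, y, columns, blocked)
    if found is None:
        return _leaf_from(y)
    j, cat, _ = found
    mask = codes[:, j] == cat
    if int(mask.sum()) < min_leaf or int((~mask).sum()) < min_leaf:
        return _leaf_from(y)
    item = columns[j]
    # on the equals branch the item is fully determined; on the rest branch
    # only this (item, category) test is exhausted
    blocked_eq = blocked | {(item, c) for c in range(N_CATEGORIES)}
    blocked_rest = blocked | {(item, cat)}
    return Split(
        item=item,
        category=SEASON_ORDER[cat],
        equals=_grow(codes[mask], y[mask], columns, depth + 1, max_depth, min_leaf, blocked_eq),
        rest=_grow(codes[~mask], y[~mask], columns, depth + 1, max_depth, min_leaf, blocked_rest),
    )


def fit_tree(
    profiles: CategoricalMatrix,
    labels: Sequence[ClassLabel],
    max_depth: int = 4,
    min_leaf: int = 1,
) -> DecisionTree:
    """Greedy Gini tree on (item == category) tests.

    Defaults (depth ≤ 4 — one level per item — minimum leaf size 1, any
    positive impurity decrease accepted) match the small-tree regime in
    which the four-path winter rule structure is expressible.
    """
    if profiles.n_rows == 0:
        raise ValidationError("cannot fit a tree on an empty matrix")
    if len(labels) != profiles.n_rows:
        raise ValidationError(
            f"labels length {len(labels)} does not match {profiles.n_rows} rows"
        )
    y = np.array([lab == ClassLabel.WINTER_TYPE for lab in labels], dtype=bool)
    root = _grow(profiles.codes, y, profiles.columns, 0, max_depth, min_leaf, frozenset())
    return DecisionTree(
        root=root, criterion="gini", max_depth=max_depth, n_training_rows=profiles.n_rows
    )


def predict_tree(tree: DecisionTree, profile: SeasonProfile) -> ClassLabel:
    """Deterministic root-to-leaf descent for one profile."""
    node = tree.root
    while isinstance(node, Split):
        node = node.equals if profile[node.item] == node.category else node.rest
    return node.label


def predict_matrix(tree: DecisionTree, profiles: CategoricalMatrix) -> list[ClassLabel]:
    col_index = {item: j for j, item in enumerate(profiles.columns)}
    out = []
    for i in range(profiles.n_rows):
        node = tree.root
        while isinstance(node, Split):
            code = profiles.codes[i, col_index[node.item]]
            node = node.equals if SEASON_ORDER[code] == node.category else node.rest
        out.append(node.label)
    return out


def _all_other(node: TreeNode) -> bool:
    if isinstance(node, Leaf):
        return node.label == ClassLabel.OTHER
    return _all_other(node.equals) and _all_other(node.rest)


def _merged_other(node: TreeNode) -> Leaf:
    """Collapse a subtree into a single OTHER leaf with summed counts."""
    if isinstance(node, Leaf):
        return Leaf(label=ClassLabel.OTHER, class_counts=dict(node.class_counts))
    a, b = _merged_other(node.equals), _merged_other(node.rest)
    return Leaf(
        label=ClassLabel.OTHER,
        class_counts={
            k: a.class_counts.get(k, 0) + b.class_counts.get(k, 0) for k in ClassLabel
        },
    )


def _prune(node: TreeNode) -> TreeNode:
    if isinstance(node, Leaf):
        if node.label == ClassLabel.WINTER_TYPE and node.sample_count == 1:
            # single-patient winter leaf: reclassify its region as OTHER
            return Leaf(label=ClassLabel.OTHER, class_counts=dict(node.class_counts))
        return node
    eq, rest = _prune(node.equals), _prune(node.rest)
    if _all_other(eq) and _all_other(rest):
        return _merged_other(Split(node.item, node.category, eq, rest))
    return Split(node.item, node.category, eq, rest)


def prune_tree(tree: DecisionTree) -> DecisionTree:
    """Apply the structural pruning rule (see module docstring).

    Removed regions keep their sample counts but predict OTHER, so every
    profile still receives a prediction and no new winter-type prediction
    can appear.
    """
    return DecisionTree(
        root=_prune(tree.root),
        criterion=tree.criterion,
        max_depth=tree.max_depth,
        n_training_rows=tree.n_training_rows,
    )


def extract_winter_paths(tree: DecisionTree) -> list[WinterPath]:
    """One path per winter-type leaf, conditions in root-to-leaf order."""
    paths: list[WinterPath] = []

    def walk(node: TreeNode, conds: tuple[tuple[str, Season, bool], ...]) -> None:
        if isinstance(node, Leaf):
            if node.label == ClassLabel.WINTER_TYPE:
                paths.append(WinterPath(conditions=conds, n_patients=node.sample_count))
            return
        walk(node.equals, conds + ((node.item, node.category, True),))
        walk(node.rest, conds + ((node.item, node.category, False),))

    walk(tree.root, ())
    return paths


def format_path(path: WinterPath) -> str:
    parts = [
        f"{item} {'==' if eq else '!='} {cat.value}" for item, cat, eq in path.conditions
    ]
    return " AND ".join(parts) + f"  ->  winter-type (n={path.n_patients})"


def evaluate(
    predictions: Sequence[ClassLabel], truth: Sequence[ClassLabel]
) -> EvaluationResult:
    """Confusion matrix and accuracy/precision/recall/F1, winter-type positive.

    Precision is defined as 1.0 when there are no positive predictions,
    which keeps F1 well-defined (it is then 0 whenever recall is 0).
    """
    if len(predictions) == 0:
        raise ValidationError("cannot evaluate an empty prediction set")
    if len(predictions) != len(truth):
        raise ValidationError(
            f"predictions ({len(predictions)}) and truth ({len(truth)}) differ in length"
        )
    W = ClassLabel.WINTER_TYPE
    tp = sum(1 for p, t in zip(predictions, truth) if p == W and t == W)
    tn = sum(1 for p, t in zip(predictions, truth) if p != W and t != W)
    fp = sum(1 for p, t in zip(predictions, truth) if p == W and t != W)
    fn = sum(1 for p, t in zip(predictions, truth) if p != W and t == W)
    cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
    accuracy = (tp + tn) / cm.total
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return EvaluationResult(
        confusion=cm, accuracy=accuracy, precision=precision, recall=recall, f1=f1
    )


def tree_to_dict(tree: DecisionTree) -> dict:
    """JSON-serializable tree document."""

    def node_dict(node: TreeNode) -> dict:
        if isinstance(node, Leaf):
            return {
                "kind": "leaf",
                "label": node.label.value,
                "class_counts": {k.value: v for k, v in node.class_counts.items()},
            }
        return {
            "kind": "split",
            "item": node.item,
            "category": node.category.value,
            "equals": node_dict(node.equals),
            "rest": node_dict(node.rest),
        }

    return {
        "criterion": tree.criterion,
        "max_depth": tree.max_depth,
        "n_training_rows": tree.n_training_rows,
        "root": node_dict(tree.root),
    }
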