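"""Shared fixtures: record factories, the 8-row clustering fixture, and a
cached set of large synthetic screened subsets reused by the slower
recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from spaqwinter import (
    ANALYSIS_ITEMS,
    ClassLabel,
    GeneratorConfig,
    Leaf,
    Season,
    SeasonProfile,
    Split,
    SPAQRecord,
    generate_screened_subset,
)
from spaqwinter.decision_tree import DecisionTree
from spaqwinter.kmodes import CategoricalMatrix


def make_record(
    pid: str = "P1",
    feel_worst=(1,),
    gain_most_weight=(1,),
    sleep_most=(1,),
    socialize_least=(1,),
    scores=(3, 3, 3, 3, 3, 3),
    impairment=3,
    flags=None,
) -> SPAQRecord:
    """Record factory with winter-ish, screen-passing defaults."""
    months = {
        "feel_worst": frozenset(feel_worst),
        "gain_most_weight": frozenset(gain_most_weight),
        "sleep_most": frozenset(sleep_most),
        "socialize_least": frozenset(socialize_least),
    }
    no_flags = {item: not months[item] for item in ANALYSIS_ITEMS}
    if flags:
        no_flags.update(flags)
    return SPAQRecord(
        participant_id=pid,
        item_months=months,
        no_month_flags=no_flags,
        domain_scores=tuple(scores),
        impairment=impairment,
    )


def make_profile(
    feel_worst=Season.WINTER,
    gain_most_weight=Season.WINTER,
    sleep_most=Season.WINTER,
    socialize_least=Season.WINTER,
) -> SeasonProfile:
    return SeasonProfile(
        items={
            "feel_worst": feel_worst,
            "gain_most_weight": gain_most_weight,
            "sleep_most": sleep_most,
            "socialize_least": socialize_least,
        }
    )


@pytest.fixture
def eight_row_matrix() -> CategoricalMatrix:
    """Small two-group instance with noise; brute-force optimum cost is 9."""
    codes = np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 4, 0],
            [0, 4, 0, 0],
            [2, 4, 2, 2],
            [2, 1, 4, 2],
            [4, 1, 2, 2],
            [0, 1, 0, 4],
            [2, 4, 4, 2],
        ]
    )
    return CategoricalMatrix(
        tuple(f"r{i}" for i in range(8)), ("a", "b", "c", "d"), codes
    )


def bipartition_oracle_cost(codes: np.ndarray) -> int:
    """Exhaustive minimum 2-cluster cost: enumerate all bipartitions and use
    the column-wise mode (provably optimal centroid) on each side."""

    def side_cost(rows: np.ndarray) -> int:
        if len(rows) == 0:
            return 0
        return int(
            sum(
                len(rows) - np.bincount(rows[:, j], minlength=5).max()
                for j in range(rows.shape[1])
            )
        )

    n = len(codes)
    best = None
    for mask in range(1, 2 ** (n - 1)):  # fix the last row in one side
        sel = np.array([(mask >> i) & 1 for i in range(n - 1)] + [0], dtype=bool)
        cost = side_cost(codes[sel]) + side_cost(codes[~sel])
        if best is None or cost < best:
            best = cost
    return best


def winter_leaf(n_winter: int, n_other: int = 0) -> Leaf:
    return Leaf(
        label=ClassLabel.WINTER_TYPE,
        class_counts={ClassLabel.WINTER_TYPE: n_winter, ClassLabel.OTHER: n_other},
    )


def other_leaf(n_other: int, n_winter: int = 0) -> Leaf:
    return Leaf(
        label=ClassLabel.OTHER,
        class_counts={ClassLabel.WINTER_TYPE: n_winter, ClassLabel.OTHER: n_other},
    )


def four_path_tree() -> DecisionTree:
    """A 96-patient tree matching the described pruned-rule structure.

    Winter leaves of sizes 7, 47, 8 and 5 plus one single-patient winter
    leaf (which the pruning rule must drop) and OTHER leaves holding the
    remaining patients (including 2 winter-cluster members that the tree
    never captured).
    """
    summer_side = Split(
        item="gain_most_weight",
        category=Season.WINTER,
        equals=winter_leaf(8),
        rest=Split(
            item="sleep_most",
            category=Season.WINTER,
            equals=Split(
                item="socialize_least",
                category=Season.NONE,
                equals=winter_leaf(5),
                rest=winter_leaf(1),  # pruned: single winter-type patient
            ),
            rest=other_leaf(14),
        ),
    )
    not_summer_side = Split(
        item="sleep_most",
        category=Season.NONE,
        equals=Split(
            item="socialize_least",
            category=Season.WINTER,
            equals=winter_leaf(7),
            rest=other_leaf(12, n_winter=2),
        ),
        rest=winter_leaf(47),
    )
    root = Split(
        item="feel_worst", category=Season.SUMMER, equals=summer_side, rest=not_summer_side
    )
    return DecisionTree(root=root, max_depth=4, n_training_rows=96)


@pytest.fixture(scope="session")
def large_screened_subsets():
    """Ten default-condition screened subsets at n_total=2000, seeds 0..9."""
    return [
        generate_screened_subset(GeneratorConfig(n_total=2000, seed=seed))
        for seed in range(10)
    ]
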