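"""Refined winter-type classification criteria.

The simplified rule set distilled from the pruned decision tree.  It keys
on the "feel worst" response and requires at least one corroborating
winter response elsewhere:

* Criteria 1 — "feel worst" is winter or none: winter-type if any of
  "gain most weight", "sleep most", "socialize least" is winter.
* Criteria 2 — "feel worst" is summer: winter-type if "gain most weight"
  or "sleep most" is winter (social withdrawal alone does not qualify
  against a summer "feel worst").

The table leaves spring/autumn "feel worst" responders uncovered; in the
default *strict* mode they are classified OTHER.  A *tree-faithful* mode
instead routes every non-summer "feel worst" through criteria 1, matching
the pruned tree's first path ("summer was not selected"); the choice is a
config flag because the two sources genuinely disagree on this corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .agreement import ContingencyTable, adjusted_rand_index, build_contingency
from .spaq_core import (
    Season,
    SeasonProfile,
    SeasonTypeLabel,
    ValidationError,
    kasper_season_type,
)
from .decision_tree import ClassLabel

CRITERIA_1_ITEMS = ("gain_most_weight", "sleep_most", "socialize_least")
CRITERIA_2_ITEMS = ("gain_most_weight", "sleep_most")

VALID_MODES = ("strict", "tree_faithful")


class CriteriaRule(str, Enum):
    CRITERIA_1 = "criteria-1"
    CRITERIA_2 = "criteria-2"
    NONE = "none"


@dataclass(frozen=True)
class CriteriaDecision:
    label: ClassLabel
    matched_rule: CriteriaRule
    matched_item: str | None

    def __post_init__(self) -> None:
        is_winter = self.label == ClassLabel.WINTER_TYPE
        if is_winter != (self.matched_rule != CriteriaRule.NONE):
            raise ValidationError("label and matched_rule are inconsistent")


def classify_refined_winter(profile: SeasonProfile, mode: str = "strict") -> CriteriaDecision:
    """Apply the refined winter-type criteria to one season profile."""
    if mode not in VALID_MODES:
        raise ValidationError(f"mode must be one of {VALID_MODES}, got {mode!r}")
    fw = profile["feel_worst"]
    if fw == Season.SUMMER:
        rule, items = CriteriaRule.CRITERIA_2, CRITERIA_2_ITEMS
    elif fw in (Season.WINTER, Season.NONE) or mode == "tree_faithful":
        rule, items = CriteriaRule.CRITERIA_1, CRITERIA_1_ITEMS
    else:  # spring/autumn feel-worst, strict mode: not covered by the table
        return CriteriaDecision(ClassLabel.OTHER, CriteriaRule.NONE, None)
    for item in items:
        if profile[item] == Season.WINTER:
            return CriteriaDecision(ClassLabel.WINTER_TYPE, rule, item)
    return CriteriaDecision(ClassLabel.OTHER, CriteriaRule.NONE, None)


@dataclass(frozen=True)
class CriteriaComparison:
    """Pairwise agreement of the refined criteria with other labelings."""

    refined_labels: tuple[ClassLabel, ...]
    kasper_labels: tuple[str, ...]  # "winter" / "other"
    cluster_labels: tuple[str, ...] | None
    tables: dict[str, ContingencyTable]
    aris: dict[str, float]


def _binary(labels) -> list[str]:
    return ["winter" if lab in (ClassLabel.WINTER_TYPE, "winter", SeasonTypeLabel.WINTER) else "other" for lab in labels]


def compare_criteria(
    profiles: Sequence[SeasonProfile],
    feel_worst_month_sets: Sequence[frozenset[int]],
    cluster_labels: Sequence[str] | None = None,
    mode: str = "strict",
) -> CriteriaComparison:
    """Label a cohort under Kasper's rule, the refined criteria, and
    (optionally) supplied cluster labels; emit pairwise tables and ARIs.

    All contingency tables use the {other, winter} × {other, winter}
    layout with "other" first.
    """
    if len(profiles) != len(feel_worst_month_sets):
        raise ValidationError("profiles and month sets differ in length")
    if cluster_labels is not None and len(cluster_labels) != len(profiles):
        raise ValidationError("cluster labels differ in length from profiles")
    refined = tuple(classify_refined_winter(p, mode=mode).label for p in profiles)
    kasper = tuple(_binary(kasper_season_type(m) for m in feel_worst_month_sets))
    order = ["other", "winter"]
    tables: dict[str, ContingencyTable] = {}
    aris: dict[str, float] = {}

    def add(name: str, a, b) -> None:
        tables[name] = build_contingency(_binary(a), _binary(b), row_order=order, col_order=order)
        aris[name] = adjusted_rand_index(tables[name]) if len(profiles) >= 2 else 1.0

    add("kasper_vs_refined", kasper, refined)
    clusters = None
    if cluster_labels is not None:
        clusters = tuple(_binary(cluster_labels))
        add("kasper_vs_cluster", kasper, clusters)
        add("refined_vs_cluster", refined, clusters)
    return CriteriaComparison(
        refined_labels=refined,
        kasper_labels=kasper,
        cluster_labels=clusters,
        tables=tables,
        aris=aris,
    )
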