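"""End-to-end pipeline: screen → profile → cluster → tree → criteria → metrics.

Stage order mirrors the analysis workflow the package implements:

1. score Question 2 (GSS) and apply the Kasper SAD/S-SAD screen;
2. collapse the four Question-1 items to five-level season profiles
   (Korea-adapted season boundaries);
3. K-Modes clustering of the screened profiles (k = 2 by default, with an
   elbow cost curve over k = 1..elbow_max_k for diagnostics) and
   identification of the winter-type cluster by its mode;
4. fit the categorical decision tree on the profiles with cluster labels
   as targets, apply the structural pruning rule, extract winter paths;
5. label everyone with Kasper's season type and the refined criteria;
   cross-tabulate all pairs of labelings and compute ARIs;
6. evaluate pruned-tree predictions against the cluster labels
   (resubstitution, as no held-out split exists at this cohort size).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

from .agreement import adjusted_rand_index, build_contingency
from .criteria import classify_refined_winter
from .decision_tree import (
    ClassLabel,
    evaluate,
    extract_winter_paths,
    fit_tree,
    predict_matrix,
    prune_tree,
)
from .io import PipelineReport
from .kmodes import (
    CategoricalMatrix,
    KModesConfig,
    elbow_curve,
    fit_kmodes,
    winter_cluster_index,
)
from .spaq_core import (
    DiagnosisLabel,
    SPAQRecord,
    SeasonTypeLabel,
    ValidationError,
    classify_kasper_diagnosis,
    derive_season_profile,
    kasper_season_type,
)

logger = logging.getLogger("spaqwinter")

BINARY_ORDER = ["other", "winter"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    k: int = 2
    n_restarts: int = 20
    max_iterations: int = 100
    elbow_max_k: int = 10
    tree_max_depth: int = 4
    prune: bool = True
    criteria_mode: str = "strict"


def screen_cohort(records: Sequence[SPAQRecord]) -> tuple[list[SPAQRecord], int, int]:
    """Kasper screen; returns (screened records, n_sad, n_ssad)."""
    screened, n_sad, n_ssad = [], 0, 0
    for r in records:
        diag = classify_kasper_diagnosis(r.gss, r.impairment)
        if diag.label == DiagnosisLabel.SAD:
            n_sad += 1
            screened.append(r)
        elif diag.label == DiagnosisLabel.S_SAD:
            n_ssad += 1
            screened.append(r)
    return screened, n_sad, n_ssad


def run_pipeline(records: Sequence[SPAQRecord], config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full analysis on a cohort; deterministic given config.seed."""
    config = config or PipelineConfig()
    if not records:
        raise ValidationError("cohort is empty")
    logger.info("pipeline start: n_input=%d seed=%d", len(records), config.seed)

    screened, n_sad, n_ssad = screen_cohort(records)
    n_screened = len(screened)
    logger.info("screen: %d/%d pass (SAD=%d, S-SAD=%d)", n_screened, len(records), n_sad, n_ssad)
    if n_screened < config.k:
        raise ValidationError(
            f"only {n_screened} participants pass the SAD/S-SAD screen; "
            f"need at least k={config.k} to cluster"
        )

    profiles = [derive_season_profile(r) for r in screened]
    matrix = CategoricalMatrix.from_profiles([r.participant_id for r in screened], profiles)

    km_config = KModesConfig(
        k=config.k,
        n_restarts=config.n_restarts,
        max_iterations=config.max_iterations,
        seed=config.seed,
    )
    elbow = elbow_curve(matrix, min(config.elbow_max_k, n_screened), km_config)
    result = fit_kmodes(matrix, km_config)
    wi = winter_cluster_index(result)
    logger.info("k-modes: sizes=%s cost=%d winter_cluster=%d",
                result.cluster_sizes(), result.cost, wi)

    cluster_binary = ["winter" if int(lab) == wi else "other" for lab in result.labels]
    cluster_classes = [
        ClassLabel.WINTER_TYPE if b == "winter" else ClassLabel.OTHER for b in cluster_binary
    ]

    kasper_binary = [
        "winter" if kasper_season_type(r.item_months["feel_worst"]) == SeasonTypeLabel.WINTER
        else "other"
        for r in screened
    ]
    refined_binary = [
        "winter"
        if classify_refined_winter(p, mode=config.criteria_mode).label == ClassLabel.WINTER_TYPE
        else "other"
        for p in profiles
    ]

    tables = {}
    aris = {}
    for name, a, b in (
        ("kasper_vs_cluster", kasper_binary, cluster_binary),
        ("criteria_vs_cluster", refined_binary, cluster_binary),
        ("kasper_vs_criteria", kasper_binary, refined_binary),
    ):
        tables[name] = build_contingency(a, b, row_order=BINARY_ORDER, col_order=BINARY_ORDER)
        aris[name] = adjusted_rand_index(tables[name]) if n_screened >= 2 else 1.0

    tree = fit_tree(matrix, cluster_classes, max_depth=config.tree_max_depth)
    pruned = prune_tree(tree) if config.prune else tree
    paths = extract_winter_paths(pruned)
    predictions = predict_matrix(pruned, matrix)
    evaluation = evaluate(predictions, cluster_classes)
    logger.info(
        "tree: %d winter paths, accuracy=%.4f f1=%.4f",
        len(paths), evaluation.accuracy, evaluation.f1,
    )

    sizes = result.cluster_sizes()
    return PipelineReport(
        n_input=len(records),
        n_screened=n_screened,
        n_sad=n_sad,
        n_ssad=n_ssad,
        cluster_sizes=sizes,
        winter_cluster_index=wi,
        elbow=elbow,
        tables=tables,
        aris=aris,
        tree=tree,
        pruned_tree=pruned,
        winter_paths=paths,
        evaluation=evaluation,
        seed=config.seed,
        config=asdict(config),
    )
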