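"""Cohort CSV readers/writers and the JSON pipeline report.

Cohort CSV schema (one row per participant): ``participant_id``, then for
each analysis item a ``<item>_months`` cell (pipe-separated 1-based month
numbers, e.g. ``12|1|2``; empty = no selection) and an ``<item>_none``
0/1 flag, then the six domain score columns and ``impairment``.  Extra
columns (e.g. the excluded SPAQ items) are accepted and ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .agreement import ContingencyTable
from .decision_tree import (
    DecisionTree,
    EvaluationResult,
    WinterPath,
    format_path,
    tree_to_dict,
)
from .spaq_core import ANALYSIS_ITEMS, DOMAIN_NAMES, SPAQRecord, ValidationError
from .synthetic_data import LatentSubtype, SyntheticCohort

SCORE_COLUMNS = tuple(f"score_{name}" for name in
                      ("sleep", "social", "mood", "weight", "appetite", "energy"))

COHORT_COLUMNS: tuple[str, ...] = (
    ("participant_id",)
    + tuple(c for item in ANALYSIS_ITEMS for c in (f"{item}_months", f"{item}_none"))
    + SCORE_COLUMNS
    + ("impairment",)
)


def _months_cell(months: frozenset[int]) -> str:
    return "|".join(str(m) for m in sorted(months))


def _parse_months(cell: str, row: int, column: str) -> frozenset[int]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    out = []
    for tok in cell.split("|"):
        try:
            out.append(int(tok))
        except ValueError:
            raise ValidationError(
                f"row {row}, column {column!r}: malformed month list {cell!r}"
            ) from None
    return frozenset(out)


def _parse_int(cell, row: int, column: str, lo: int, hi: int) -> int:
    try:
        v = int(str(cell).strip())
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}, column {column!r}: expected an integer, got {cell!r}"
        ) from None
    if not lo <= v <= hi:
        raise ValidationError(
            f"row {row}, column {column!r}: value {v} outside {lo}..{hi}"
        )
    return v


def write_cohort_csv(records: Sequence[SPAQRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {"participant_id": r.participant_id}
        for item in ANALYSIS_ITEMS:
            row[f"{item}_months"] = _months_cell(r.item_months[item])
            row[f"{item}_none"] = int(r.no_month_flags[item])
        for col, score in zip(SCORE_COLUMNS, r.domain_scores):
            row[col] = score
        row["impairment"] = r.impairment
        rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SPAQRecord]:
    """Read and validate a cohort CSV; errors carry the 1-based data row."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records: list[SPAQRecord] = []
    seen: set[str] = set()
    for idx, raw in enumerate(frame.to_dict("records"), start=1):
        pid = str(raw["participant_id"]).strip()
        if not pid:
            raise ValidationError(f"row {idx}: empty participant_id")
        if pid in seen:
            raise ValidationError(f"row {idx}: duplicate participant_id {pid!r}")
        seen.add(pid)
        months = {}
        flags = {}
        for item in ANALYSIS_ITEMS:
            months[item] = _parse_months(raw[f"{item}_months"], idx, f"{item}_months")
            flags[item] = bool(_parse_int(raw[f"{item}_none"], idx, f"{item}_none", 0, 1))
        scores = tuple(
            _parse_int(raw[col], idx, col, 0, 4) for col in SCORE_COLUMNS
        )
        impairment = _parse_int(raw["impairment"], idx, "impairment", 0, 5)
        try:
            records.append(
                SPAQRecord(
                    participant_id=pid,
                    item_months=months,
                    no_month_flags=flags,
                    domain_scores=scores,
                    impairment=impairment,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
    return records


def write_ground_truth_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in cohort.records],
            "latent_subtype": [s.value for s in cohort.latent_subtype],
        }
    ).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> dict[str, LatentSubtype]:
    frame = pd.read_csv(path, dtype=str)
    return {
        str(pid): LatentSubtype(sub)
        for pid, sub in zip(frame["participant_id"], frame["latent_subtype"])
    }


def truncate_percent(fraction: float, digits: int = 2) -> str:
    """Format a 0–1 fraction as a percentage truncated (not rounded).

    0.96875 → "96.87%": truncation matches how the headline accuracy is
    conventionally printed from 93/96.
    """
    scale = 10 ** digits
    value = math.floor(fraction * 100 * scale + 1e-9) / scale
    return f"{value:.{digits}f}%"


def table_to_dict(table: ContingencyTable) -> dict:
    return {
        "row_labels": list(table.row_labels),
        "col_labels": list(table.col_labels),
        "counts": table.counts.tolist(),
        "n": table.n,
    }


def write_contingency_csv(table: ContingencyTable, path: str | Path,
                          row_title: str = "", col_title: str = "") -> None:
    """CSV mirroring the printed contingency layout (row-label column first)."""
    frame = pd.DataFrame(
        table.counts,
        index=[f"{row_title}{r}" for r in table.row_labels],
        columns=[f"{col_title}{c}" for c in table.col_labels],
    )
    frame.to_csv(path, index_label="")


@dataclass(frozen=True)
class PipelineReport:
    """Aggregated end-to-end pipeline outputs (counts, tables, metrics)."""

    n_input: int
    n_screened: int
    n_sad: int
    n_ssad: int
    cluster_sizes: list[int]
    winter_cluster_index: int
    elbow: list[tuple[int, int]]
    tables: dict[str, ContingencyTable]
    aris: dict[str, float]
    tree: DecisionTree
    pruned_tree: DecisionTree
    winter_paths: list[WinterPath]
    evaluation: EvaluationResult
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        ev = self.evaluation
        return {
            "n_input": self.n_input,
            "n_screened": self.n_screened,
            "n_sad": self.n_sad,
            "n_ssad": self.n_ssad,
            "cluster_sizes": list(self.cluster_sizes),
            "winter_cluster_index": self.winter_cluster_index,
            "elbow": [[k, c] for k, c in self.elbow],
            "contingency": {name: table_to_dict(t) for name, t in self.tables.items()},
            "ari": {
                name: {"value": v, "display": f"{v:.3f}"} for name, v in self.aris.items()
            },
            "winter_paths": [
                {
                    "conditions": [
                        {"item": i, "category": c.value, "equals": eq}
                        for i, c, eq in p.conditions
                    ],
                    "n_patients": p.n_patients,
                    "rule": format_path(p),
                }
                for p in self.winter_paths
            ],
            "confusion_matrix": {
                "tp": ev.confusion.tp,
                "tn": ev.confusion.tn,
                "fp": ev.confusion.fp,
                "fn": ev.confusion.fn,
            },
            "metrics": {
                "accuracy": ev.accuracy,
                "accuracy_display": truncate_percent(ev.accuracy),
                "precision": ev.precision,
                "recall": ev.recall,
                "f1": ev.f1,
                "f1_display": truncate_percent(ev.f1),
            },
            "pruned_tree": tree_to_dict(self.pruned_tree),
            "tree": tree_to_dict(self.tree),
            "seed": self.seed,
            "config": dict(self.config),
        }


def write_report(report: PipelineReport, path: str | Path) -> None:
    """Write the report as JSON with stable key order."""
    path = Path(path)
    try:
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=False) + "\n")
    except OSError as err:
        raise ValidationError(f"cannot write report to {path}: {err}") from err


def read_report(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except OSError as err:
        raise ValidationError(f"cannot read report from {path}: {err}") from err
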