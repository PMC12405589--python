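"""Partition agreement: contingency tables and the Adjusted Rand Index.

The ARI (Hubert–Arabie) is the chance-corrected pair-counting agreement
between two partitions of the same participants.  With contingency counts
``n_ij`` and margins ``a_i`` (rows), ``b_j`` (columns):

    Index    = Σ_ij C(n_ij, 2)
    Expected = Σ_i C(a_i, 2) · Σ_j C(b_j, 2) / C(n, 2)
    Max      = [Σ_i C(a_i, 2) + Σ_j C(b_j, 2)] / 2
    ARI      = (Index − Expected) / (Max − Expected)

ARI is 1 for identical partitions, ~0 for chance-level agreement, and can
be negative for worse-than-chance agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Hashable, Sequence

import numpy as np

from .spaq_core import ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    """r×c cross-classification counts with named rows and columns."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D grid")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.col_labels, self.row_labels)


def build_contingency(
    labels_a: Sequence[Hashable],
    labels_b: Sequence[Hashable],
    row_order: Sequence[Hashable] | None = None,
    col_order: Sequence[Hashable] | None = None,
) -> ContingencyTable:
    """Cross-classify two equal-length label sequences.

    Row/column orders default to sorted string order of the distinct labels;
    pass explicit orders to pin a reporting layout.
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    rows = list(row_order) if row_order is not None else sorted(set(labels_a), key=str)
    cols = list(col_order) if col_order is not None else sorted(set(labels_b), key=str)
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: j for j, lab in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        if a not in ri:
            raise ValidationError(f"label {a!r} not in the given row order")
        if b not in ci:
            raise ValidationError(f"label {b!r} not in the given column order")
        counts[ri[a], ci[b]] += 1
    return ContingencyTable(counts, tuple(str(r) for r in rows), tuple(str(c) for c in cols))


def adjusted_rand_index(table: ContingencyTable) -> float:
    """Hubert–Arabie ARI from a contingency table, in [−1, 1].

    Computed with exact integer/rational arithmetic before the final float
    conversion.  Degenerate case (Max == Expected, e.g. both partitions a
    single block): 1.0 when Index equals them, else 0.0.
    """
    n = table.n
    if n < 2:
        raise ValidationError("ARI needs at least 2 items")
    index = sum(comb(int(v), 2) for v in table.counts.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.row_margins)
    sum_b = sum(comb(int(v), 2) for v in table.col_margins)
    expected = Fraction(sum_a * sum_b, comb(n, 2))
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        return 1.0 if index == expected else 0.0
    return float(Fraction(index - expected) / (max_index - expected))


def ari_from_labels(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float:
    """Convenience: contingency table + ARI in one call."""
    return adjusted_rand_index(build_contingency(labels_a, labels_b))
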