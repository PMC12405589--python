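"""K-Modes clustering over categorical season profiles.

K-Modes (Huang's extension of k-means to categorical data) replaces the
Euclidean distance with simple-matching dissimilarity — the count of
attribute positions at which two rows differ — and replaces the centroid
mean with the component-wise mode.  Lloyd-style alternation between
assignment and mode update monotonically decreases the clustering cost
(the sum of dissimilarities of rows to their assigned modes).

This implementation is deterministic given a seed:

* initialization draws k distinct row indices per restart, seeded from
  ``config.seed + restart_index``;
* a row equidistant to several modes keeps its current cluster when that
  cluster is among the minimizers, otherwise takes the lowest index;
* mode ties within a component resolve to the season earliest in the
  fixed category order (winter, spring, summer, autumn, none);
* a cluster that empties during iteration is reseeded with the row
  farthest from its current mode, keeping the cluster count fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spaq_core import (
    ANALYSIS_ITEMS,
    SEASON_ORDER,
    Season,
    SeasonProfile,
    ValidationError,
)

N_CATEGORIES = len(SEASON_ORDER)


@dataclass(frozen=True)
class CategoricalMatrix:
    """Rectangular matrix of season categories, integer-coded internally.

    ``codes[i, j]`` is the index of the season in :data:`SEASON_ORDER` for
    row ``i`` (participant) and column ``j`` (item).
    """

    row_ids: tuple[str, ...]
    columns: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape != (len(self.row_ids), len(self.columns)):
            raise ValidationError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.columns)} columns"
            )
        if codes.size and (codes.min() < 0 or codes.max() >= N_CATEGORIES):
            raise ValidationError("category codes must be in 0..4")
        object.__setattr__(self, "codes", codes)

    @classmethod
    def from_profiles(
        cls, row_ids: Sequence[str], profiles: Sequence[SeasonProfile]
    ) -> "CategoricalMatrix":
        if len(row_ids) != len(profiles):
            raise ValidationError("row_ids and profiles differ in length")
        codes = np.array(
            [[SEASON_ORDER.index(s) for s in p.as_tuple()] for p in profiles],
            dtype=np.int64,
        ).reshape(len(profiles), len(ANALYSIS_ITEMS))
        return cls(tuple(row_ids), ANALYSIS_ITEMS, codes)

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row_seasons(self, i: int) -> tuple[Season, ...]:
        return tuple(SEASON_ORDER[c] for c in self.codes[i])


@dataclass(frozen=True)
class KModesConfig:
    k: int
    n_restarts: int = 20
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.n_restarts < 1:
            raise ValidationError(f"n_restarts must be >= 1, got {self.n_restarts}")
        if self.max_iterations < 1:
            raise ValidationError(f"max_iterations must be >= 1, got {self.max_iterations}")


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray  # (n,) cluster index per row
    modes: np.ndarray  # (k, n_cols) category codes
    cost: int
    n_iterations: int
    converged: bool
    cost_history: tuple[int, ...] = field(default=())

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    def cluster_sizes(self) -> list[int]:
        return [int((self.labels == j).sum()) for j in range(self.k)]

    def mode_seasons(self, j: int) -> tuple[Season, ...]:
        return tuple(SEASON_ORDER[c] for c in self.modes[j])


def _as_code_row(row) -> np.ndarray:
    arr = np.asarray(
        [SEASON_ORDER.index(x) if isinstance(x, Season) else int(x) for x in row],
        dtype=np.int64,
    )
    return arr


def matching_dissimilarity(a, b) -> int:
    """Simple-matching dissimilarity: positions at which the rows differ."""
    ca, cb = _as_code_row(a), _as_code_row(b)
    if ca.shape != cb.shape:
        raise ValidationError(f"rows differ in length: {ca.shape[0]} vs {cb.shape[0]}")
    return int((ca != cb).sum())


def clustering_cost(data: CategoricalMatrix, labels, modes) -> int:
    """Σ over rows of the dissimilarity to the assigned mode (pure recompute)."""
    labels = np.asarray(labels, dtype=np.int64)
    modes = np.asarray(modes, dtype=np.int64)
    if labels.shape != (data.n_rows,):
        raise ValidationError("labels length does not match the data")
    if modes.ndim != 2 or modes.shape[1] != len(data.columns):
        raise ValidationError("modes shape does not match the data columns")
    if labels.size and (labels.min() < 0 or labels.max() >= modes.shape[0]):
        raise ValidationError("cluster index out of range")
    return int((data.codes != modes[labels]).sum())


def _column_modes(codes: np.ndarray) -> np.ndarray:
    """Per-column modal category; ties go to the lowest code (fixed order)."""
    out = np.empty(codes.shape[1], dtype=np.int64)
    for j in range(codes.shape[1]):
        counts = np.bincount(codes[:, j], minlength=N_CATEGORIES)
        out[j] = int(np.argmax(counts))  # argmax returns the first maximum
    return out


def _distances(codes: np.ndarray, modes: np.ndarray) -> np.ndarray:
    return (codes[:, None, :] != modes[None, :, :]).sum(axis=2)


def _single_run(
    codes: np.ndarray, k: int, max_iterations: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, int, bool, list[int]]:
    n = codes.shape[0]
    init_rows = rng.choice(n, size=k, replace=False)
    modes = codes[init_rows].copy()
    labels = np.full(n, -1, dtype=np.int64)
    history: list[int] = []
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        d = _distances(codes, modes)
        mind = d.min(axis=1)
        best = d.argmin(axis=1)
        # sticky assignment: keep the current cluster when it ties the minimum
        keep = (labels >= 0) & (d[np.arange(n), np.where(labels >= 0, labels, 0)] == mind)
        new_labels = np.where(keep, labels, best)
        for j in range(k):
            members = codes[new_labels == j]
            if len(members):
                modes[j] = _column_modes(members)
            else:
                # reseed an emptied cluster with the row farthest from its mode
                far = int(np.argmax((codes != modes[j]).sum(axis=1)))
                modes[j] = codes[far]
        history.append(int((codes != modes[new_labels]).sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
    return labels, modes, history[-1], it, converged, history


def fit_kmodes(data: CategoricalMatrix, config: KModesConfig) -> ClusteringResult:
    """Best-of-restarts K-Modes fit.

    Runs ``config.n_restarts`` seeded Lloyd-style runs and returns the one
    with the lowest cost (first such run on ties).
    """
    if data.n_rows == 0:
        raise ValidationError("cannot cluster an empty matrix")
    if config.k > data.n_rows:
        raise ValidationError(f"k={config.k} exceeds the number of rows ({data.n_rows})")
    best: ClusteringResult | None = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + r)
        labels, modes, cost, n_iter, converged, history = _single_run(
            data.codes, config.k, config.max_iterations, rng
        )
        if best is None or cost < best.cost:
            best = ClusteringResult(
                labels=labels,
                modes=modes,
                cost=cost,
                n_iterations=n_iter,
                converged=converged,
                cost_history=tuple(history),
            )
    assert best is not None
    return best


def elbow_curve(
    data: CategoricalMatrix, k_max: int, base_config: KModesConfig
) -> list[tuple[int, int]]:
    """Best-of-restarts cost for k = 1..k_max, in ascending k."""
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")
    if k_max > data.n_rows:
        raise ValidationError(f"k_max={k_max} exceeds the number of rows ({data.n_rows})")
    curve = []
    for k in range(1, k_max + 1):
        cfg = KModesConfig(
            k=k,
            n_restarts=base_config.n_restarts,
            max_iterations=base_config.max_iterations,
            seed=base_config.seed,
        )
        curve.append((k, fit_kmodes(data, cfg).cost))
    return curve


def winter_cluster_index(result: ClusteringResult) -> int:
    """Index of the cluster to report as the winter-type cluster.

    The cluster whose mode contains more WINTER components wins; ties go to
    the larger cluster, then to the lower index.
    """
    winter_code = SEASON_ORDER.index(Season.WINTER)
    n_winter = (result.modes == winter_code).sum(axis=1)
    sizes = np.asarray(result.cluster_sizes())
    order = sorted(
        range(result.k), key=lambda j: (-int(n_winter[j]), -int(sizes[j]), j)
    )
    return order[0]
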