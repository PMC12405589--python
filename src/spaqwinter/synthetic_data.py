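"""Seeded synthetic SPAQ cohort generator.

Emulates a mood-disorder cohort in which roughly a fifth of participants
screen in as SAD/S-SAD, and the screened subset hides a two-subtype
structure: a *winter-type* majority that concentrates winter responses
across all four analysis items, and an *other* minority answering mostly
summer or "no particular month".  Default sizes follow the study cohort
the pipeline is modelled on: 495 recruited, ~96 screened, ~70/26
winter/other among the screened.

Each participant is generated as:

1. draw seasonal status (Bernoulli, ``screened_fraction_target``), then —
   if seasonal — the winter subtype (Bernoulli, ``winter_prevalence``);
2. draw the six domain scores and impairment from the group's score
   distributions (seasonal groups are parameterized to pass the Kasper
   screen with high probability, non-seasonal ones to fail);
3. for each analysis item, draw a season from the subtype's categorical
   concentration, then uniform month(s) within that Korea-mapped season
   (NONE → empty set with the explicit flag).

Everything is reproducible from ``config.seed``.  The latent subtype is
kept separate from the observable record, so recovery of the latent
structure by the pipeline is a measurable property, not an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .spaq_core import (
    ANALYSIS_ITEMS,
    SEASON_MONTHS,
    SEASON_ORDER,
    Season,
    SPAQRecord,
    ValidationError,
    classify_kasper_diagnosis,
    compute_gss,
)


class LatentSubtype(str, Enum):
    WINTER_TYPE = "winter-type"
    OTHER = "other"
    NON_SEASONAL = "non-seasonal"


#: Per-item season concentrations (winter, spring, summer, autumn, none).
#: Winter-type concentrates on winter; the other seasonal subtype on
#: summer/none; non-seasonal participants mostly have no particular month.
DEFAULT_CONCENTRATIONS: dict[LatentSubtype, tuple[float, ...]] = {
    LatentSubtype.WINTER_TYPE: (0.70, 0.05, 0.10, 0.05, 0.10),
    LatentSubtype.OTHER: (0.05, 0.05, 0.45, 0.05, 0.40),
    LatentSubtype.NON_SEASONAL: (0.05, 0.05, 0.20, 0.05, 0.65),
}


@dataclass(frozen=True)
class ScoreParams:
    """Distributions of the six 0–4 domain scores and 0–5 impairment."""

    domain_pmf: tuple[float, ...]
    impairment_pmf: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_pmf(self.domain_pmf, 5, "domain_pmf")
        _check_pmf(self.impairment_pmf, 6, "impairment_pmf")


def _check_pmf(p, size: int, name: str) -> None:
    p = tuple(p)
    if len(p) != size:
        raise ValidationError(f"{name}: expected {size} probabilities, got {len(p)}")
    if any(x < 0 or x > 1 for x in p):
        raise ValidationError(f"{name}: probabilities must be in [0, 1]")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities must sum to 1, got {sum(p)}")


#: Seasonal scores centred at 2–3 (GSS ≈ 15 ± 2.6, screen pass ≈ 98%);
#: non-seasonal centred at 0–1 (GSS ≈ 4.4 ± 2.2, screen pass ≈ 1%).
DEFAULT_SEASONAL_SCORES = ScoreParams(
    domain_pmf=(0.05, 0.10, 0.30, 0.35, 0.20),
    impairment_pmf=(0.05, 0.10, 0.30, 0.30, 0.15, 0.10),
)
DEFAULT_NON_SEASONAL_SCORES = ScoreParams(
    domain_pmf=(0.50, 0.32, 0.13, 0.04, 0.01),
    impairment_pmf=(0.55, 0.25, 0.12, 0.05, 0.02, 0.01),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort draw."""

    n_total: int = 495
    screened_fraction_target: float = 96 / 495
    winter_prevalence: float = 70 / 96
    item_concentration: dict[LatentSubtype, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS)
    )
    seasonal_scores: ScoreParams = DEFAULT_SEASONAL_SCORES
    non_seasonal_scores: ScoreParams = DEFAULT_NON_SEASONAL_SCORES
    max_months_per_item: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError(f"n_total must be >= 1, got {self.n_total}")
        for name, p in (
            ("screened_fraction_target", self.screened_fraction_target),
            ("winter_prevalence", self.winter_prevalence),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for subtype in LatentSubtype:
            if subtype not in self.item_concentration:
                raise ValidationError(f"item_concentration missing subtype {subtype.value}")
            _check_pmf(self.item_concentration[subtype], 5, f"item_concentration[{subtype.value}]")
        if self.max_months_per_item < 1:
            raise ValidationError("max_months_per_item must be >= 1")


@dataclass(frozen=True)
class SyntheticCohort:
    records: tuple[SPAQRecord, ...]
    latent_subtype: tuple[LatentSubtype, ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.latent_subtype):
            raise ValidationError("records and latent labels differ in length")

    def __len__(self) -> int:
        return len(self.records)


def _draw_months(
    rng: np.random.Generator, pmf: tuple[float, ...], max_months: int
) -> tuple[frozenset[int], bool]:
    season = SEASON_ORDER[int(rng.choice(5, p=np.asarray(pmf)))]
    if season == Season.NONE:
        return frozenset(), True
    pool = SEASON_MONTHS[season]
    n_months = 1 if max_months == 1 else int(rng.integers(1, min(max_months, len(pool)) + 1))
    months = rng.choice(len(pool), size=n_months, replace=False)
    return frozenset(pool[i] for i in months), False


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full (unscreened) cohort with latent ground truth."""
    rng = np.random.default_rng(config.seed)
    records: list[SPAQRecord] = []
    latents: list[LatentSubtype] = []
    width = max(4, len(str(config.n_total)))
    for i in range(config.n_total):
        seasonal = rng.random() < config.screened_fraction_target
        if seasonal:
            subtype = (
                LatentSubtype.WINTER_TYPE
                if rng.random() < config.winter_prevalence
                else LatentSubtype.OTHER
            )
            scores = config.seasonal_scores
        else:
            subtype = LatentSubtype.NON_SEASONAL
            scores = config.non_seasonal_scores
        domain = tuple(
            int(rng.choice(5, p=np.asarray(scores.domain_pmf))) for _ in range(6)
        )
        impairment = int(rng.choice(6, p=np.asarray(scores.impairment_pmf)))
        months: dict[str, frozenset[int]] = {}
        flags: dict[str, bool] = {}
        pmf = config.item_concentration[subtype]
        for item in ANALYSIS_ITEMS:
            months[item], flags[item] = _draw_months(rng, pmf, config.max_months_per_item)
        records.append(
            SPAQRecord(
                participant_id=f"P{i + 1:0{width}d}",
                item_months=months,
                no_month_flags=flags,
                domain_scores=domain,
                impairment=impairment,
            )
        )
        latents.append(subtype)
    return SyntheticCohort(records=tuple(records), latent_subtype=tuple(latents))


def generate_screened_subset(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort and keep only the SAD / S-SAD screen-positive records."""
    cohort = generate_cohort(config)
    keep = [
        i
        for i, r in enumerate(cohort.records)
        if classify_kasper_diagnosis(compute_gss(r.domain_scores), r.impairment).screened_in
    ]
    return SyntheticCohort(
        records=tuple(cohort.records[i] for i in keep),
        latent_subtype=tuple(cohort.latent_subtype[i] for i in keep),
    )
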