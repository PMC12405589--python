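"""Core SPAQ domain model.

The Seasonal Pattern Assessment Questionnaire (SPAQ) asks, among other things:

* Question 1 — in which month(s) each of several mood/behaviour extremes
  occurs (e.g. "feel worst", "sleep most"), or "no particular month";
* Question 2 — six 0–4 change scores (sleep length, social activity, mood,
  weight, appetite, energy) whose sum is the Global Seasonality Score (GSS,
  range 0–24);
* Question 3 — a 0–5 rating of how much seasonal change impairs the
  respondent (none … disabling).

Kasper's screening rules combine the GSS and the impairment rating into
SAD / subsyndromal-SAD (S-SAD) / non-seasonal labels, and assign a season
*type* from the calendar months ticked for "feel worst" (Dec/Jan/Feb →
winter type, Jun/Jul/Aug → summer type).

For subtype clustering in a Korean climate, months are instead collapsed to
seasons with locally adapted boundaries: winter Nov–Mar, summer May–Sep,
spring = April, autumn = October.  Four Question-1 items are retained for
the analysis: "feel worst", "gain most weight", "sleep most",
"socialize least".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class ValidationError(ValueError):
    """Raised when a SPAQ record or a scalar input violates its contract."""


class Season(str, Enum):
    """Five-level season category used for the four analysis items."""

    WINTER = "winter"
    SPRING = "spring"
    SUMMER = "summer"
    AUTUMN = "autumn"
    NONE = "none"


#: Fixed category order; also the deterministic tie-break order wherever a
#: single season must be picked among equals (mode ties, reporting).
SEASON_ORDER: tuple[Season, ...] = (
    Season.WINTER,
    Season.SPRING,
    Season.SUMMER,
    Season.AUTUMN,
    Season.NONE,
)
SEASON_CODE: dict[Season, int] = {s: i for i, s in enumerate(SEASON_ORDER)}

#: The four Question-1 items retained for subtype analysis, in fixed order.
ANALYSIS_ITEMS: tuple[str, ...] = (
    "feel_worst",
    "gain_most_weight",
    "sleep_most",
    "socialize_least",
)

#: The six Question-2 domains summed into the GSS.
DOMAIN_NAMES: tuple[str, ...] = (
    "sleep_length",
    "social_activity",
    "mood",
    "weight",
    "appetite",
    "energy",
)

# Korea-adapted month->season boundaries.
KOREA_WINTER_MONTHS = frozenset({11, 12, 1, 2, 3})
KOREA_SUMMER_MONTHS = frozenset({5, 6, 7, 8, 9})
#: Calendar triplets used by Kasper's season type (NOT the Korea mapping).
KASPER_WINTER_MONTHS = frozenset({12, 1, 2})
KASPER_SUMMER_MONTHS = frozenset({6, 7, 8})

#: Months of each Korea-mapped season (for sampling and round-trips).
SEASON_MONTHS: dict[Season, tuple[int, ...]] = {
    Season.WINTER: (11, 12, 1, 2, 3),
    Season.SPRING: (4,),
    Season.SUMMER: (5, 6, 7, 8, 9),
    Season.AUTUMN: (10,),
}


class DiagnosisLabel(str, Enum):
    SAD = "SAD"
    S_SAD = "S-SAD"
    NON_SEASONAL = "non-seasonal"


class SeasonTypeLabel(str, Enum):
    """Kasper season type from the calendar 'feel worst' months."""

    WINTER = "winter"
    SUMMER = "summer"
    OTHER = "other"


def _check_months(months: Iterable[int], where: str = "months") -> frozenset[int]:
    months = frozenset(months)
    bad = sorted(m for m in months if not (isinstance(m, int) and 1 <= m <= 12))
    if bad:
        raise ValidationError(f"{where}: month numbers must be in 1..12, got {bad}")
    return months


@dataclass(frozen=True)
class SPAQRecord:
    """One participant's SPAQ responses (the fields this analysis uses).

    Parameters
    ----------
    participant_id
        Opaque identifier, unique within a cohort.
    item_months
        For each analysis item, the set of month numbers (1–12) ticked;
        may be empty.
    no_month_flags
        For each analysis item, whether "no particular month" was ticked
        explicitly.  If true the month set must be empty.
    domain_scores
        The six Question-2 change scores, each 0–4, in :data:`DOMAIN_NAMES`
        order.
    impairment
        Question-3 impairment rating, 0–5.
    """

    participant_id: str
    item_months: Mapping[str, frozenset[int]]
    no_month_flags: Mapping[str, bool]
    domain_scores: tuple[int, ...]
    impairment: int

    def __post_init__(self) -> None:
        pid = self.participant_id
        if not pid:
            raise ValidationError("participant_id must be a non-empty string")
        for mapping, what in ((self.item_months, "item_months"), (self.no_month_flags, "no_month_flags")):
            missing = set(ANALYSIS_ITEMS) - set(mapping)
            extra = set(mapping) - set(ANALYSIS_ITEMS)
            if missing or extra:
                raise ValidationError(
                    f"{pid}: {what} must have exactly the items {ANALYSIS_ITEMS}; "
                    f"missing={sorted(missing)} extra={sorted(extra)}"
                )
        norm = {}
        for item in ANALYSIS_ITEMS:
            months = _check_months(self.item_months[item], f"{pid}:{item}")
            if self.no_month_flags[item] and months:
                raise ValidationError(
                    f"{pid}:{item}: 'no particular month' flag set but months {sorted(months)} given"
                )
            norm[item] = months
        object.__setattr__(self, "item_months", norm)
        validate_domain_scores(self.domain_scores, where=pid)
        if not (isinstance(self.impairment, int) and 0 <= self.impairment <= 5):
            raise ValidationError(f"{pid}: impairment must be an integer in 0..5, got {self.impairment!r}")

    @property
    def gss(self) -> int:
        return compute_gss(self.domain_scores)


@dataclass(frozen=True)
class SeasonProfile:
    """The four analysis items mapped to five-level season categories."""

    items: Mapping[str, Season]

    def __post_init__(self) -> None:
        if tuple(sorted(self.items)) != tuple(sorted(ANALYSIS_ITEMS)):
            raise ValidationError(
                f"SeasonProfile needs exactly the items {ANALYSIS_ITEMS}, got {sorted(self.items)}"
            )
        for item, season in self.items.items():
            if not isinstance(season, Season):
                raise ValidationError(f"{item}: category must be a Season, got {season!r}")

    def __getitem__(self, item: str) -> Season:
        return self.items[item]

    def as_tuple(self) -> tuple[Season, ...]:
        """Categories in :data:`ANALYSIS_ITEMS` order."""
        return tuple(self.items[item] for item in ANALYSIS_ITEMS)


@dataclass(frozen=True)
class KasperDiagnosis:
    label: DiagnosisLabel
    gss: int
    impairment: int

    @property
    def screened_in(self) -> bool:
        """True when the respondent meets SAD or S-SAD criteria."""
        return self.label in (DiagnosisLabel.SAD, DiagnosisLabel.S_SAD)


def validate_domain_scores(scores, where: str = "domain_scores") -> tuple[int, ...]:
    scores = tuple(scores)
    if len(scores) != len(DOMAIN_NAMES):
        raise ValidationError(f"{where}: expected {len(DOMAIN_NAMES)} domain scores, got {len(scores)}")
    for name, s in zip(DOMAIN_NAMES, scores):
        if not (isinstance(s, int) and 0 <= s <= 4):
            raise ValidationError(f"{where}: domain score '{name}' must be an integer in 0..4, got {s!r}")
    return scores


def compute_gss(domain_scores: Iterable[int]) -> int:
    """Global Seasonality Score: the sum of the six 0–4 domain scores (0–24)."""
    return sum(validate_domain_scores(domain_scores))


def classify_kasper_diagnosis(gss: int, impairment: int) -> KasperDiagnosis:
    """Kasper SAD / S-SAD screen from GSS and impairment.

    SAD: GSS >= 11 with impairment >= 2.  S-SAD: GSS of 9 or 10 with
    impairment >= 1, or GSS >= 11 with impairment <= 1.  Everything else is
    non-seasonal.  Thresholds are read inclusively, which is the only
    reading under which the SAD and S-SAD branches partition the GSS >= 11
    region.
    """
    if not (isinstance(gss, int) and 0 <= gss <= 24):
        raise ValidationError(f"gss must be an integer in 0..24, got {gss!r}")
    if not (isinstance(impairment, int) and 0 <= impairment <= 5):
        raise ValidationError(f"impairment must be an integer in 0..5, got {impairment!r}")
    if gss >= 11:
        label = DiagnosisLabel.SAD if impairment >= 2 else DiagnosisLabel.S_SAD
    elif gss >= 9 and impairment >= 1:
        label = DiagnosisLabel.S_SAD
    else:
        label = DiagnosisLabel.NON_SEASONAL
    return KasperDiagnosis(label=label, gss=gss, impairment=impairment)


def map_month_to_season(month: int) -> Season:
    """Korea-adapted month→season mapping (never NONE).

    Winter Nov–Mar, summer May–Sep, spring April, autumn October.
    """
    if not (isinstance(month, int) and 1 <= month <= 12):
        raise ValidationError(f"month must be an integer in 1..12, got {month!r}")
    if month in KOREA_WINTER_MONTHS:
        return Season.WINTER
    if month in KOREA_SUMMER_MONTHS:
        return Season.SUMMER
    return Season.SPRING if month == 4 else Season.AUTUMN


def derive_item_season(months: Iterable[int], no_month_flag: bool = False) -> Season:
    """Collapse one item's month set to a single five-level category.

    An empty set (or an explicit "no particular month") maps to NONE.
    Otherwise the season holding the strict majority of the mapped months
    wins; a tie between seasons also maps to NONE, keeping the rule
    deterministic and symmetric.
    """
    months = _check_months(months)
    if no_month_flag and months:
        raise ValidationError("no_month_flag set but a non-empty month set was given")
    if not months:
        return Season.NONE
    counts: dict[Season, int] = {}
    for m in months:
        s = map_month_to_season(m)
        counts[s] = counts.get(s, 0) + 1
    top = max(counts.values())
    winners = [s for s, c in counts.items() if c == top]
    return winners[0] if len(winners) == 1 else Season.NONE


def derive_season_profile(record: SPAQRecord) -> SeasonProfile:
    """Apply :func:`derive_item_season` to each of the four analysis items."""
    return SeasonProfile(
        items={
            item: derive_item_season(record.item_months[item], record.no_month_flags[item])
            for item in ANALYSIS_ITEMS
        }
    )


def kasper_season_type(feel_worst_months: Iterable[int]) -> SeasonTypeLabel:
    """Kasper season type from the calendar "feel worst" months.

    Winter type when the (non-empty) set lies entirely within Dec/Jan/Feb,
    summer type when entirely within Jun/Jul/Aug, otherwise other.  Uses
    calendar triplets, deliberately NOT the Korea-adapted season mapping.
    """
    months = _check_months(feel_worst_months, "feel_worst_months")
    if months and months <= KASPER_WINTER_MONTHS:
        return SeasonTypeLabel.WINTER
    if months and months <= KASPER_SUMMER_MONTHS:
        return SeasonTypeLabel.SUMMER
    return SeasonTypeLabel.OTHER
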