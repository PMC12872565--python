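"""Core domain types for individual case safety reports (ICSRs).

An ICSR is one spontaneous adverse-drug-reaction report: an opaque case
identifier, reporter/patient metadata, one or more suspect medicinal
products (each a set of active ingredients, so fixed-dose combinations
carry more than one), and one or more coded reactions.  Reactions are
MedDRA preferred terms (PTs), each with a reported clinical outcome.

Outcomes follow the six-level spontaneous-reporting convention; the
"severe" subset — fatal, recovered/resolved with sequelae, and not
recovered/not resolved — is the one used when comparing outcome severity
between exposure groups.
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field


class OutcomeCategory(enum.Enum):
    """Reported outcome of a single reaction, six mutually exclusive levels."""

    FATAL = "Fatal"
    RECOVERED_WITH_SEQUELAE = "Recovered/Resolved with sequelae"
    NOT_RECOVERED = "Not recovered/Not resolved"
    RECOVERING = "Recovering/Resolving"
    RECOVERED = "Recovered/Resolved"
    UNKNOWN = "Not specified/Unknown"

    @classmethod
    def from_label(cls, label: str) -> "OutcomeCategory":
        """Parse a serialized outcome label; unrecognized strings fall back to UNKNOWN."""
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        return cls.UNKNOWN


#: Outcomes counted as severe when comparing groups.
SEVERE_OUTCOMES = frozenset(
    {
        OutcomeCategory.FATAL,
        OutcomeCategory.RECOVERED_WITH_SEQUELAE,
        OutcomeCategory.NOT_RECOVERED,
    }
)


class SourceQualification(enum.Enum):
    HEALTHCARE_PROFESSIONAL = "Healthcare professional"
    NON_HEALTHCARE_PROFESSIONAL = "Non-healthcare professional"
    UNSPECIFIED = "Not specified"

    @classmethod
    def from_label(cls, label: str) -> "SourceQualification":
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        return cls.UNSPECIFIED


class SourceArea(enum.Enum):
    EEA = "EU area"
    NON_EEA = "Non-EU area"
    UNSPECIFIED = "Not specified"

    @classmethod
    def from_label(cls, label: str) -> "SourceArea":
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        return cls.UNSPECIFIED


class AgeGroup(enum.Enum):
    """Patient age band.  Boundaries are closed-open on the printed limits:
    [0, 18), [18, 65), [65, 86), [86, inf) — an 85-year-old is ELDERLY."""

    PEDIATRIC = "Pediatrics (<18 years)"
    ADULT = "Adults (18-64 years)"
    ELDERLY = "Elderly (65-85 years)"
    VERY_ELDERLY = "Very elderly (>85 years)"
    UNSPECIFIED = "Not specified"

    @classmethod
    def from_label(cls, label: str) -> "AgeGroup":
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        return cls.UNSPECIFIED

    @classmethod
    def from_years(cls, years: float | None) -> "AgeGroup":
        if years is None:
            return cls.UNSPECIFIED
        if years < 0:
            raise ValueError(f"negative age: {years}")
        if years < 18:
            return cls.PEDIATRIC
        if years < 65:
            return cls.ADULT
        if years < 86:
            return cls.ELDERLY
        return cls.VERY_ELDERLY


class Sex(enum.Enum):
    FEMALE = "Female"
    MALE = "Male"
    UNSPECIFIED = "Not specified"

    @classmethod
    def from_label(cls, label: str) -> "Sex":
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        return cls.UNSPECIFIED


class ExposureGroup(enum.Enum):
    """Exposure classification of a report given target/comparator ingredient sets.

    NEITHER reports are retained in the dataset but excluded from every
    table and analysis.
    """

    TARGET_ONLY = "target_only"
    COMPARATOR_ONLY = "comparator_only"
    BOTH = "both"
    NEITHER = "neither"


_WS = re.compile(r"\s+")


def normalize_ingredient(raw_name: str) -> str:
    """Normalize an active-ingredient name for exact-token matching.

    Lower-cases, trims, and collapses internal whitespace.  Salt/ester
    suffixes are deliberately NOT stripped: matching is on the exact
    normalized token.

    Raises
    ------
    ValueError
        If the input is empty or whitespace-only.
    """
    name = _WS.sub(" ", raw_name.strip()).lower()
    if not name:
        raise ValueError("ingredient name must be non-empty")
    return name


def is_severe(outcome: OutcomeCategory) -> bool:
    """True iff the outcome is fatal, resolved with sequelae, or not recovered."""
    return outcome in SEVERE_OUTCOMES


@dataclass(frozen=True)
class Reaction:
    """One coded reaction: a MedDRA preferred term plus its reported outcome."""

    pt: str
    outcome: OutcomeCategory = OutcomeCategory.UNKNOWN

    def __post_init__(self) -> None:
        if not self.pt or not self.pt.strip():
            raise ValueError("reaction PT must be non-empty")


@dataclass
class ICSR:
    """One individual case safety report.

    ``suspect_drugs`` is a list of frozensets of normalized ingredient
    names — one set per suspect product, so a combination product
    contributes a multi-ingredient set.
    """

    case_id: str
    source_qualification: SourceQualification = SourceQualification.UNSPECIFIED
    source_area: SourceArea = SourceArea.UNSPECIFIED
    age_group: AgeGroup = AgeGroup.UNSPECIFIED
    sex: Sex = Sex.UNSPECIFIED
    suspect_drugs: list[frozenset[str]] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    receive_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        for product in self.suspect_drugs:
            if not product:
                raise ValueError(
                    f"case {self.case_id}: suspect product with no ingredients"
                )

    @property
    def pts(self) -> set[str]:
        """Distinct preferred terms reported on this case (normalized casing kept)."""
        return {r.pt for r in self.reactions}

    def has_pt(self, pt: str) -> bool:
        key = pt.strip().lower()
        return any(r.pt.strip().lower() == key for r in self.reactions)

    def all_ingredients(self) -> set[str]:
        out: set[str] = set()
        for product in self.suspect_drugs:
            out |= product
        return out
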