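"""Exposure classification and descriptive (demographics) tabulation.

A report is *exposed* to the target (or comparator) drug when any of its
suspect products contains any target (comparator) ingredient, so
fixed-dose combinations count.  Reports exposed to both drugs form their
own group; reports exposed to neither are retained but excluded from
every table and analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._format import format_cell
from .icsr import ICSR, AgeGroup, ExposureGroup, Sex, SourceArea, SourceQualification, normalize_ingredient
from .meddra import UNMAPPED, MedDRAMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureConfig:
    """Target and comparator active-ingredient sets (normalized, disjoint)."""

    target_ingredients: frozenset[str] = frozenset({"bempedoic acid"})
    comparator_ingredients: frozenset[str] = frozenset({"atorvastatin"})

    def __post_init__(self) -> None:
        tgt = frozenset(normalize_ingredient(i) for i in self.target_ingredients)
        cmp_ = frozenset(normalize_ingredient(i) for i in self.comparator_ingredients)
        if not tgt or not cmp_:
            raise ValueError("ingredient sets must be non-empty")
        if tgt & cmp_:
            raise ValueError(f"target/comparator sets overlap: {sorted(tgt & cmp_)}")
        object.__setattr__(self, "target_ingredients", tgt)
        object.__setattr__(self, "comparator_ingredients", cmp_)


@dataclass
class ExposureCohorts:
    """Partition of a deduplicated report set by exposure group."""

    target_only: list[ICSR] = field(default_factory=list)
    comparator_only: list[ICSR] = field(default_factory=list)
    both: list[ICSR] = field(default_factory=list)
    neither: list[ICSR] = field(default_factory=list)

    @property
    def analysis_n(self) -> int:
        """Reports entering any analysis (NEITHER excluded)."""
        return len(self.target_only) + len(self.comparator_only) + len(self.both)

    def group(self, which: ExposureGroup) -> list[ICSR]:
        return {
            ExposureGroup.TARGET_ONLY: self.target_only,
            ExposureGroup.COMPARATOR_ONLY: self.comparator_only,
            ExposureGroup.BOTH: self.both,
            ExposureGroup.NEITHER: self.neither,
        }[which]


def classify_exposure(report: ICSR, config: ExposureConfig) -> ExposureGroup:
    """Exposure group of one report; invariant to product and ingredient order."""
    target = any(
        product & config.target_ingredients for product in report.suspect_drugs
    )
    comparator = any(
        product & config.comparator_ingredients for product in report.suspect_drugs
    )
    if target and comparator:
        return ExposureGroup.BOTH
    if target:
        return ExposureGroup.TARGET_ONLY
    if comparator:
        return ExposureGroup.COMPARATOR_ONLY
    return ExposureGroup.NEITHER


def build_cohorts(reports: list[ICSR], config: ExposureConfig | None = None) -> ExposureCohorts:
    """Partition (deduplicated) reports into the four exposure groups."""
    config = config or ExposureConfig()
    cohorts = ExposureCohorts()
    for report in reports:
        cohorts.group(classify_exposure(report, config)).append(report)
    logger.info(
        "cohorts: target_only=%d comparator_only=%d both=%d neither=%d",
        len(cohorts.target_only),
        len(cohorts.comparator_only),
        len(cohorts.both),
        len(cohorts.neither),
    )
    return cohorts


_COLUMNS = (
    ("Overall", None),
    ("Both", ExposureGroup.BOTH),
    ("Comparator-only", ExposureGroup.COMPARATOR_ONLY),
    ("Target-only", ExposureGroup.TARGET_ONLY),
)

_DEMOGRAPHIC_BLOCKS = (
    (
        "Primary source qualification",
        lambda r: r.source_qualification,
        (
            SourceQualification.HEALTHCARE_PROFESSIONAL,
            SourceQualification.NON_HEALTHCARE_PROFESSIONAL,
            SourceQualification.UNSPECIFIED,
        ),
    ),
    (
        "Primary source country",
        lambda r: r.source_area,
        (SourceArea.EEA, SourceArea.NON_EEA, SourceArea.UNSPECIFIED),
    ),
    (
        "Patient age group",
        lambda r: r.age_group,
        (
            AgeGroup.PEDIATRIC,
            AgeGroup.ADULT,
            AgeGroup.ELDERLY,
            AgeGroup.VERY_ELDERLY,
            AgeGroup.UNSPECIFIED,
        ),
    ),
    ("Patient sex", lambda r: r.sex, (Sex.FEMALE, Sex.MALE, Sex.UNSPECIFIED)),
)


def soc_presence_counts(reports: list[ICSR], meddra: MedDRAMap) -> dict[str, int]:
    """Report-level SOC presence: each report counts once per SOC it touches,
    however many of its PTs map there.  Unmapped PTs fall under the UNMAPPED
    sentinel row (and are logged)."""
    counts: dict[str, int] = {}
    unmapped_pts: set[str] = set()
    for report in reports:
        socs = set()
        for reaction in report.reactions:
            soc = meddra.soc_of(reaction.pt)
            if soc == UNMAPPED:
                unmapped_pts.add(reaction.pt)
            socs.add(soc)
        for soc in socs:
            counts[soc] = counts.get(soc, 0) + 1
    if unmapped_pts:
        logger.warning("unmapped PTs encountered: %s", sorted(unmapped_pts))
    return counts


def demographics_table(cohorts: ExposureCohorts, meddra: MedDRAMap) -> pd.DataFrame:
    """Descriptive summary of the analysis cohorts (NEITHER excluded).

    Tidy frame with one row per (section, level, column): raw ``count``,
    ``percent`` of the column N, and a ``display`` string rendered with
    the registry conventions.  Sections cover source qualification,
    source area, age group, sex, and report-level SOC presence (one row
    per SOC observed anywhere in the analysis set, alphabetical).
    """
    overall = cohorts.target_only + cohorts.comparator_only + cohorts.both
    col_reports = {
        "Overall": overall,
        "Both": cohorts.both,
        "Comparator-only": cohorts.comparator_only,
        "Target-only": cohorts.target_only,
    }
    rows: list[dict] = []

    def add(section: str, level: str, column: str, count: int, total: int) -> None:
        rows.append(
            {
                "section": section,
                "level": level,
                "column": column,
                "count": count,
                "n": total,
                "percent": (100.0 * count / total) if total else 0.0,
                "display": format_cell(count, total) if total else "0 (0%)",
            }
        )

    for column, reports in col_reports.items():
        n = len(reports)
        add("N", "N", column, n, n)
        for section, keyfn, levels in _DEMOGRAPHIC_BLOCKS:
            for level in levels:
                count = sum(1 for r in reports if keyfn(r) is level)
                add(section, level.value, column, count, n)

    per_col_soc = {
        column: soc_presence_counts(reports, meddra)
        for column, reports in col_reports.items()
    }
    all_socs = sorted(set().union(*per_col_soc.values()))
    for column, reports in col_reports.items():
        n = len(reports)
        for soc in all_socs:
            add("Clinical disorder reported", soc, column,
                per_col_soc[column].get(soc, 0), n)

    return pd.DataFrame(rows)


def render_demographics(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy demographics frame to the familiar wide layout."""
    wide = table.pivot_table(
        index=["section", "level"],
        columns="column",
        values="display",
        aggfunc="first",
        sort=False,
    )
    return wide[[c for c, _ in _COLUMNS]]
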