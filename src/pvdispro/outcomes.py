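"""Per-PT outcome distributions and severity summaries.

For each preferred term, the reported outcomes of its reactions are
tabulated over the six outcome categories; the severe fraction is
(fatal + recovered with sequelae + not recovered) / total, always
computed from raw counts rather than from rounded percentage cells.
One (report, PT) pair contributes a single record even if the report
lists the PT twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._format import format_cell
from .cohorts import ExposureCohorts
from .icsr import ICSR, OutcomeCategory, is_severe
from .meddra import MRPTSet, normalize_pt

OUTCOME_ORDER = (
    OutcomeCategory.FATAL,
    OutcomeCategory.RECOVERED_WITH_SEQUELAE,
    OutcomeCategory.NOT_RECOVERED,
    OutcomeCategory.RECOVERING,
    OutcomeCategory.RECOVERED,
    OutcomeCategory.UNKNOWN,
)


@dataclass(frozen=True)
class OutcomeDistribution:
    """Outcome counts for one PT within one report set."""

    pt: str
    counts: dict[OutcomeCategory, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self, outcome: OutcomeCategory) -> float:
        return 100.0 * self.counts[outcome] / self.total if self.total else 0.0


def outcome_distribution(reports: list[ICSR], pt: str) -> OutcomeDistribution:
    """Distribution of outcomes for ``pt`` among ``reports``.

    One record per (report, PT): when a report lists the PT more than
    once, the first reaction's outcome stands for the pair.  A PT absent
    from every report yields an all-zero distribution, not an error.
    """
    key = normalize_pt(pt)
    counts = {cat: 0 for cat in OUTCOME_ORDER}
    for report in reports:
        for reaction in report.reactions:
            if normalize_pt(reaction.pt) == key:
                counts[reaction.outcome] += 1
                break
    return OutcomeDistribution(pt=pt, counts=counts)


def severe_outcome_proportion(distribution: OutcomeDistribution) -> float:
    """Fraction of records with a severe outcome (raw-count arithmetic).

    Raises
    ------
    ValueError
        If the distribution is empty (the proportion is undefined).
    """
    total = distribution.total
    if total == 0:
        raise ValueError(f"no records for PT {distribution.pt!r}: proportion undefined")
    severe = sum(n for cat, n in distribution.counts.items() if is_severe(cat))
    return severe / total


def severity_comparison_table(
    cohorts: ExposureCohorts, mrpts: MRPTSet | None = None
) -> pd.DataFrame:
    """Cross-group severity table for every muscle-related PT.

    Tidy frame with one row per (pt, group, row) where ``row`` is either
    ``TOTAL`` (PT record count, percentage of the group size) or one of
    the six outcome labels (percentage of the PT row total).  The severe
    proportion per (pt, group) rides along on the TOTAL rows.
    """
    mrpts = mrpts or MRPTSet()
    overall = cohorts.target_only + cohorts.comparator_only + cohorts.both
    groups = {
        "Overall": overall,
        "Both": cohorts.both,
        "Comparator-only": cohorts.comparator_only,
        "Target-only": cohorts.target_only,
    }
    rows: list[dict] = []
    for pt in mrpts:
        for group, reports in groups.items():
            dist = outcome_distribution(reports, pt)
            total = dist.total
            rows.append(
                {
                    "pt": pt,
                    "group": group,
                    "row": "TOTAL",
                    "count": total,
                    "denominator": len(reports),
                    "display": format_cell(total, len(reports)) if reports else "0 (0%)",
                    "severe_proportion": (
                        severe_outcome_proportion(dist) if total else float("nan")
                    ),
                }
            )
            for cat in OUTCOME_ORDER:
                rows.append(
                    {
                        "pt": pt,
                        "group": group,
                        "row": cat.value,
                        "count": dist.counts[cat],
                        "denominator": total,
                        "display": format_cell(dist.counts[cat], total)
                        if total
                        else "0 (0%)",
                        "severe_proportion": float("nan"),
                    }
                )
    return pd.DataFrame(rows)
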