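"""Reporting odds ratio (ROR) disproportionality statistics.

The ROR contrasts how often an event is reported under a target drug
versus a comparator in a spontaneous-reporting database.  For the
report-level 2x2 table

    ==============  =======  =========
    .               event    no event
    ==============  =======  =========
    target          a        b
    comparator      c        d
    ==============  =======  =========

ROR = (a/b) / (c/d), with a 95% confidence interval from the Woolf
(log-normal) approximation exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))
and a Pearson chi-squared test of association (df = 1, two-sided,
no continuity correction by default).

Zero cells make the ROR or its variance undefined; the default policy is
the Haldane–Anscombe correction (+0.5 to all four cells before every
computation), flagged on the result so downstream tables can annotate it.
An ROR is a reporting-disproportionality signal statistic, not a risk or
incidence estimate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterable

from scipy.special import chdtrc

from .cohorts import ExposureCohorts
from .icsr import ICSR
from .meddra import MedDRAMap, MRPTSet, normalize_pt

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


class ZeroCellPolicy(enum.Enum):
    HALDANE_HALF = "haldane_half"
    ERROR = "error"


class DegenerateCohortError(ValueError):
    """An analysis cohort is empty, so no 2x2 table can be formed."""


class ZeroCellError(ValueError):
    """A zero cell was met under the strict zero-cell policy."""


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level event-by-exposure 2x2 counts."""

    a: int  # target reports with the event
    b: int  # target reports without the event
    c: int  # comparator reports with the event
    d: int  # comparator reports without the event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exchange the exposure rows (target <-> comparator)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RORResult:
    """ROR point estimate with Woolf CI and Pearson chi-squared test."""

    event_label: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    zero_cell_corrected: bool = False
    low_count_flag: bool = False  # a < 3: too few target events to interpret

    @property
    def significant(self) -> bool:
        """CI excludes 1 (the conventional screening criterion)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def _pearson_chi2(a: float, b: float, c: float, d: float, yates: bool) -> float:
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def ror(
    table: ContingencyTable,
    event_label: str = "",
    z: float = Z_95,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE_HALF,
    yates: bool = False,
) -> RORResult:
    """Compute the ROR, Woolf CI and chi-squared test for one 2x2 table.

    With any zero cell, ``HALDANE_HALF`` adds 0.5 to all four cells
    before *all* computations (point estimate, CI and chi-squared) and
    sets ``zero_cell_corrected``; ``ERROR`` raises :class:`ZeroCellError`.
    ``low_count_flag`` marks a < 3 on the *uncorrected* table.
    """
    if table.n_target == 0 or table.n_comparator == 0:
        raise DegenerateCohortError(
            f"{event_label or 'table'}: empty exposure row ({table})"
        )
    corrected = 0 in (table.a, table.b, table.c, table.d)
    if corrected and zero_cell_policy is ZeroCellPolicy.ERROR:
        raise ZeroCellError(f"{event_label or 'table'}: zero cell in {table}")
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (
        table.a + shift,
        table.b + shift,
        table.c + shift,
        table.d + shift,
    )
    estimate = (a / b) / (c / d)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    chi2 = _pearson_chi2(a, b, c, d, yates=yates)
    return RORResult(
        event_label=event_label,
        table=table,
        ror=estimate,
        ci_low=estimate * math.exp(-z * se_log),
        ci_high=estimate * math.exp(z * se_log),
        chi2=chi2,
        p_value=float(chdtrc(1, chi2)),
        zero_cell_corrected=corrected,
        low_count_flag=table.a < 3,
    )


def build_contingency(
    exposed: list[ICSR],
    reference: list[ICSR],
    event_test: Callable[[ICSR], bool],
) -> ContingencyTable:
    """Report-level 2x2 for an arbitrary event predicate.

    For a SOC the predicate is "the report has >=1 PT mapping to that
    SOC"; for a PT, "the report has >=1 reaction with that PT".
    """
    if not exposed or not reference:
        raise DegenerateCohortError("exposed and reference cohorts must be non-empty")
    a = sum(1 for r in exposed if event_test(r))
    c = sum(1 for r in reference if event_test(r))
    return ContingencyTable(a=a, b=len(exposed) - a, c=c, d=len(reference) - c)


def _soc_tables(
    exposed: list[ICSR], reference: list[ICSR], meddra: MedDRAMap
) -> dict[str, ContingencyTable]:
    if not exposed or not reference:
        raise DegenerateCohortError("exposed and reference cohorts must be non-empty")
    counts: dict[str, list[int]] = {}
    for idx, cohort in enumerate((exposed, reference)):
        for report in cohort:
            for soc in {meddra.soc_of(rx.pt) for rx in report.reactions}:
                counts.setdefault(soc, [0, 0])[idx] += 1
    return {
        soc: ContingencyTable(
            a=ac[0], b=len(exposed) - ac[0], c=ac[1], d=len(reference) - ac[1]
        )
        for soc, ac in counts.items()
    }


def analyze_by_soc(
    cohorts: ExposureCohorts,
    meddra: MedDRAMap,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE_HALF,
    yates: bool = False,
) -> list[RORResult]:
    """One ROR per SOC observed in either analysis cohort, descending ROR.

    Target-only vs comparator-only; dual-exposure (BOTH) reports are
    excluded.  SOCs absent from both cohorts never appear (a = c = 0
    cannot arise).
    """
    tables = _soc_tables(cohorts.target_only, cohorts.comparator_only, meddra)
    results = [
        ror(t, event_label=soc, zero_cell_policy=zero_cell_policy, yates=yates)
        for soc, t in tables.items()
    ]
    return sorted(results, key=lambda r: r.ror, reverse=True)


def analyze_mr_pts(
    cohorts: ExposureCohorts,
    mrpts: MRPTSet | None = None,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE_HALF,
    yates: bool = False,
) -> list[RORResult]:
    """One ROR per muscle-related PT with at least one event in either cohort.

    PTs with events in only one cohort get the configured zero-cell
    handling and come back flagged; PTs with no events anywhere are
    omitted.  Sorted by descending ROR.
    """
    mrpts = mrpts or MRPTSet()
    exposed, reference = cohorts.target_only, cohorts.comparator_only
    if not exposed or not reference:
        raise DegenerateCohortError("exposed and reference cohorts must be non-empty")
    # Normalize once per report so spelling variants match the PT set.
    exposed_pts = [{normalize_pt(p) for p in r.pts} for r in exposed]
    reference_pts = [{normalize_pt(p) for p in r.pts} for r in reference]
    results = []
    for pt in mrpts:
        key = normalize_pt(pt)
        a = sum(1 for pts in exposed_pts if key in pts)
        c = sum(1 for pts in reference_pts if key in pts)
        if a + c == 0:
            continue
        table = ContingencyTable(a=a, b=len(exposed) - a, c=c, d=len(reference) - c)
        results.append(
            ror(table, event_label=pt, zero_cell_policy=zero_cell_policy, yates=yates)
        )
    return sorted(results, key=lambda r: r.ror, reverse=True)


def results_frame(results: Iterable[RORResult]):
    """Flatten results to a DataFrame ready for delimited-text output."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "event_label": r.event_label,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "zero_cell_corrected": r.zero_cell_corrected,
                "low_count_flag": r.low_count_flag,
            }
            for r in results
        ]
    )
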