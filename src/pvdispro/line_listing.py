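"""Reading and writing delimited-text ICSR line listings.

The input dialect mirrors the "line listing" exports of the European
public adverse-reaction portal (adrreports.eu): one row per report (or
per report-reaction pair), a configurable delimiter, and cells that may
hold several values separated by a multi-value separator.  Suspect
products within one cell are separated by the multi-value separator;
ingredients within one combination product by ``ingredient_separator``
(e.g. ``bempedoic acid + ezetimibe``).

Rows sharing a case identifier are merged into a single report (union
of suspect products, concatenation of reactions).  All categorical
fields parse fail-soft: unrecognized strings become the UNSPECIFIED /
UNKNOWN level with a log record, never an exception, because registry
exports are dirty and a single malformed cell must not abort a run.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .icsr import (
    ICSR,
    AgeGroup,
    OutcomeCategory,
    Reaction,
    Sex,
    SourceArea,
    SourceQualification,
    normalize_ingredient,
)

logger = logging.getLogger(__name__)

LOGICAL_FIELDS = (
    "case_id",
    "qualification",
    "country",
    "age_group",
    "sex",
    "suspect_drug",
    "reaction_pt",
    "outcome",
)

#: EEA member-state ISO-3166 alpha-2 codes (EU-27 + IS, LI, NO).
DEFAULT_EEA_CODES = frozenset(
    """AT BE BG HR CY CZ DK EE FI FR DE GR HU IE IT LV LT LU MT NL PL PT RO
    SK SI ES SE IS LI NO""".split()
)


class LineListingFormatError(ValueError):
    """The file does not conform to the declared dialect."""


@dataclass(frozen=True)
class LineListingDialect:
    """Column layout and separators of one line-listing export flavour."""

    delimiter: str = ","
    multivalue_separator: str = ";"
    ingredient_separator: str = "+"
    column_map: dict[str, str] = field(
        default_factory=lambda: {
            "case_id": "EU Local Number",
            "qualification": "Primary Source Qualification",
            "country": "Primary Source Country for Regulatory Purposes",
            "age_group": "Patient Age Group",
            "sex": "Patient Sex",
            "suspect_drug": "Suspect Drug List",
            "reaction_pt": "Reaction PT",
            "outcome": "Reaction Outcome",
        }
    )
    #: Optional: column holding the gateway receipt date (ISO format).
    receive_date_column: str | None = "Receive Date"

    def __post_init__(self) -> None:
        missing = [f for f in LOGICAL_FIELDS if f not in self.column_map]
        if missing:
            raise ValueError(f"column_map missing logical fields: {missing}")
        if self.delimiter == self.multivalue_separator:
            raise ValueError("delimiter and multivalue_separator must differ")


DEFAULT_DIALECT = LineListingDialect()

# Portal exports label age bands several ways; fold the common spellings.
_AGE_SYNONYMS = {
    "<18": AgeGroup.PEDIATRIC,
    "0-17 years": AgeGroup.PEDIATRIC,
    "pediatrics (<18 years)": AgeGroup.PEDIATRIC,
    "18-64 years": AgeGroup.ADULT,
    "adults (18-64 years)": AgeGroup.ADULT,
    "65-85 years": AgeGroup.ELDERLY,
    "elderly (65-85 years)": AgeGroup.ELDERLY,
    ">85": AgeGroup.VERY_ELDERLY,
    "more than 85 years": AgeGroup.VERY_ELDERLY,
    "very elderly (>85 years)": AgeGroup.VERY_ELDERLY,
}


def _parse_age_group(label: str) -> AgeGroup:
    key = " ".join(label.strip().lower().split())
    if key in _AGE_SYNONYMS:
        return _AGE_SYNONYMS[key]
    return AgeGroup.from_label(label)


def _split_cell(cell: str, sep: str) -> list[str]:
    if not cell or not cell.strip():
        return []
    return [part.strip() for part in cell.split(sep) if part.strip()]


def _parse_products(cell: str, dialect: LineListingDialect) -> list[frozenset[str]]:
    products = []
    for product in _split_cell(cell, dialect.multivalue_separator):
        ingredients = frozenset(
            normalize_ingredient(i)
            for i in _split_cell(product, dialect.ingredient_separator)
        )
        if ingredients:
            products.append(ingredients)
    return products


def _parse_date(cell: object) -> _dt.date | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    try:
        return _dt.date.fromisoformat(text[:10])
    except ValueError:
        logger.warning("unparseable receive date %r; treated as missing", text)
        return None


def read_line_listing(
    path: str | Path,
    dialect: LineListingDialect = DEFAULT_DIALECT,
    eea_country_codes: frozenset[str] | set[str] = DEFAULT_EEA_CODES,
) -> list[ICSR]:
    """Parse a line-listing file into one ICSR per distinct case identifier.

    Source area is derived from the country column via ``eea_country_codes``
    (blank country -> UNSPECIFIED).  Reports whose reaction list is empty
    after parsing are dropped with a warning — they cannot enter any 2x2
    table.

    Raises
    ------
    LineListingFormatError
        If a mapped column is absent from the header.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing = [
        col for col in dialect.column_map.values() if col not in df.columns
    ]
    if missing:
        raise LineListingFormatError(
            f"{path}: missing mapped column(s) {missing}; header is {list(df.columns)}"
        )
    eea = {c.strip().upper() for c in eea_country_codes}
    cm = dialect.column_map
    has_date = (
        dialect.receive_date_column is not None
        and dialect.receive_date_column in df.columns
    )

    by_case: dict[str, ICSR] = {}
    n_skipped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        record = dict(zip(df.columns, row))
        case_id = str(record[cm["case_id"]]).strip()
        if not case_id:
            n_skipped += 1
            logger.warning("%s: row %d has no case identifier; skipped", path, idx)
            continue
        country = str(record[cm["country"]]).strip().upper()
        if not country:
            area = SourceArea.UNSPECIFIED
        elif country in eea:
            area = SourceArea.EEA
        else:
            area = SourceArea.NON_EEA
        pts = _split_cell(str(record[cm["reaction_pt"]]), dialect.multivalue_separator)
        outcomes = _split_cell(str(record[cm["outcome"]]), dialect.multivalue_separator)
        reactions = [
            Reaction(
                pt=pt,
                outcome=OutcomeCategory.from_label(outcomes[i])
                if i < len(outcomes)
                else OutcomeCategory.UNKNOWN,
            )
            for i, pt in enumerate(pts)
        ]
        report = ICSR(
            case_id=case_id,
            source_qualification=SourceQualification.from_label(
                str(record[cm["qualification"]])
            ),
            source_area=area,
            age_group=_parse_age_group(str(record[cm["age_group"]])),
            sex=Sex.from_label(str(record[cm["sex"]])),
            suspect_drugs=_parse_products(str(record[cm["suspect_drug"]]), dialect),
            reactions=reactions,
            receive_date=_parse_date(record[dialect.receive_date_column])
            if has_date
            else None,
        )
        existing = by_case.get(case_id)
        if existing is None:
            by_case[case_id] = report
        else:
            _merge_into(existing, report)

    reports = [r for r in by_case.values() if r.reactions]
    dropped = len(by_case) - len(reports)
    if dropped:
        logger.warning("%s: dropped %d report(s) with no parseable reaction", path, dropped)
    if n_skipped:
        logger.warning("%s: skipped %d unreadable row(s)", path, n_skipped)
    return reports


def _merge_into(target: ICSR, other: ICSR) -> None:
    """Merge a same-case row into an accumulating report in place."""
    for product in other.suspect_drugs:
        if product not in target.suspect_drugs:
            target.suspect_drugs.append(product)
    target.reactions.extend(other.reactions)
    if target.source_qualification is SourceQualification.UNSPECIFIED:
        target.source_qualification = other.source_qualification
    if target.source_area is SourceArea.UNSPECIFIED:
        target.source_area = other.source_area
    if target.age_group is AgeGroup.UNSPECIFIED:
        target.age_group = other.age_group
    if target.sex is Sex.UNSPECIFIED:
        target.sex = other.sex
    if target.receive_date is None:
        target.receive_date = other.receive_date


def write_reports(
    reports: list[ICSR],
    path: str | Path,
    dialect: LineListingDialect = DEFAULT_DIALECT,
    eea_country_codes: frozenset[str] | set[str] = DEFAULT_EEA_CODES,
) -> None:
    """Write reports as a line listing, one row per (report, reaction).

    The round trip ``read_line_listing(write_reports(x))`` reproduces the
    reports up to reaction order.  Source area is serialized back to a
    representative country code (first EEA code for EEA reports, "US" for
    non-EEA, blank for unspecified) since the logical field is the area.
    """
    cm = dialect.column_map
    eea_repr = sorted(c.strip().upper() for c in eea_country_codes)[0] if eea_country_codes else "DE"
    area_to_country = {
        SourceArea.EEA: eea_repr,
        SourceArea.NON_EEA: "US",
        SourceArea.UNSPECIFIED: "",
    }
    rows = []
    for report in reports:
        drug_cell = dialect.multivalue_separator.join(
            f" {dialect.ingredient_separator} ".join(sorted(product))
            for product in report.suspect_drugs
        )
        base = {
            cm["case_id"]: report.case_id,
            cm["qualification"]: report.source_qualification.value,
            cm["country"]: area_to_country[report.source_area],
            cm["age_group"]: report.age_group.value,
            cm["sex"]: report.sex.value,
            cm["suspect_drug"]: drug_cell,
        }
        if dialect.receive_date_column:
            base[dialect.receive_date_column] = (
                report.receive_date.isoformat() if report.receive_date else ""
            )
        if not report.reactions:
            rows.append({**base, cm["reaction_pt"]: "", cm["outcome"]: ""})
        for reaction in report.reactions:
            rows.append(
                {
                    **base,
                    cm["reaction_pt"]: reaction.pt,
                    cm["outcome"]: reaction.outcome.value,
                }
            )
    columns = [
        cm["case_id"],
        cm["qualification"],
        cm["country"],
        cm["age_group"],
        cm["sex"],
        cm["suspect_drug"],
        cm["reaction_pt"],
        cm["outcome"],
    ]
    if dialect.receive_date_column:
        columns.append(dialect.receive_date_column)
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep=dialect.delimiter, index=False, encoding="utf-8"
    )


def deduplicate(reports: list[ICSR]) -> tuple[list[ICSR], int]:
    """Keep one report per case identifier; return (kept, n_removed).

    Among duplicates the version with the latest receive date wins; ties
    (including all-missing dates) resolve to the last occurrence in input
    order.  Idempotent, and stable in first-occurrence order.
    """
    best: dict[str, tuple[int, ICSR]] = {}
    order: list[str] = []
    for pos, report in enumerate(reports):
        key = report.case_id
        if key not in best:
            best[key] = (pos, report)
            order.append(key)
        else:
            _, incumbent = best[key]
            old = incumbent.receive_date or _dt.date.min
            new = report.receive_date or _dt.date.min
            if new >= old:
                best[key] = (best[key][0], report)
    kept = [best[k][1] for k in order]
    removed = len(reports) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate record(s)", removed)
    return kept, removed
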