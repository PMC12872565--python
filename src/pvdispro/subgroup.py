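"""Stratified re-analysis of the exposure cohorts (sex subgrouping).

Reports with unspecified sex are excluded before stratification; each
stratum is itself a full exposure partition, so the SOC- and PT-level
disproportionality analyses run unchanged within it.  The API takes a
generic key function so other partitions (e.g. age bands) are possible,
but sex is the only stratification exercised by the shipped analyses.
"""

from __future__ import annotations

import logging
from typing import Callable, Hashable

from .cohorts import ExposureCohorts
from .disproportionality import (
    DegenerateCohortError,
    RORResult,
    ZeroCellPolicy,
    analyze_by_soc,
    analyze_mr_pts,
)
from .icsr import ICSR, Sex
from .meddra import MedDRAMap, MRPTSet

logger = logging.getLogger(__name__)


def stratify(
    cohorts: ExposureCohorts,
    key: Callable[[ICSR], Hashable],
    exclude: Callable[[ICSR], bool] = lambda r: False,
) -> dict[Hashable, ExposureCohorts]:
    """Partition each exposure group by ``key``, dropping ``exclude`` hits."""
    strata: dict[Hashable, ExposureCohorts] = {}
    for group_name in ("target_only", "comparator_only", "both", "neither"):
        for report in getattr(cohorts, group_name):
            if exclude(report):
                continue
            stratum = strata.setdefault(key(report), ExposureCohorts())
            getattr(stratum, group_name).append(report)
    return strata


def stratify_by_sex(cohorts: ExposureCohorts) -> dict[Sex, ExposureCohorts]:
    """Female and male strata; unspecified-sex reports are excluded.

    The two strata partition the sex-specified analysis set:
    |FEMALE| + |MALE| = N − N_unspecified in every exposure group.
    """
    strata = stratify(
        cohorts,
        key=lambda r: r.sex,
        exclude=lambda r: r.sex is Sex.UNSPECIFIED,
    )
    return {
        sex: strata.get(sex, ExposureCohorts()) for sex in (Sex.FEMALE, Sex.MALE)
    }


def sex_subgroup_analysis(
    strata: dict[Sex, ExposureCohorts],
    meddra: MedDRAMap,
    mrpts: MRPTSet | None = None,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE_HALF,
) -> dict[Sex, dict[str, list[RORResult]]]:
    """SOC-level and MR-PT-level ROR analyses within each sex stratum.

    A stratum with an empty target or comparator cohort is skipped with
    a warning rather than aborting the run.
    """
    out: dict[Sex, dict[str, list[RORResult]]] = {}
    for sex, stratum in strata.items():
        try:
            out[sex] = {
                "soc": analyze_by_soc(stratum, meddra, zero_cell_policy=zero_cell_policy),
                "mr_pt": analyze_mr_pts(
                    stratum, mrpts, zero_cell_policy=zero_cell_policy
                ),
            }
        except DegenerateCohortError:
            logger.warning(
                "sex stratum %s has an empty analysis cohort; skipped", sex.value
            )
    return out
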