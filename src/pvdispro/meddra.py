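"""Preferred-term (PT) to system-organ-class (SOC) mapping.

MedDRA assigns each PT one primary SOC; this module implements that
lookup from a two-column delimited file plus the predefined 13-member
muscle-related PT (MR-PT) set used to refine the broad musculoskeletal
SOC (which also contains terms such as arthralgia that are not
unambiguously muscular).

The real MedDRA dictionary is licensed and cannot be redistributed; the
package ships a small synthetic mapping (``data/meddra_toy.csv``)
covering every PT and SOC the analyses and the simulator touch,
following the primary-SOC convention — in particular "blood creatine
phosphokinase increased" maps to Investigations, not to the
musculoskeletal SOC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned for PTs absent from the mapping.
UNMAPPED = "UNMAPPED"

#: MedDRA uses British spelling; accept common American variants on input.
_SPELLING_VARIANTS = {
    "necrotizing myositis": "necrotising myositis",
}

#: The predefined muscle-related preferred terms (13 members).
DEFAULT_MR_PTS: tuple[str, ...] = (
    "myalgia",
    "blood creatine phosphokinase increased",
    "rhabdomyolysis",
    "muscle spasms",
    "muscular weakness",
    "myopathy",
    "musculoskeletal stiffness",
    "muscle disorder",
    "muscle discomfort",
    "musculoskeletal pain",
    "musculoskeletal discomfort",
    "myositis",
    "necrotising myositis",
)

#: SOC label of the broad musculoskeletal class.
MSK_SOC = "Musculoskeletal and connective tissue disorders"


def normalize_pt(pt: str) -> str:
    """Canonical lower-cased form of a PT, folding spelling variants."""
    key = " ".join(pt.strip().lower().split())
    return _SPELLING_VARIANTS.get(key, key)


class MappingConflictError(ValueError):
    """A PT appears with two different SOCs in the mapping file."""


@dataclass(frozen=True)
class MedDRAMap:
    """Case-insensitive PT -> primary SOC lookup table."""

    pt_to_soc: dict[str, str]
    version_label: str = ""

    def soc_of(self, pt: str) -> str:
        """Primary SOC of ``pt``, or the ``UNMAPPED`` sentinel (never raises)."""
        soc = self.pt_to_soc.get(normalize_pt(pt))
        if soc is None:
            logger.debug("PT %r not in MedDRA map (version %s)", pt, self.version_label)
            return UNMAPPED
        return soc

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())


@dataclass(frozen=True)
class MRPTSet:
    """The predefined muscle-related PT set; overridable via configuration."""

    pts: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_MR_PTS)
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pts", frozenset(normalize_pt(p) for p in self.pts)
        )

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.pts

    def __iter__(self):
        # Default-set members keep the canonical declaration order.
        ordered = [p for p in DEFAULT_MR_PTS if p in self.pts]
        ordered += sorted(self.pts - set(ordered))
        return iter(ordered)

    def __len__(self) -> int:
        return len(self.pts)


def is_mr_pt(pt: str, mrpts: MRPTSet | None = None) -> bool:
    """Membership test in the muscle-related PT set (spelling-variant aware)."""
    return pt in (mrpts or MRPTSet())


def soc_of(pt: str, meddra: MedDRAMap) -> str:
    """Functional alias for :meth:`MedDRAMap.soc_of`."""
    return meddra.soc_of(pt)


def load_meddra_map(path: str | Path, version_label: str = "") -> MedDRAMap:
    """Load a two-column (pt, soc) delimited mapping file.

    Duplicate identical rows collapse; a PT mapped to two different SOCs
    is a :class:`MappingConflictError` naming the offending PT.
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["pt", "soc"]:
        raise ValueError(
            f"mapping file {path} must start with columns 'pt,soc'; got {list(df.columns)}"
        )
    mapping: dict[str, str] = {}
    for pt_raw, soc_raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pt = normalize_pt(str(pt_raw))
        soc = str(soc_raw).strip()
        if pt in mapping and mapping[pt] != soc:
            raise MappingConflictError(
                f"PT {pt!r} mapped to both {mapping[pt]!r} and {soc!r}"
            )
        mapping[pt] = soc
    return MedDRAMap(pt_to_soc=mapping, version_label=version_label)


def default_meddra_map() -> MedDRAMap:
    """The bundled synthetic mapping (all PTs/SOCs used by the analyses)."""
    ref = resources.files("pvdispro.data").joinpath("meddra_toy.csv")
    with resources.as_file(ref) as path:
        return load_meddra_map(path, version_label="toy-27.0")
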