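"""Trio-based inheritance assignment, cis/trans phasing and mosaic-fraction
estimation from read depth.

Phasing here is phasing *by inheritance*: a heterozygous variant carried by
exactly one parent is assigned to that parental allele.  No read-backed or
population phasing is attempted.  Two variants phased to different parents
are in trans (compound heterozygous); to the same parent, in cis.

The mosaic model: a heterozygous deletion present in a fraction ``f`` of
cells removes one of two copies in those cells, so expected depth over the
deleted region is ``flank_depth * (1 - f/2)``.  Inverting the observed
depth ratio ``r = depth_in / depth_flank`` gives ``f = 2 * (1 - r)``,
clamped to [0, 1].  A constitutive heterozygote (r = 0.5) gives f = 100%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class Origin(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    DE_NOVO = "de_novo"
    AMBIGUOUS = "ambiguous"  # both parents carry: origin undecidable from GTs
    UNKNOWN_NO_TRIO = "unknown_no_trio"


class Phase(str, enum.Enum):
    TRANS = "trans"
    CIS = "cis"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


def _carries(gt: Optional[str]) -> Optional[bool]:
    """True/False for carrier status, None for a missing genotype."""
    if gt is None:
        return None
    if gt in ("./.", ".", ".|."):
        return None
    return "1" in gt.replace("|", "/").split("/")


def inherited_from(
    proband_gt: str, mother_gt: Optional[str], father_gt: Optional[str]
) -> Origin:
    """Assign parental origin of a variant carried by the proband.

    Requires a carrier proband (calling this for a non-carrier is a contract
    violation and raises).  A missing parental genotype makes the origin
    undecidable (UNKNOWN_NO_TRIO).
    """
    if not _carries(proband_gt):
        raise ValueError(
            f"proband genotype {proband_gt!r} is not a carrier; "
            "inheritance of an uncarried variant is undefined"
        )
    mother = _carries(mother_gt)
    father = _carries(father_gt)
    if mother is None or father is None:
        return Origin.UNKNOWN_NO_TRIO
    if mother and father:
        return Origin.AMBIGUOUS
    if mother:
        return Origin.MATERNAL
    if father:
        return Origin.PATERNAL
    return Origin.DE_NOVO


def phase_pair(origin_a: Origin, origin_b: Origin) -> Phase:
    """Cis/trans relation of two variants from their parental origins.

    Only unambiguous single-parent origins phase; any de novo, ambiguous or
    missing-trio input yields UNKNOWN.
    """
    definite = (Origin.MATERNAL, Origin.PATERNAL)
    if origin_a not in definite or origin_b not in definite:
        return Phase.UNKNOWN
    return Phase.CIS if origin_a == origin_b else Phase.TRANS


@dataclass(frozen=True)
class MosaicEstimate:
    depth_in: float
    depth_flank: float
    fraction_pct: float  # percentage of cells carrying the heterozygous deletion

    @property
    def depth_ratio(self) -> float:
        return self.depth_in / self.depth_flank


def mosaic_fraction(depth_in: float, depth_flank: float) -> float:
    """Percent of cells heterozygous for a deletion, from mean read depths.

    ``100 * clamp(2 * (1 - depth_in/depth_flank), 0, 1)``.  Intended for
    deletions; duplication mosaicism is out of scope.
    """
    if depth_flank <= 0:
        raise ValueError("depth_flank must be positive")
    if depth_in < 0:
        raise ValueError("depth_in must be non-negative")
    raw = 2.0 * (1.0 - depth_in / depth_flank)
    return 100.0 * min(1.0, max(0.0, raw))


def mosaic_estimate(depth_in: float, depth_flank: float) -> MosaicEstimate:
    return MosaicEstimate(depth_in, depth_flank, mosaic_fraction(depth_in, depth_flank))


def _alleles(gt: str):
    return tuple(int(a) for a in gt.replace("|", "/").split("/"))


def mendelian_consistent(proband_gt: str, mother_gt: str, father_gt: str) -> bool:
    """True iff the proband's diploid genotype can be drawn one allele from
    each parent.  All three genotypes must be present."""
    for gt in (proband_gt, mother_gt, father_gt):
        if _carries(gt) is None:
            raise ValueError(f"genotype {gt!r} is missing; all three are required")
    child = _alleles(proband_gt)
    mother = _alleles(mother_gt)
    father = _alleles(father_gt)
    for m in mother:
        for f in father:
            if sorted((m, f)) == sorted(child):
                return True
    return False
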