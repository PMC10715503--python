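"""Case manifest: recruited probands, first-hit variants, solve status."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from .variants import SmallVariant, variant_key


class RecruitmentStatus(str, enum.Enum):
    CORRECTLY_RECRUITED = "correctly_recruited"
    EXCLUDED_MISRECRUITED = "excluded_misrecruited"
    EXCLUDED_DATA_QUALITY = "excluded_data_quality"
    NO_FIRST_HIT_INFO = "no_first_hit_info"


class SolvedStatus(str, enum.Enum):
    PREVIOUSLY_SOLVED = "previously_solved"
    NEWLY_SOLVED = "newly_solved"
    UNSOLVED = "unsolved"


class FirstHitKind(str, enum.Enum):
    SMALL_VARIANT = "small"
    SV_CLUSTER = "sv"
    ROH_ONLY = "roh_only"  # recruited on a homozygosity region, no specific variant
    NONE = "none"


@dataclass(frozen=True)
class FirstHit:
    """The already-known pathogenic variant anchoring the second-hit screen.

    ``variant_key`` identifies a small variant as (chrom, pos, ref, alt);
    SV first hits are referenced by description only.  The sentinels
    ``roh_only`` and ``none`` cover cases recruited on a region of
    homozygosity or with no specific variant recorded.
    """

    gene_symbol: str
    kind: FirstHitKind = FirstHitKind.SMALL_VARIANT
    variant_key: Optional[Tuple[str, int, str, str]] = None
    description: str = ""


@dataclass
class CaseRecord:
    case_id: str
    proband_id: str
    referral_condition: str = ""
    recruitment_status: RecruitmentStatus = RecruitmentStatus.CORRECTLY_RECRUITED
    first_hit: Optional[FirstHit] = None
    solved: SolvedStatus = SolvedStatus.UNSOLVED

    def __post_init__(self) -> None:
        has_info = self.recruitment_status != RecruitmentStatus.NO_FIRST_HIT_INFO
        if has_info != (self.first_hit is not None):
            raise ValueError(
                "first_hit must be absent exactly when recruitment_status is "
                f"no_first_hit_info (case {self.case_id})"
            )


class FirstHitConfirmation(str, enum.Enum):
    CONFIRMED = "confirmed"
    NOT_CONFIRMED = "not_confirmed"
    NOT_APPLICABLE = "not_applicable"


def confirm_first_hit(
    case: CaseRecord, variants: Iterable[SmallVariant]
) -> FirstHitConfirmation:
    """Check that the proband actually carries its recorded first-hit variant.

    Returns NOT_APPLICABLE for sentinel first hits (no specific variant, or a
    homozygosity region only) rather than raising.
    """
    fh = case.first_hit
    if fh is None or fh.kind in (FirstHitKind.ROH_ONLY, FirstHitKind.NONE):
        return FirstHitConfirmation.NOT_APPLICABLE
    if fh.kind is not FirstHitKind.SMALL_VARIANT or fh.variant_key is None:
        return FirstHitConfirmation.NOT_APPLICABLE
    for v in variants:
        if v.key == fh.variant_key:
            if v.is_carrier(case.proband_id):
                return FirstHitConfirmation.CONFIRMED
            return FirstHitConfirmation.NOT_CONFIRMED
    return FirstHitConfirmation.NOT_CONFIRMED


MANIFEST_COLUMNS = [
    "case_id",
    "proband_id",
    "referral_condition",
    "recruitment_status",
    "solved",
    "first_hit_gene",
    "first_hit_kind",
    "first_hit_variant",
    "first_hit_description",
]


def _fh_variant_str(fh: FirstHit) -> str:
    if fh.variant_key is None:
        return ""
    chrom, pos, ref, alt = fh.variant_key
    return f"{chrom}:{pos}:{ref}:{alt}"


def write_case_manifest(cases: List[CaseRecord], path) -> None:
    rows = []
    for c in cases:
        fh = c.first_hit
        rows.append(
            {
                "case_id": c.case_id,
                "proband_id": c.proband_id,
                "referral_condition": c.referral_condition,
                "recruitment_status": c.recruitment_status.value,
                "solved": c.solved.value,
                "first_hit_gene": fh.gene_symbol if fh else "",
                "first_hit_kind": fh.kind.value if fh else "",
                "first_hit_variant": _fh_variant_str(fh) if fh else "",
                "first_hit_description": fh.description if fh else "",
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_case_manifest(path) -> List[CaseRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cases = []
    for row in df.itertuples(index=False):
        status = RecruitmentStatus(row.recruitment_status)
        fh = None
        if status != RecruitmentStatus.NO_FIRST_HIT_INFO:
            key = None
            if row.first_hit_variant:
                chrom, pos, ref, alt = row.first_hit_variant.split(":")
                key = variant_key(chrom, int(pos), ref, alt)
            fh = FirstHit(
                gene_symbol=row.first_hit_gene,
                kind=FirstHitKind(row.first_hit_kind),
                variant_key=key,
                description=row.first_hit_description,
            )
        cases.append(
            CaseRecord(
                case_id=row.case_id,
                proband_id=row.proband_id,
                referral_condition=row.referral_condition,
                recruitment_status=status,
                first_hit=fh,
                solved=SolvedStatus(row.solved),
            )
        )
    return cases
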