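"""Variant records: structural-variant calls and small variants with evidence.

Genotype conventions
--------------------
SV calls carry a coarse genotype in ``{"het", "hom", "missing"}`` (cohort
frequency counts carriers, not alleles, so zygosity detail beyond het/hom is
not needed).  Small variants carry diploid VCF-style genotype strings
(``0/0``, ``0/1``, ``1/1``, ``./.``) per sample; samples absent from the
genotype map are implicitly homozygous reference, which keeps records for
rare variants compact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .intervals import GenomicInterval

SV_TYPES = ("DEL", "DUP", "INV", "INS")
SV_GENOTYPES = ("het", "hom", "missing")

#: splice-model delta-score channels: acceptor/donor gain/loss
SPLICE_CHANNELS = ("AG", "AL", "DG", "DL")


@dataclass(frozen=True)
class SvCall:
    """One caller's structural-variant observation in one sample.

    Insertions are modelled as point-like loci (length <= 2 bp) with an
    explicit ``ins_length``; reciprocal overlap is undefined for them and
    they are matched by breakpoint proximity and length similarity instead.
    """

    sample_id: str
    caller: str
    svtype: str
    locus: GenomicInterval
    ins_length: Optional[int] = None
    genotype: str = "het"
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.genotype not in SV_GENOTYPES:
            raise ValueError(f"unknown SV genotype {self.genotype!r}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        if self.svtype == "INS":
            if self.ins_length is None or self.ins_length <= 0:
                raise ValueError("INS calls require a positive ins_length")
            if self.locus.length() > 2:
                raise ValueError(
                    "INS locus must be point-like (length <= 2), "
                    f"got {self.locus.length()} bp"
                )
        elif self.ins_length is not None:
            raise ValueError(f"{self.svtype} calls must not carry ins_length")


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> Tuple[str, int, str, str]:
    """Canonical identity key for a small variant."""
    return (chrom, pos, ref, alt)


@dataclass
class SmallVariant:
    """A substitution or indel with per-sample genotypes and evidence.

    Allele frequencies (``af_*``) and in-silico scores are optional: an
    absent frequency means the variant was not observed in that resource
    (treated as novel downstream), an absent score means un-annotated.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Dict[str, str] = field(default_factory=dict)
    af_1000g: Optional[float] = None
    af_gnomad: Optional[float] = None
    af_cohort: Optional[float] = None
    cadd_phred: Optional[float] = None
    splice_deltas: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for name in ("af_1000g", "af_gnomad", "af_cohort"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        for ch, v in self.splice_deltas.items():
            if ch not in SPLICE_CHANNELS:
                raise ValueError(f"unknown splice channel {ch!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"splice delta {ch}={v} outside [0,1]")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def genotype_of(self, sample_id: str) -> str:
        return self.genotypes.get(sample_id, "0/0")

    def is_carrier(self, sample_id: str) -> bool:
        return "1" in self.genotype_of(sample_id).split("/")

    def is_hom_alt(self, sample_id: str) -> bool:
        return self.genotype_of(sample_id) == "1/1"

    def max_splice_delta(self) -> Optional[float]:
        """Largest delta over present channels, or None if none present."""
        if not self.splice_deltas:
            return None
        return max(self.splice_deltas.values())

    def population_afs(self) -> Dict[str, Optional[float]]:
        return {
            "af_1000g": self.af_1000g,
            "af_gnomad": self.af_gnomad,
            "af_cohort": self.af_cohort,
        }


def compute_cohort_af(variants, n_samples: int) -> None:
    """Fill ``af_cohort`` in place as carrier fraction over *n_samples*.

    Mirrors the participant-based (not allele-based) rarity convention used
    for SV clusters: het and hom carriers each count once.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    for v in variants:
        carriers = sum(1 for gt in v.genotypes.values() if "1" in gt.split("/"))
        v.af_cohort = carriers / n_samples
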