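"""Per-case second-hit screening and cohort-level accounting.

For each recruited case with a known first-hit gene the screen assembles,
in order:

1. rare SV clusters overlapping the first-hit gene padded by ~1 kb whose
   carriers include the proband;
2. rare small variants carried by the proband in the same window (the
   first-hit variant itself is excluded);
3. trio phasing of every candidate against the first hit, where a trio and
   a first-hit genotype exist;
4. the homozygous path: proband-homozygous rare variants lying inside a
   run of homozygosity are promoted as HOMOZYGOUS_IN_ROH candidates;
5. ranking: in-trans (and homozygous-in-ROH) candidates first, then
   unknown phase, then cis — cis candidates are flagged, never dropped —
   with evidence score, SV-before-small-variant priority and genomic
   position breaking ties.

SVs are screened before small variants but both are always reported: the
sequential wording of the clinical workflow is treated as a priority
ordering, not a short-circuit, so reports are complete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .cases import CaseRecord, FirstHitKind, RecruitmentStatus, SolvedStatus
from .intervals import Gene, GenomicInterval
from .pedigree import Pedigree
from .phasing import Origin, Phase, inherited_from, mosaic_fraction, phase_pair
from .roh import RohRegion, containing_roh
from .smallvar import EvidenceWeights, VariantIndex, filter_rare_small, ranking_score
from .splice import SpliceConsequence, acceptor_gain_retention, frameshift
from .svcluster import SvCluster
from .variants import SmallVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    sv_max_freq: float = 0.01
    gene_window_bp: int = 1000
    weights: EvidenceWeights = field(default_factory=EvidenceWeights)


@dataclass
class CandidateSecondHit:
    case_id: str
    candidate: Union[SvCluster, SmallVariant]
    zygosity_path: str  # "COMPOUND_HET" | "HOMOZYGOUS_IN_ROH"
    phase: Phase
    roh: Optional[RohRegion] = None
    consequence: Optional[SpliceConsequence] = None
    rank_score: float = 0.0
    evidence_notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.zygosity_path == "HOMOZYGOUS_IN_ROH" and self.roh is None:
            raise ValueError("HOMOZYGOUS_IN_ROH candidates must carry their ROH")

    @property
    def is_sv(self) -> bool:
        return isinstance(self.candidate, SvCluster)

    @property
    def locus(self) -> GenomicInterval:
        if self.is_sv:
            return self.candidate.representative
        v = self.candidate
        return GenomicInterval(v.chrom, v.pos, v.pos)

    @property
    def label(self) -> str:
        if self.is_sv:
            c = self.candidate
            return f"{c.cluster_id}:{c.svtype}:{c.representative}"
        v = self.candidate
        return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def sv_window_overlap(cluster: SvCluster, gene: Gene, window_bp: int = 1000) -> bool:
    """True iff the cluster's representative intersects the gene body padded
    by *window_bp* on both sides (boundary inclusive)."""
    return cluster.representative.intersects(gene.window(window_bp))


def _sv_origin(
    cluster: SvCluster, proband: str, pedigree: Pedigree
) -> Origin:
    father, mother = pedigree.parents_of(proband)
    if father is None or mother is None:
        return Origin.UNKNOWN_NO_TRIO
    mother_gt = "0/1" if mother in cluster.carriers else "0/0"
    father_gt = "0/1" if father in cluster.carriers else "0/0"
    return inherited_from("0/1", mother_gt, father_gt)


def _variant_origin(
    v: SmallVariant, proband: str, pedigree: Pedigree
) -> Origin:
    father, mother = pedigree.parents_of(proband)
    if father is None or mother is None:
        return Origin.UNKNOWN_NO_TRIO
    return inherited_from(
        v.genotype_of(proband), v.genotype_of(mother), v.genotype_of(father)
    )


def _acceptor_gain_consequence(
    v: SmallVariant, gene: Gene
) -> Optional[SpliceConsequence]:
    """Retention arithmetic for predicted acceptor gains close to an exon.

    Only computed when the variant carries an acceptor-gain delta and lies
    3-50 bp on the intronic side of an exon's acceptor boundary (exon start
    on the + strand, exon end on the - strand).
    """
    if "AG" not in v.splice_deltas:
        return None
    for ex in gene.exons:
        if gene.strand == "+":
            offset = v.pos - ex.start  # negative when intronic, upstream
        else:
            offset = ex.end - v.pos
        if -50 <= offset <= -3:
            n = acceptor_gain_retention(offset)
            return SpliceConsequence(n, frameshift(n))
    return None


def _mosaic_notes(
    cluster: SvCluster,
    depth_table: Optional[pd.DataFrame],
    members: Sequence[str],
) -> List[str]:
    """Depth-ratio mosaic estimates over a DEL cluster for family members."""
    if depth_table is None or depth_table.empty or cluster.svtype != "DEL":
        return []
    iv = cluster.representative
    notes = []
    for sample in members:
        sub = depth_table[
            (depth_table["sample_id"] == sample) & (depth_table["chrom"] == iv.chrom)
        ]
        if sub.empty:
            continue
        mid = (sub["start"] + sub["end"]) / 2.0
        inside = sub[(mid >= iv.start) & (mid <= iv.end)]
        outside = sub[(sub["end"] < iv.start) | (sub["start"] > iv.end)]
        if inside.empty or outside.empty:
            continue
        w_in = (inside["end"] - inside["start"] + 1).to_numpy()
        w_out = (outside["end"] - outside["start"] + 1).to_numpy()
        depth_in = float((inside["mean_depth"].to_numpy() * w_in).sum() / w_in.sum())
        depth_flank = float((outside["mean_depth"].to_numpy() * w_out).sum() / w_out.sum())
        f = mosaic_fraction(depth_in, depth_flank)
        notes.append(
            f"{sample}: deletion in {f:.0f}% of cells "
            f"(depth {depth_in:.1f} in vs {depth_flank:.1f} flank)"
        )
    return notes


def _phase_tier(c: CandidateSecondHit) -> int:
    if c.zygosity_path == "HOMOZYGOUS_IN_ROH":
        return 0  # a homozygous hit in an ROH is a complete biallelic finding
    if c.phase is Phase.TRANS:
        return 0
    if c.phase is Phase.CIS:
        return 2
    return 1  # UNKNOWN, or NOT_APPLICABLE because no trio exists


def _rank_key(c: CandidateSecondHit):
    return (
        _phase_tier(c),
        -c.rank_score,
        0 if c.is_sv else 1,  # SVs are screened first
        c.locus.chrom,
        c.locus.start,
        c.label,
    )


def screen_case(
    case: CaseRecord,
    clusters: Sequence[SvCluster],
    variants: Union[VariantIndex, Sequence[SmallVariant]],
    pedigree: Pedigree,
    depth_table: Optional[pd.DataFrame],
    roh_regions: Mapping[str, Sequence[RohRegion]],
    genes: Mapping[str, Gene],
    params: ScreenParams = ScreenParams(),
) -> List[CandidateSecondHit]:
    """Rank candidate second hits for one case; see the module docstring for
    the five steps.  Raises if the case has no first-hit gene or the gene is
    missing from the annotation."""
    if case.first_hit is None:
        raise ValueError(f"case {case.case_id} has no first-hit information")
    gene = genes.get(case.first_hit.gene_symbol)
    if gene is None:
        raise KeyError(
            f"first-hit gene {case.first_hit.gene_symbol!r} of case "
            f"{case.case_id} is absent from the gene annotation"
        )
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(list(variants))
    proband = case.proband_id
    window = gene.window(params.gene_window_bp)
    father, mother = pedigree.parents_of(proband)
    has_trio = father is not None and mother is not None
    proband_roh = list(roh_regions.get(proband, ()))

    # first-hit parental origin, when resolvable
    first_origin: Optional[Origin] = None
    fh = case.first_hit
    if fh.kind is FirstHitKind.SMALL_VARIANT and fh.variant_key is not None:
        fh_var = variants.lookup(fh.variant_key)
        if fh_var is not None and fh_var.is_carrier(proband) and has_trio:
            first_origin = _variant_origin(fh_var, proband, pedigree)

    candidates: List[CandidateSecondHit] = []

    # step 1: rare SV clusters in the gene window carried by the proband
    for cl in clusters:
        if cl.cohort_frequency is None:
            raise ValueError(f"cluster {cl.cluster_id} lacks a cohort frequency")
        if cl.cohort_frequency >= params.sv_max_freq:
            logger.debug("%s: drop %s (freq %.4f)", case.case_id, cl.cluster_id,
                         cl.cohort_frequency)
            continue
        if not sv_window_overlap(cl, gene, params.gene_window_bp):
            continue
        if proband not in cl.carriers:
            continue
        origin = _sv_origin(cl, proband, pedigree)
        if not has_trio:
            phase = Phase.NOT_APPLICABLE
        elif first_origin is not None:
            phase = phase_pair(origin, first_origin)
        else:
            phase = Phase.UNKNOWN
        notes = [f"origin={origin.value}", f"frequency={cl.cohort_frequency:.5f}"]
        notes += _mosaic_notes(cl, depth_table,
                               [proband] + [p for p in (father, mother) if p])
        if phase is Phase.CIS:
            notes.append("flag: phased cis with first hit")
        candidates.append(
            CandidateSecondHit(
                case_id=case.case_id, candidate=cl, zygosity_path="COMPOUND_HET",
                phase=phase, rank_score=0.0, evidence_notes=notes,
            )
        )

    # steps 2-4: rare small variants in the window
    in_window = variants.in_window(window)
    rare = filter_rare_small(in_window, proband, params.weights)
    for v in rare:
        if fh.variant_key is not None and v.key == fh.variant_key:
            logger.debug("%s: exclude first-hit variant %s", case.case_id, v.key)
            continue
        score = ranking_score(v, params.weights)
        consequence = _acceptor_gain_consequence(v, gene)
        locus = GenomicInterval(v.chrom, v.pos, v.pos)
        roh_hit = containing_roh(proband_roh, locus) if v.is_hom_alt(proband) else None
        if roh_hit is not None:
            candidates.append(
                CandidateSecondHit(
                    case_id=case.case_id, candidate=v,
                    zygosity_path="HOMOZYGOUS_IN_ROH", phase=Phase.NOT_APPLICABLE,
                    roh=roh_hit, consequence=consequence, rank_score=score,
                    evidence_notes=[
                        f"homozygous inside {roh_hit.interval} "
                        f"({roh_hit.interval.length() / 1e6:.1f} Mb ROH)"
                    ],
                )
            )
            continue
        origin = _variant_origin(v, proband, pedigree)
        if not has_trio:
            phase = Phase.NOT_APPLICABLE
        elif first_origin is not None:
            phase = phase_pair(origin, first_origin)
        else:
            phase = Phase.UNKNOWN
        notes = [f"origin={origin.value}"]
        if phase is Phase.CIS:
            notes.append("flag: phased cis with first hit")
        candidates.append(
            CandidateSecondHit(
                case_id=case.case_id, candidate=v, zygosity_path="COMPOUND_HET",
                phase=phase, consequence=consequence, rank_score=score,
                evidence_notes=notes,
            )
        )

    candidates.sort(key=_rank_key)
    return candidates


def diagnostic_yield(n_solved: int, n_total: int) -> float:
    """Percent of cases solved, to one decimal place."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_solved <= n_total):
        raise ValueError("require 0 <= n_solved <= n_total")
    return round(100.0 * n_solved / n_total, 1)


@dataclass(frozen=True)
class CarrierEnrichment:
    pct_cohort: float  # 2 decimal places
    pct_sub: float  # 1 decimal place
    ratio: Optional[float]  # pct_sub / pct_cohort; None when undefined


def carrier_enrichment(
    carriers_cohort: int, n_cohort: int, carriers_sub: int, n_sub: int
) -> CarrierEnrichment:
    """Carrier percentage in the whole cohort vs a subcohort, with their
    ratio (None when the cohort percentage is zero)."""
    if n_cohort <= 0 or n_sub <= 0:
        raise ValueError("denominators must be positive")
    if carriers_sub > carriers_cohort:
        raise ValueError("subcohort carriers cannot exceed cohort carriers")
    if n_sub > n_cohort:
        raise ValueError("subcohort cannot exceed cohort")
    if carriers_cohort < 0 or carriers_sub < 0:
        raise ValueError("carrier counts must be non-negative")
    pct_cohort = round(100.0 * carriers_cohort / n_cohort, 2)
    pct_sub = round(100.0 * carriers_sub / n_sub, 1)
    ratio = pct_sub / pct_cohort if pct_cohort > 0 else None
    return CarrierEnrichment(pct_cohort, pct_sub, ratio)


@dataclass(frozen=True)
class CohortSummary:
    n_recruited: int
    n_excluded: int
    n_no_first_hit_info: int
    n_correctly_recruited: int
    n_previously_solved: int
    n_newly_solved: int
    yield_before: float
    yield_after: float


def cohort_summary(cases: Sequence[CaseRecord]) -> CohortSummary:
    """Cohort accounting: recruitment and solve-status counts, and the
    diagnostic yield over correctly recruited cases before and after the
    second-hit screen."""
    if not cases:
        raise ValueError("no cases supplied")
    n_recruited = len(cases)
    n_excluded = sum(
        1
        for c in cases
        if c.recruitment_status
        in (RecruitmentStatus.EXCLUDED_MISRECRUITED, RecruitmentStatus.EXCLUDED_DATA_QUALITY)
    )
    n_no_info = sum(
        1 for c in cases if c.recruitment_status is RecruitmentStatus.NO_FIRST_HIT_INFO
    )
    correctly = [
        c for c in cases if c.recruitment_status is RecruitmentStatus.CORRECTLY_RECRUITED
    ]
    n_prev = sum(1 for c in correctly if c.solved is SolvedStatus.PREVIOUSLY_SOLVED)
    n_new = sum(1 for c in correctly if c.solved is SolvedStatus.NEWLY_SOLVED)
    denom = len(correctly)
    return CohortSummary(
        n_recruited=n_recruited,
        n_excluded=n_excluded,
        n_no_first_hit_info=n_no_info,
        n_correctly_recruited=denom,
        n_previously_solved=n_prev,
        n_newly_solved=n_new,
        yield_before=diagnostic_yield(n_prev, denom),
        yield_after=diagnostic_yield(n_prev + n_new, denom),
    )


REPORT_COLUMNS = [
    "case_id", "rank", "candidate_kind", "candidate", "zygosity_path", "phase",
    "rank_score", "roh", "consequence_nt", "frameshift", "evidence",
]


def candidates_to_frame(candidates: Sequence[CandidateSecondHit]) -> pd.DataFrame:
    rows = []
    for rank, c in enumerate(candidates, start=1):
        rows.append(
            {
                "case_id": c.case_id,
                "rank": rank,
                "candidate_kind": "SV" if c.is_sv else "SNV",
                "candidate": c.label,
                "zygosity_path": c.zygosity_path,
                "phase": c.phase.value,
                "rank_score": round(c.rank_score, 4),
                "roh": str(c.roh.interval) if c.roh else "",
                "consequence_nt": c.consequence.inserted_or_removed_nt if c.consequence else "",
                "frameshift": c.consequence.frameshift if c.consequence else "",
                "evidence": "; ".join(c.evidence_notes),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    per_case: Dict[str, List[CandidateSecondHit]],
    summary: CohortSummary,
    outdir,
) -> None:
    """Per-case candidate TSVs plus a cohort JSON summary."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = [candidates_to_frame(cands) for cands in per_case.values() if cands]
    all_rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=REPORT_COLUMNS)
    )
    all_rows.to_csv(out / "candidates.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "n_recruited": summary.n_recruited,
                "n_excluded": summary.n_excluded,
                "n_no_first_hit_info": summary.n_no_first_hit_info,
                "n_correctly_recruited": summary.n_correctly_recruited,
                "n_previously_solved": summary.n_previously_solved,
                "n_newly_solved": summary.n_newly_solved,
                "yield_before_pct": summary.yield_before,
                "yield_after_pct": summary.yield_after,
                "n_cases_screened": len(per_case),
                "n_cases_with_candidates": sum(1 for v in per_case.values() if v),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
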