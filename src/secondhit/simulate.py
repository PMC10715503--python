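"""Synthetic cohort generator with planted second hits.

Emulates the statistical structure a second-hit screen assumes, so every
downstream stage is testable without access-controlled data:

* trio families with Mendelian genotypes over a backbone of common
  biallelic sites (allele frequency 0.5) on two synthetic 250 Mb
  chromosomes;
* two SV callers ("A" and "B") reporting each true SV with independent
  breakpoint jitter and per-caller dropout;
* a background SV frequency spectrum mixing common (>1%) and rare (<1%)
  carrier fractions;
* planted cases: compound-het second hits (SV or deep-intronic SNV)
  genuinely in trans with a planted first hit, one mosaic parental
  deletion reflected in the depth table, and consanguinity-style ROH
  blocks containing a homozygous second hit;
* a truth table recording what was planted where.

All randomness flows through a single seeded generator; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cases import CaseRecord, FirstHit, FirstHitKind, SolvedStatus, write_case_manifest
from .intervals import Gene, GenomicInterval
from .pedigree import PedRecord, Pedigree, write_ped
from .variants import SmallVariant, SvCall, compute_cohort_af
from .vcfio import (
    write_depth_tsv,
    write_gene_bed,
    write_small_variant_vcf,
    write_sv_vcf,
)

# planted-case kinds
SECOND_HIT_SV = "second_hit_SV"
SECOND_HIT_INTRONIC_SNV = "second_hit_intronic_SNV"
HOMOZYGOUS_IN_ROH = "homozygous_in_ROH"
MOSAIC_PARENT_SV = "mosaic_parent_SV"
PLANT_KINDS = (SECOND_HIT_SV, SECOND_HIT_INTRONIC_SNV, HOMOZYGOUS_IN_ROH, MOSAIC_PARENT_SV)

#: carrier-fraction cycle for background SV clusters: mostly rare (<1%),
#: with common clusters (5% and 12%) interleaved so the rarity filter has
#: something to reject.
DEFAULT_SPECTRUM_CYCLE = (0.002, 0.005, 0.001, 0.05, 0.003, 0.008, 0.12, 0.004)

#: splice-delta / CADD evidence assigned to planted intronic SNVs, cycled in
#: order.  The values span the realistic range: a near-zero predictor score
#: on a genuinely causal variant, a near-certain acceptor gain, and a
#: moderate donor-loss call.
PLANTED_SNV_EVIDENCE = (("AG", 0.02, 1.25), ("AG", 0.99, 18.5), ("AL", 0.51, 10.0))

MOSAIC_TRUE_FRACTION = 0.44  # fraction of cells carrying the mosaic parental DEL


def default_planted_kinds(n: int) -> List[str]:
    """Deterministic mix covering all planted kinds: SV-heavy, with intronic
    SNVs, homozygous-in-ROH cases and one mosaic parent per ten cases."""
    pattern = (
        SECOND_HIT_SV,
        SECOND_HIT_INTRONIC_SNV,
        HOMOZYGOUS_IN_ROH,
        SECOND_HIT_SV,
        SECOND_HIT_INTRONIC_SNV,
        MOSAIC_PARENT_SV,
        SECOND_HIT_SV,
        SECOND_HIT_INTRONIC_SNV,
        HOMOZYGOUS_IN_ROH,
        SECOND_HIT_SV,
    )
    return [pattern[i % len(pattern)] for i in range(n)]


def default_background_spectrum(n: int) -> List[float]:
    return [DEFAULT_SPECTRUM_CYCLE[i % len(DEFAULT_SPECTRUM_CYCLE)] for i in range(n)]


@dataclass
class SimConfig:
    n_families: int = 200
    n_background_sv_clusters: int = 40
    background_freq_spectrum: Optional[List[float]] = None
    breakpoint_jitter_sd: float = 20.0
    caller_dropout_prob: float = 0.1
    n_planted_cases: int = 10
    planted_kinds: Optional[List[str]] = None
    roh_length_mb: float = 20.0
    mean_depth: float = 60.0
    genotype_error_rate: float = 0.005
    seed: int = 0
    # cohort geometry (see docs: the site density is sized so a 5 Mb ROH
    # block carries ~250 sites, comfortably above the detector's min_sites,
    # and a 50-site detector window spans ~1 Mb)
    site_density_per_mb: float = 50.0
    n_genes: int = 30
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 250_000_000, "chr2": 250_000_000}
    )
    private_snvs_per_sample: float = 3.0

    def __post_init__(self) -> None:
        if self.planted_kinds is None:
            self.planted_kinds = default_planted_kinds(self.n_planted_cases)
        if self.background_freq_spectrum is None:
            self.background_freq_spectrum = default_background_spectrum(
                self.n_background_sv_clusters
            )
        if len(self.planted_kinds) != self.n_planted_cases:
            raise ValueError("planted_kinds length must equal n_planted_cases")
        if self.n_planted_cases > self.n_families:
            raise ValueError("more planted cases requested than families")
        if self.n_planted_cases > self.n_genes:
            raise ValueError("more planted cases requested than genes")
        for k in self.planted_kinds:
            if k not in PLANT_KINDS:
                raise ValueError(f"unknown planted kind {k!r}")
        for f in self.background_freq_spectrum:
            if not (0.0 < f < 1.0):
                raise ValueError("background carrier fractions must lie in (0,1)")
        for name in ("caller_dropout_prob", "genotype_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dict(self.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """What was planted in one case, for downstream recall scoring."""

    case_id: str
    family_id: str
    kind: str
    gene_symbol: str
    first_hit_desc: str
    second_hit_kind: str  # "sv" | "snv"
    second_hit_desc: str
    phase: str  # "trans" for compound-het plants, "hom" for ROH plants
    sv_interval: Optional[GenomicInterval] = None
    sv_svtype: Optional[str] = None
    sv_ins_length: Optional[int] = None
    snv_key: Optional[tuple] = None
    mosaic_fraction: Optional[float] = None
    mosaic_sample: Optional[str] = None
    roh_interval: Optional[GenomicInterval] = None


@dataclass
class TrueSv:
    svtype: str
    interval: GenomicInterval
    ins_length: Optional[int]
    carriers: List[Tuple[str, str]]  # (sample_id, genotype)
    planted: bool = False
    mosaic: Dict[str, float] = field(default_factory=dict)  # sample -> fraction
    config_fraction: Optional[float] = None  # configured background carrier fraction


_CODE_TO_STATE = {0: "hom_ref", 1: "het", 2: "hom_alt"}
_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class Backbone:
    """Dense genotype matrix over common backbone sites (alt-allele count
    codes 0/1/2), one block per chromosome."""

    positions: Dict[str, np.ndarray]
    codes: Dict[str, np.ndarray]  # (n_sites, n_samples) int8
    sample_index: Dict[str, int]

    def series(self, sample_id: str, chrom: str) -> List[Tuple[int, str]]:
        """Ordered (pos, state) genotype series for ROH detection."""
        col = self.sample_index[sample_id]
        pos = self.positions[chrom]
        codes = self.codes[chrom][:, col]
        return [(int(p), _CODE_TO_STATE[int(c)]) for p, c in zip(pos, codes)]

    def to_small_variants(self, samples: Sequence[str]) -> List[SmallVariant]:
        """Materialize backbone sites as variant records (carriers only)."""
        out: List[SmallVariant] = []
        cols = [self.sample_index[s] for s in samples]
        for chrom in sorted(self.positions):
            pos = self.positions[chrom]
            codes = self.codes[chrom]
            for i in range(len(pos)):
                row = codes[i]
                genotypes = {
                    samples[k]: _CODE_TO_GT[int(row[c])]
                    for k, c in enumerate(cols)
                    if row[c] > 0
                }
                out.append(
                    SmallVariant(
                        chrom=chrom, pos=int(pos[i]), ref="A", alt="G", genotypes=genotypes
                    )
                )
        return out


@dataclass
class SyntheticCohort:
    config: SimConfig
    samples: List[str]
    pedigree: Pedigree
    genes: List[Gene]
    sv_calls: Dict[str, List[SvCall]]  # caller -> calls
    true_svs: List[TrueSv]
    backbone: Backbone
    rare_variants: List[SmallVariant]
    annotations: Dict[tuple, dict]
    depth: pd.DataFrame
    truth: List[TruthRecord]
    cases: List[CaseRecord]

    @property
    def n_participants(self) -> int:
        return len(self.samples)

    def gene_by_symbol(self, symbol: str) -> Optional[Gene]:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        return None

    def all_calls(self) -> List[SvCall]:
        out: List[SvCall] = []
        for caller in sorted(self.sv_calls):
            out.extend(self.sv_calls[caller])
        return out


def jitter_call(true_sv: SvCall, sd: float, rng: np.random.Generator) -> SvCall:
    """A caller's imperfect observation of a true SV: breakpoints shifted by
    rounded Normal(0, sd) noise, coordinate order repaired.

    Insertions keep their point-like locus (a single jittered breakpoint)
    and their inserted length.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    loc = true_sv.locus
    if true_sv.svtype == "INS":
        bp = max(1, loc.start + int(round(rng.normal(0.0, sd))))
        new_locus = GenomicInterval(loc.chrom, bp, bp + loc.length() - 1)
    else:
        s = loc.start + int(round(rng.normal(0.0, sd)))
        e = loc.end + int(round(rng.normal(0.0, sd)))
        if s > e:
            s, e = e, s
        s = max(1, s)
        e = max(s, e)
        new_locus = GenomicInterval(loc.chrom, s, e)
    return SvCall(
        sample_id=true_sv.sample_id,
        caller=true_sv.caller,
        svtype=true_sv.svtype,
        locus=new_locus,
        ins_length=true_sv.ins_length,
        genotype=true_sv.genotype,
        qual=true_sv.qual,
    )


def _place_genes(config: SimConfig, rng: np.random.Generator) -> List[Gene]:
    chroms = sorted(config.chrom_lengths)
    per_chrom = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1
    genes: List[Gene] = []
    idx = 0
    for chrom in chroms:
        n = per_chrom[chrom]
        if n == 0:
            continue
        slot = config.chrom_lengths[chrom] // (n + 1)
        for j in range(n):
            anchor = slot * (j + 1) + int(rng.integers(-slot // 8, slot // 8 + 1))
            n_exons = int(rng.integers(10, 31))
            exon_lens = rng.integers(80, 301, size=n_exons)
            intron_lens = rng.integers(1500, 8001, size=n_exons - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            start = anchor
            for k in range(n_exons):
                end = start + int(exon_lens[k]) - 1
                exons.append(GenomicInterval(chrom, start, end))
                if k < n_exons - 1:
                    start = end + 1 + int(intron_lens[k])
            body = GenomicInterval(chrom, exons[0].start, exons[-1].end)
            genes.append(
                Gene(
                    gene_id=f"G{idx:04d}",
                    symbol=f"GENE{idx:04d}",
                    body=body,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            idx += 1
    return genes


_BASES = np.array(list("ACGT"))


def _random_snv(rng: np.random.Generator) -> Tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _deep_intronic_pos(gene: Gene, rng: np.random.Generator) -> int:
    """A position well inside an intron (>= 500 bp from flanking exons)."""
    introns = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if b.start - a.end - 1 >= 1200:
            introns.append((a.end + 1, b.start - 1))
    lo, hi = introns[int(rng.integers(len(introns)))]
    return int(rng.integers(lo + 500, hi - 500 + 1))


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_lengths)

    # --- families and samples (column layout: proband, father, mother) ---
    samples: List[str] = []
    ped_records: List[PedRecord] = []
    family_ids: List[str] = []
    for i in range(config.n_families):
        fid = f"FAM{i:04d}"
        family_ids.append(fid)
        p, f, m = f"{fid}_P", f"{fid}_F", f"{fid}_M"
        samples.extend([p, f, m])
        ped_records.append(PedRecord(f, fid, sex="1"))
        ped_records.append(PedRecord(m, fid, sex="2"))
        ped_records.append(PedRecord(p, fid, father_id=f, mother_id=m, affected=True))
    pedigree = Pedigree(ped_records)
    sample_index = {s: k for k, s in enumerate(samples)}

    genes = _place_genes(config, rng)

    # --- choose planted families/genes and their events up front (ROH
    # intervals must be known before backbone genotypes are drawn) ---
    gene_order = rng.permutation(len(genes))
    planted_genes = [genes[gene_order[i]] for i in range(config.n_planted_cases)]
    plants = []  # per planted case: dict of decisions
    roh_plants: List[Tuple[int, GenomicInterval]] = []  # (family index, interval)
    sv_case_counter = 0
    snv_case_counter = 0
    for i, kind in enumerate(config.planted_kinds):
        gene = planted_genes[i]
        fid = family_ids[i]
        proband, father, mother = f"{fid}_P", f"{fid}_F", f"{fid}_M"
        first_parent = father if rng.random() < 0.5 else mother
        second_parent = mother if first_parent == father else father
        plant = {
            "kind": kind,
            "family_index": i,
            "gene": gene,
            "proband": proband,
            "first_parent": first_parent,
            "second_parent": second_parent,
        }
        if kind == HOMOZYGOUS_IN_ROH:
            chrom = gene.body.chrom
            half = int(config.roh_length_mb * 1e6 / 2)
            centre = (gene.body.start + gene.body.end) // 2
            lo = max(1, centre - half)
            hi = min(config.chrom_lengths[chrom], centre + half)
            roh_iv = GenomicInterval(chrom, lo, hi)
            plant["roh_interval"] = roh_iv
            roh_plants.append((i, roh_iv))
        if kind in (SECOND_HIT_SV, MOSAIC_PARENT_SV):
            # every third pure-SV plant is an insertion (LINE1-like, 1591 bp)
            if kind == SECOND_HIT_SV and sv_case_counter % 3 == 1:
                plant["svtype"] = "INS"
            else:
                plant["svtype"] = "DEL"
            sv_case_counter += 1
        if kind == SECOND_HIT_INTRONIC_SNV:
            plant["evidence"] = PLANTED_SNV_EVIDENCE[
                snv_case_counter % len(PLANTED_SNV_EVIDENCE)
            ]
            snv_case_counter += 1
        plants.append(plant)

    # --- backbone genotypes: Mendelian trios over common sites ---
    positions: Dict[str, np.ndarray] = {}
    codes: Dict[str, np.ndarray] = {}
    n_fam = config.n_families
    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        n_sites = int(round(config.site_density_per_mb * length / 1e6))
        # distinct positions without materializing the whole chromosome:
        # over-draw, deduplicate, subsample back to the target count
        draw = rng.integers(1, length + 1, size=int(n_sites * 1.2) + 16, dtype=np.int64)
        uniq = np.unique(draw)
        keep = rng.choice(len(uniq), size=n_sites, replace=False)
        pos = np.sort(uniq[keep])
        # parental allele draws (allele frequency 0.5), child inherits one
        # allele from each parent
        fa = rng.integers(0, 2, size=(n_sites, n_fam, 2), dtype=np.int8)
        ma = rng.integers(0, 2, size=(n_sites, n_fam, 2), dtype=np.int8)
        pick_f = rng.integers(0, 2, size=(n_sites, n_fam))
        pick_m = rng.integers(0, 2, size=(n_sites, n_fam))
        child = (
            np.take_along_axis(fa, pick_f[:, :, None], axis=2)[:, :, 0]
            + np.take_along_axis(ma, pick_m[:, :, None], axis=2)[:, :, 0]
        ).astype(np.int8)
        father = fa.sum(axis=2, dtype=np.int8)
        mother = ma.sum(axis=2, dtype=np.int8)
        block = np.empty((n_sites, 3 * n_fam), dtype=np.int8)
        block[:, 0::3] = child
        block[:, 1::3] = father
        block[:, 2::3] = mother
        positions[chrom] = pos
        codes[chrom] = block

    # overwrite planted ROH families: parents share one allele per site,
    # child homozygous for it, with heterozygote contamination at the
    # genotyping error rate
    for fam_i, roh_iv in roh_plants:
        chrom = roh_iv.chrom
        pos = positions[chrom]
        mask = (pos >= roh_iv.start) & (pos <= roh_iv.end)
        n_in = int(mask.sum())
        shared = rng.integers(0, 2, size=n_in, dtype=np.int8)
        other_f = rng.integers(0, 2, size=n_in, dtype=np.int8)
        other_m = rng.integers(0, 2, size=n_in, dtype=np.int8)
        codes[chrom][mask, 3 * fam_i + 1] = shared + other_f
        codes[chrom][mask, 3 * fam_i + 2] = shared + other_m
        child = (2 * shared).astype(np.int8)
        contam = rng.random(n_in) < config.genotype_error_rate
        child[contam] = 1
        codes[chrom][mask, 3 * fam_i] = child

    backbone = Backbone(positions=positions, codes=codes, sample_index=sample_index)

    # --- planted variants, cases and truth ---
    rare_variants: List[SmallVariant] = []
    annotations: Dict[tuple, dict] = {}
    true_svs: List[TrueSv] = []
    truth: List[TruthRecord] = []
    cases: List[CaseRecord] = []
    used_keys = set()
    depth_rows: List[dict] = []

    def add_depth_rows(sample: str, iv: GenomicInterval, f: float) -> None:
        """Observed mean depths over the SV span and over equal-length
        flanks separated by a 1 kb breakpoint guard zone."""
        L = iv.length()
        guard = 1000
        mean = config.mean_depth
        d_in = rng.poisson(mean * (1.0 - f / 2.0) * L) / L
        depth_rows.append(
            {"sample_id": sample, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "mean_depth": round(float(d_in), 3)}
        )
        left = GenomicInterval(iv.chrom, max(1, iv.start - guard - L), max(1, iv.start - guard - 1))
        right = GenomicInterval(iv.chrom, iv.end + guard + 1, iv.end + guard + L)
        for flank in (left, right):
            d = rng.poisson(mean * flank.length()) / flank.length()
            depth_rows.append(
                {"sample_id": sample, "chrom": flank.chrom, "start": flank.start,
                 "end": flank.end, "mean_depth": round(float(d), 3)}
            )

    for i, plant in enumerate(plants):
        kind = plant["kind"]
        gene: Gene = plant["gene"]
        fid = family_ids[plant["family_index"]]
        proband = plant["proband"]
        case_id = f"CASE{i:03d}"
        chrom = gene.body.chrom
        n_exons = len(gene.exons)

        if kind == HOMOZYGOUS_IN_ROH:
            # recruited on a region of homozygosity, no specific first variant
            pos = _deep_intronic_pos(gene, rng)
            ref, alt = _random_snv(rng)
            snv = SmallVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                genotypes={proband: "1/1", plant["first_parent"]: "0/1",
                           plant["second_parent"]: "0/1"},
            )
            rare_variants.append(snv)
            used_keys.add(snv.key)
            annotations[snv.key] = {
                "cadd_phred": 18.5,
                "splice_deltas": {"AG": 0.99},
            }
            first_hit = FirstHit(
                gene_symbol=gene.symbol, kind=FirstHitKind.ROH_ONLY,
                description=f"ROH over {gene.symbol}",
            )
            truth.append(
                TruthRecord(
                    case_id=case_id, family_id=fid, kind=kind, gene_symbol=gene.symbol,
                    first_hit_desc="ROH_only", second_hit_kind="snv",
                    second_hit_desc=f"{chrom}:{pos}:{ref}:{alt} hom",
                    phase="hom", snv_key=snv.key, roh_interval=plant["roh_interval"],
                )
            )
        else:
            # planted first hit: an exonic SNV in the first third of the gene
            fh_exon = gene.exons[int(rng.integers(0, max(1, n_exons // 3)))]
            fh_pos = int(rng.integers(fh_exon.start, fh_exon.end + 1))
            fh_ref, fh_alt = _random_snv(rng)
            fh_var = SmallVariant(
                chrom=chrom, pos=fh_pos, ref=fh_ref, alt=fh_alt,
                genotypes={proband: "0/1", plant["first_parent"]: "0/1"},
            )
            rare_variants.append(fh_var)
            used_keys.add(fh_var.key)
            annotations[fh_var.key] = {"cadd_phred": 25.0}
            first_hit = FirstHit(
                gene_symbol=gene.symbol, kind=FirstHitKind.SMALL_VARIANT,
                variant_key=fh_var.key,
                description=f"{chrom}:{fh_pos}:{fh_ref}:{fh_alt}",
            )
            second_parent = plant["second_parent"]

            if kind == SECOND_HIT_INTRONIC_SNV:
                pos = _deep_intronic_pos(gene, rng)
                ref, alt = _random_snv(rng)
                snv = SmallVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    genotypes={proband: "0/1", second_parent: "0/1"},
                )
                rare_variants.append(snv)
                used_keys.add(snv.key)
                channel, delta, cadd = plant["evidence"]
                annotations[snv.key] = {
                    "cadd_phred": cadd, "splice_deltas": {channel: delta},
                }
                truth.append(
                    TruthRecord(
                        case_id=case_id, family_id=fid, kind=kind,
                        gene_symbol=gene.symbol, first_hit_desc=first_hit.description,
                        second_hit_kind="snv",
                        second_hit_desc=f"{chrom}:{pos}:{ref}:{alt}",
                        phase="trans", snv_key=snv.key,
                    )
                )
            else:  # SECOND_HIT_SV or MOSAIC_PARENT_SV
                if plant["svtype"] == "INS":
                    ex = gene.exons[int(rng.integers(n_exons // 2, n_exons))]
                    bp = int(rng.integers(ex.start, ex.end + 1))
                    iv = GenomicInterval(chrom, bp, bp)
                    true_sv = TrueSv(
                        svtype="INS", interval=iv, ins_length=1591,
                        carriers=[(proband, "het"), (second_parent, "het")],
                        planted=True,
                    )
                else:
                    # deletion over 1-3 exons in the distal half of the gene
                    first_ex = int(rng.integers(n_exons // 2, n_exons - 1))
                    last_ex = min(n_exons - 1, first_ex + int(rng.integers(1, 4)) - 1)
                    pad_l = int(rng.integers(200, 2001))
                    pad_r = int(rng.integers(200, 2001))
                    iv = GenomicInterval(
                        chrom,
                        max(1, gene.exons[first_ex].start - pad_l),
                        gene.exons[last_ex].end + pad_r,
                    )
                    mosaic = {}
                    if kind == MOSAIC_PARENT_SV:
                        mosaic = {second_parent: MOSAIC_TRUE_FRACTION}
                    true_sv = TrueSv(
                        svtype="DEL", interval=iv, ins_length=None,
                        carriers=[(proband, "het"), (second_parent, "het")],
                        planted=True, mosaic=mosaic,
                    )
                true_svs.append(true_sv)
                if true_sv.svtype == "DEL":
                    for member in (proband, f"{fid}_F", f"{fid}_M"):
                        if member == proband:
                            frac = 1.0
                        elif member == second_parent:
                            frac = true_sv.mosaic.get(member, 1.0)
                        else:
                            frac = 0.0
                        add_depth_rows(member, true_sv.interval, frac)
                mosaic_frac = true_sv.mosaic.get(second_parent)
                truth.append(
                    TruthRecord(
                        case_id=case_id, family_id=fid, kind=kind,
                        gene_symbol=gene.symbol, first_hit_desc=first_hit.description,
                        second_hit_kind="sv",
                        second_hit_desc=f"{true_sv.svtype} {true_sv.interval}",
                        phase="trans", sv_interval=true_sv.interval,
                        sv_svtype=true_sv.svtype, sv_ins_length=true_sv.ins_length,
                        mosaic_fraction=mosaic_frac,
                        mosaic_sample=second_parent if mosaic_frac else None,
                    )
                )

        cases.append(
            CaseRecord(
                case_id=case_id, proband_id=proband,
                referral_condition="synthetic recessive disorder",
                first_hit=first_hit, solved=SolvedStatus.UNSOLVED,
            )
        )

    # unplanted families: recruited with a (randomly chosen) first-hit gene
    # but no plant; these measure the screen's false-positive behaviour
    for i in range(config.n_planted_cases, config.n_families):
        fid = family_ids[i]
        gene = genes[int(rng.integers(len(genes)))]
        cases.append(
            CaseRecord(
                case_id=f"CASE{i:03d}", proband_id=f"{fid}_P",
                referral_condition="synthetic recessive disorder",
                first_hit=FirstHit(
                    gene_symbol=gene.symbol, kind=FirstHitKind.NONE,
                    description="no confirmed first-hit variant",
                ),
                solved=SolvedStatus.UNSOLVED,
            )
        )

    # --- background SV clusters at configured carrier fractions ---
    genome = [(c, config.chrom_lengths[c]) for c in chroms]
    total_len = sum(l for _, l in genome)
    for f_cfg in config.background_freq_spectrum:
        r = int(rng.integers(total_len))
        for chrom, length in genome:
            if r < length:
                break
            r -= length
        sv_len = int(rng.integers(2000, 50_001))
        start = int(rng.integers(1, max(2, length - sv_len)))
        svtype = str(rng.choice(["DEL", "DUP", "INV"], p=[0.5, 0.3, 0.2]))
        iv = GenomicInterval(chrom, start, start + sv_len - 1)
        carriers: List[Tuple[str, str]] = []
        father_carrier = rng.random(n_fam) < f_cfg
        mother_carrier = rng.random(n_fam) < f_cfg
        pass_f = father_carrier & (rng.random(n_fam) < 0.5)
        pass_m = mother_carrier & (rng.random(n_fam) < 0.5)
        for j in range(n_fam):
            fid = family_ids[j]
            if father_carrier[j]:
                carriers.append((f"{fid}_F", "het"))
            if mother_carrier[j]:
                carriers.append((f"{fid}_M", "het"))
            n_child = int(pass_f[j]) + int(pass_m[j])
            if n_child:
                carriers.append((f"{fid}_P", "hom" if n_child == 2 else "het"))
        true_svs.append(
            TrueSv(svtype=svtype, interval=iv, ins_length=None,
                   carriers=carriers, config_fraction=f_cfg)
        )

    # --- caller observations: jitter + dropout ---
    sv_calls: Dict[str, List[SvCall]] = {"A": [], "B": []}
    for sv in true_svs:
        for sample, genotype in sv.carriers:
            emitted = []
            for caller in ("A", "B"):
                if rng.random() < config.caller_dropout_prob:
                    continue
                emitted.append(caller)
            if sv.planted and not emitted:
                # a planted second hit must exist in the call set for the
                # screen's recall to be defined; keep one caller
                emitted = ["A"]
            for caller in emitted:
                truth_call = SvCall(
                    sample_id=sample, caller=caller, svtype=sv.svtype,
                    locus=sv.interval, ins_length=sv.ins_length,
                    genotype=genotype, qual=float(round(rng.uniform(20, 60), 1)),
                )
                sv_calls[caller].append(
                    jitter_call(truth_call, config.breakpoint_jitter_sd, rng)
                )
    for caller in sv_calls:
        sv_calls[caller].sort(
            key=lambda c: (c.locus.chrom, c.locus.start, c.locus.end, c.sample_id)
        )

    # --- private rare SNVs (screen false-positive background) ---
    n_priv = rng.poisson(config.private_snvs_per_sample, size=len(samples))
    for s_i, sample in enumerate(samples):
        for _ in range(int(n_priv[s_i])):
            r = int(rng.integers(total_len))
            for chrom, length in genome:
                if r < length:
                    break
                r -= length
            pos = int(rng.integers(1, length + 1))
            ref, alt = _random_snv(rng)
            key = (chrom, pos, ref, alt)
            if key in used_keys:
                continue
            used_keys.add(key)
            rare_variants.append(
                SmallVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             genotypes={sample: "0/1"})
            )

    compute_cohort_af(rare_variants, len(samples))
    depth = pd.DataFrame(
        depth_rows, columns=["sample_id", "chrom", "start", "end", "mean_depth"]
    )

    return SyntheticCohort(
        config=config, samples=samples, pedigree=pedigree, genes=genes,
        sv_calls=sv_calls, true_svs=true_svs, backbone=backbone,
        rare_variants=rare_variants, annotations=annotations, depth=depth,
        truth=truth, cases=cases,
    )


TRUTH_COLUMNS = [
    "case_id", "family_id", "kind", "gene_symbol", "first_hit", "second_hit_kind",
    "second_hit", "phase", "sv_chrom", "sv_start", "sv_end", "sv_svtype",
    "sv_ins_length", "snv_key", "mosaic_fraction", "mosaic_sample",
    "roh_chrom", "roh_start", "roh_end",
]


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "case_id": t.case_id, "family_id": t.family_id, "kind": t.kind,
                "gene_symbol": t.gene_symbol, "first_hit": t.first_hit_desc,
                "second_hit_kind": t.second_hit_kind, "second_hit": t.second_hit_desc,
                "phase": t.phase,
                "sv_chrom": t.sv_interval.chrom if t.sv_interval else "",
                "sv_start": t.sv_interval.start if t.sv_interval else "",
                "sv_end": t.sv_interval.end if t.sv_interval else "",
                "sv_svtype": t.sv_svtype or "",
                "sv_ins_length": t.sv_ins_length or "",
                "snv_key": ":".join(map(str, t.snv_key)) if t.snv_key else "",
                "mosaic_fraction": t.mosaic_fraction if t.mosaic_fraction else "",
                "mosaic_sample": t.mosaic_sample or "",
                "roh_chrom": t.roh_interval.chrom if t.roh_interval else "",
                "roh_start": t.roh_interval.start if t.roh_interval else "",
                "roh_end": t.roh_interval.end if t.roh_interval else "",
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, Path]:
    """Write the cohort in the exact formats the rest of the package reads."""
    from .smallvar import write_annotation_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sv_vcf_A": out / "caller_A.sv.vcf",
        "sv_vcf_B": out / "caller_B.sv.vcf",
        "small_vcf": out / "small_variants.vcf",
        "ped": out / "cohort.ped",
        "genes": out / "genes.bed",
        "depth": out / "depth.tsv",
        "truth": out / "truth.tsv",
        "cases": out / "cases.tsv",
        "annotations": out / "annotations.tsv",
        "config": out / "config.yaml",
    }
    contigs = dict(cohort.config.chrom_lengths)
    write_sv_vcf(cohort.sv_calls["A"], paths["sv_vcf_A"], cohort.samples, contigs)
    write_sv_vcf(cohort.sv_calls["B"], paths["sv_vcf_B"], cohort.samples, contigs)
    all_small = cohort.backbone.to_small_variants(cohort.samples) + cohort.rare_variants
    write_small_variant_vcf(all_small, paths["small_vcf"], cohort.samples, contigs)
    write_ped(cohort.pedigree, paths["ped"])
    write_gene_bed(cohort.genes, paths["genes"])
    write_depth_tsv(cohort.depth, paths["depth"])
    truth_to_frame(cohort.truth).to_csv(paths["truth"], sep="\t", index=False)
    write_case_manifest(cohort.cases, paths["cases"])
    write_annotation_tsv(cohort.annotations, paths["annotations"])
    cohort.config.to_yaml(paths["config"])
    return paths
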