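"""File I/O for the standard formats: VCF 4.2 (via pysam), exon BED, and the
depth TSV.

Internal coordinates are 1-based inclusive (VCF-native); BED files are
0-based half-open and converted at this boundary only.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .intervals import Gene, GenomicInterval
from .variants import SmallVariant, SvCall

logger = logging.getLogger(__name__)

DEFAULT_CONTIGS: Dict[str, int] = {"chr1": 250_000_000, "chr2": 250_000_000}


def _sv_header(samples: Sequence[str], contigs: Dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.info.add("SVTYPE", 1, "String", "Type of structural variant")
    h.info.add("SVLEN", 1, "Integer", "Length of inserted sequence for INS")
    h.info.add("CALLER", 1, "String", "Calling algorithm label")
    h.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        h.add_sample(s)
    return h


_SV_GT = {"het": (0, 1), "hom": (1, 1), "missing": (None, None)}


def write_sv_vcf(
    calls: Sequence[SvCall],
    path,
    samples: Optional[Sequence[str]] = None,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write SV calls as VCF 4.2 with symbolic ALTs, one record per call.

    Each record genotypes only the call's own sample as non-reference, so a
    read round-trip reproduces the call list exactly.
    """
    if samples is None:
        samples = sorted({c.sample_id for c in calls})
    if contigs is None:
        contigs = dict(DEFAULT_CONTIGS)
        for c in calls:
            contigs.setdefault(c.locus.chrom, c.locus.end + 1_000_000)
    header = _sv_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in calls:
            rec = vf.new_record(
                contig=c.locus.chrom,
                start=c.locus.start - 1,
                alleles=("N", f"<{c.svtype}>"),
            )
            rec.stop = c.locus.end
            rec.info["SVTYPE"] = c.svtype
            rec.info["CALLER"] = c.caller
            if c.ins_length is not None:
                rec.info["SVLEN"] = c.ins_length
            rec.qual = c.qual
            for s in samples:
                rec.samples[s]["GT"] = _SV_GT[c.genotype] if s == c.sample_id else (0, 0)
            vf.write(rec)


def _info_get(rec, key: str, default=None):
    # pysam raises when a key is absent from the header, not just the record
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _gt_to_sv_genotype(gt: Tuple) -> Optional[str]:
    if gt is None or all(a is None for a in gt):
        return "missing"
    alleles = [a for a in gt if a is not None]
    n_alt = sum(1 for a in alleles if a and a > 0)
    if n_alt == 0:
        return None  # homozygous reference: not a call
    return "hom" if n_alt >= 2 else "het"


def _validate_sv_ends(path) -> None:
    """Reject records with END < POS by name.

    htslib silently discards a malformed END (demoting the record to a
    1 bp span), so this contract needs an explicit pre-scan of the INFO
    column.
    """
    import gzip
    import re

    opener = gzip.open if str(path).endswith(".gz") else open
    end_re = re.compile(r"(?:^|;)END=(\d+)")
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.split("\t", 8)
            if len(fields) < 8:
                continue
            m = end_re.search(fields[7])
            if m and int(m.group(1)) < int(fields[1]):
                raise ValueError(
                    f"record {fields[0]}:{fields[1]} has END={m.group(1)} < POS"
                )


def read_sv_vcf(path, default_caller: str = "A") -> List[SvCall]:
    """Read an SV VCF into calls: one call per sample with a non-reference
    genotype per record.

    Records without SVTYPE are rejected with a logged warning; a record
    whose END precedes POS is a hard error naming the record.
    """
    _validate_sv_ends(path)
    calls: List[SvCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None:
                logger.warning(
                    "record %s:%d has no SVTYPE; rejected", rec.chrom, rec.pos
                )
                continue
            end = rec.stop
            if end < rec.pos:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} has END={end} < POS={rec.pos}"
                )
            caller = _info_get(rec, "CALLER", default_caller)
            ins_length = _info_get(rec, "SVLEN") if svtype == "INS" else None
            locus = GenomicInterval(rec.chrom, rec.pos, max(rec.pos, end))
            qual = rec.qual if rec.qual is not None else 0.0
            for sample in rec.samples:
                gt = rec.samples[sample].get("GT")
                genotype = _gt_to_sv_genotype(gt)
                if genotype is None or genotype == "missing":
                    continue
                calls.append(
                    SvCall(
                        sample_id=sample,
                        caller=caller,
                        svtype=svtype,
                        locus=locus,
                        ins_length=ins_length,
                        genotype=genotype,
                        qual=qual,
                    )
                )
    return calls


def _small_header(samples: Sequence[str], contigs: Dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        h.add_sample(s)
    return h


_SMALL_GT = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}


def write_small_variant_vcf(
    variants: Sequence[SmallVariant],
    path,
    samples: Sequence[str],
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write a multi-sample small-variant VCF (genotypes only; evidence
    annotations travel in the separate annotation TSV)."""
    if contigs is None:
        contigs = dict(DEFAULT_CONTIGS)
        for v in variants:
            contigs.setdefault(v.chrom, v.pos + 1_000_000)
    header = _small_header(samples, contigs)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in ordered:
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            for s in samples:
                rec.samples[s]["GT"] = _SMALL_GT[v.genotype_of(s)]
            vf.write(rec)


def read_small_variant_vcf(path) -> Tuple[List[SmallVariant], List[str]]:
    """Read a multi-sample VCF into small variants.

    Multi-allelic records are split into one bi-allelic variant per ALT;
    genotypes are recoded against each ALT in turn.  Only non-reference
    genotypes are stored (absent samples are implicitly 0/0).
    """
    variants: List[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: Dict[str, str] = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or all(a is None for a in gt):
                        genotypes[s] = "./."
                        continue
                    n_alt = sum(1 for a in gt if a == alt_index)
                    if n_alt == 0:
                        continue
                    genotypes[s] = "1/1" if n_alt >= 2 else "0/1"
                variants.append(
                    SmallVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                    )
                )
    return variants, samples


def write_gene_bed(genes: Sequence[Gene], path) -> None:
    """Write genes as BED12 (exons as blocks, 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            chrom_start = g.body.start - 1
            chrom_end = g.body.end
            exons = g.exons or (g.body,)
            sizes = ",".join(str(e.length()) for e in exons) + ","
            starts = ",".join(str(e.start - 1 - chrom_start) for e in exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.body.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        g.symbol,
                        "0",
                        g.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_gene_bed(path) -> List[Gene]:
    """Read a BED12 gene file written by :func:`write_gene_bed`."""
    genes: List[Gene] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {i + 1}: expected BED12, got {len(fields)} fields")
            chrom = fields[0]
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            symbol = fields[3]
            strand = fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            body = GenomicInterval(chrom, chrom_start + 1, chrom_end)
            exons = tuple(
                GenomicInterval(chrom, chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(
                Gene(gene_id=symbol, symbol=symbol, body=body, strand=strand, exons=exons)
            )
    return genes


DEPTH_COLUMNS = ["sample_id", "chrom", "start", "end", "mean_depth"]


def read_depth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth TSV missing columns: {sorted(missing)}")
    return df


def write_depth_tsv(df: pd.DataFrame, path) -> None:
    df.loc[:, DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)
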