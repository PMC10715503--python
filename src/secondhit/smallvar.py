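"""Rare small-variant retrieval, evidence annotation and ranking.

Population allele frequencies are the only *filter*: a variant is retained
iff every frequency that is present (1000 Genomes, gnomAD, cohort) is below
the rarity threshold, and an absent frequency is treated as zero (novel).
Deleteriousness (CADD) and splice delta scores are *ranking evidence only*
and never exclude a variant: demonstrably pathogenic deep-intronic variants
can score near zero on splice predictors, so a low score must not act as a
gate.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .intervals import GenomicInterval
from .variants import SPLICE_CHANNELS, SmallVariant, variant_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceWeights:
    """Rarity threshold and ranking weights.

    ``cadd_floor`` affects ranking only: CADD values below it contribute
    nothing to the score (default 0, i.e. every present CADD contributes).
    It is never a hard filter.
    """

    af_rare_threshold: float = 0.01
    cadd_floor: float = 0.0
    cadd_weight: float = 1.0
    splice_max_delta_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.af_rare_threshold <= 1.0):
            raise ValueError("af_rare_threshold must lie in (0,1]")
        if self.cadd_weight < 0 or self.splice_max_delta_weight < 0:
            raise ValueError("ranking weights must be non-negative")


def ranking_score(v: SmallVariant, weights: EvidenceWeights = EvidenceWeights()) -> float:
    """Evidence score for ordering candidates; absent terms contribute 0."""
    score = 0.0
    if v.cadd_phred is not None and v.cadd_phred >= weights.cadd_floor:
        score += weights.cadd_weight * v.cadd_phred
    delta = v.max_splice_delta()
    if delta is not None:
        score += weights.splice_max_delta_weight * delta
    return score


def is_rare(v: SmallVariant, threshold: float) -> bool:
    """True iff every present population AF is strictly below *threshold*."""
    for name, af in v.population_afs().items():
        if af is not None and af >= threshold:
            logger.debug("drop %s: %s=%.4g >= %.4g", v.key, name, af, threshold)
            return False
    return True


def filter_rare_small(
    variants: Iterable[SmallVariant],
    sample_id: str,
    weights: EvidenceWeights = EvidenceWeights(),
) -> List[SmallVariant]:
    """Variants carried by *sample_id* and rare in every AF resource,
    sorted by descending ranking score (position breaks ties).

    Ranking never excludes: the returned set depends on the AF threshold
    only.
    """
    kept = [
        v
        for v in variants
        if v.is_carrier(sample_id) and is_rare(v, weights.af_rare_threshold)
    ]
    kept.sort(key=lambda v: (-ranking_score(v, weights), v.chrom, v.pos, v.ref, v.alt))
    return kept


class VariantIndex:
    """Per-chromosome position-sorted index over small variants for fast
    window queries."""

    def __init__(self, variants: Sequence[SmallVariant]):
        self._by_chrom: Dict[str, Tuple[List[int], List[SmallVariant]]] = {}
        by_chrom: Dict[str, List[SmallVariant]] = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for chrom, vs in by_chrom.items():
            vs.sort(key=lambda v: (v.pos, v.ref, v.alt))
            self._by_chrom[chrom] = ([v.pos for v in vs], vs)
        self._all = list(variants)

    def __len__(self) -> int:
        return len(self._all)

    def __iter__(self):
        return iter(self._all)

    def in_window(self, window: GenomicInterval) -> List[SmallVariant]:
        entry = self._by_chrom.get(window.chrom)
        if entry is None:
            return []
        positions, vs = entry
        lo = bisect.bisect_left(positions, window.start)
        hi = bisect.bisect_right(positions, window.end)
        return vs[lo:hi]

    def lookup(self, key) -> Optional[SmallVariant]:
        chrom, pos, ref, alt = key
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, vs = entry
        lo = bisect.bisect_left(positions, pos)
        while lo < len(vs) and vs[lo].pos == pos:
            if vs[lo].ref == ref and vs[lo].alt == alt:
                return vs[lo]
            lo += 1
        return None


ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "af_1000g",
    "af_gnomad",
    "cadd_phred",
    "ag",
    "al",
    "dg",
    "dl",
]


def read_annotation_tsv(path) -> Dict[tuple, dict]:
    """Read a precomputed annotation table keyed by (chrom, pos, ref, alt).

    Empty cells mean absent.  The package consumes these scores; it never
    runs the underlying models.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    table: Dict[tuple, dict] = {}
    for row in df.itertuples(index=False):
        rec: dict = {}
        for col in ("af_1000g", "af_gnomad", "cadd_phred"):
            val = getattr(row, col)
            if pd.notna(val):
                rec[col] = float(val)
        deltas = {}
        for ch in SPLICE_CHANNELS:
            val = getattr(row, ch.lower())
            if pd.notna(val):
                deltas[ch] = float(val)
        if deltas:
            rec["splice_deltas"] = deltas
        table[variant_key(row.chrom, int(row.pos), row.ref, row.alt)] = rec
    return table


def write_annotation_tsv(table: Dict[tuple, dict], path) -> None:
    rows = []
    for (chrom, pos, ref, alt), rec in sorted(table.items()):
        deltas = rec.get("splice_deltas", {})
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "af_1000g": rec.get("af_1000g"),
                "af_gnomad": rec.get("af_gnomad"),
                "cadd_phred": rec.get("cadd_phred"),
                "ag": deltas.get("AG"),
                "al": deltas.get("AL"),
                "dg": deltas.get("DG"),
                "dl": deltas.get("DL"),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def apply_annotations(variants: Iterable[SmallVariant], table: Dict[tuple, dict]) -> None:
    """Attach AFs/CADD/splice deltas from an annotation table, in place."""
    for v in variants:
        rec = table.get(v.key)
        if rec is None:
            continue
        if "af_1000g" in rec:
            v.af_1000g = rec["af_1000g"]
        if "af_gnomad" in rec:
            v.af_gnomad = rec["af_gnomad"]
        if "cadd_phred" in rec:
            v.cadd_phred = rec["cadd_phred"]
        if "splice_deltas" in rec:
            v.splice_deltas = dict(rec["splice_deltas"])
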