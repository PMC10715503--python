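"""Run-of-homozygosity (ROH) detection from a genotype series.

A sliding window of a fixed number of consecutive sites is flagged when it
contains at most a small number of heterozygous genotypes; overlapping
flagged windows are merged and short or sparse merged regions discarded.
Site-count windows (rather than physical-length windows) make the detector
robust to variant-density variation.  Defaults are sized to comfortably
detect multi-megabase ROH of the scale seen in consanguineous probands
(roughly 5-20 Mb) while tolerating sporadic genotyping errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval

HOM_STATES = ("hom_ref", "hom_alt")
GT_STATES = ("het",) + HOM_STATES


@dataclass(frozen=True)
class RohRegion:
    interval: GenomicInterval
    n_sites: int
    n_het: int

    @property
    def het_fraction(self) -> float:
        return self.n_het / self.n_sites if self.n_sites else 0.0


@dataclass(frozen=True)
class RohParams:
    window_sites: int = 50
    max_het_per_window: int = 2
    min_length_mb: float = 2.0
    min_sites: int = 100
    max_het_fraction: float = 0.05


def detect_roh(
    sites: Sequence[Tuple[int, str]],
    params: RohParams = RohParams(),
) -> List[RohRegion]:
    """Detect ROH on one chromosome of one sample.

    *sites* is an ordered (by position, strictly increasing) sequence of
    ``(pos, gt)`` with gt in ``{"het", "hom_ref", "hom_alt"}``.
    """
    n = len(sites)
    if n == 0:
        return []
    pos = np.asarray([p for p, _ in sites], dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be sorted by position")
    for _, gt in sites:
        if gt not in GT_STATES:
            raise ValueError(f"unknown genotype state {gt!r}")
    het = np.asarray([gt == "het" for _, gt in sites], dtype=np.int32)
    w = params.window_sites
    if n < w:
        return []
    # het count per window of w consecutive sites
    csum = np.concatenate(([0], np.cumsum(het)))
    win_het = csum[w:] - csum[:-w]  # length n - w + 1
    flagged = win_het <= params.max_het_per_window
    if not flagged.any():
        return []
    # site i is covered if any flagged window [j, j+w-1] contains it
    covered = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(flagged)
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + w, -1)
    covered = np.cumsum(delta[:-1]) > 0
    # runs of covered sites -> candidate regions
    edges = np.diff(covered.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1) + 1
    run_ends = np.flatnonzero(edges == -1)
    if covered[0]:
        run_starts = np.concatenate(([0], run_starts))
    if covered[-1]:
        run_ends = np.concatenate((run_ends, [n - 1]))
    regions: List[RohRegion] = []
    min_len_bp = params.min_length_mb * 1e6
    for i0, i1 in zip(run_starts, run_ends):
        n_sites = int(i1 - i0 + 1)
        n_het = int(het[i0 : i1 + 1].sum())
        iv = GenomicInterval("?", int(pos[i0]), int(pos[i1]))
        if iv.length() < min_len_bp:
            continue
        if n_sites < params.min_sites:
            continue
        if n_sites and n_het / n_sites > params.max_het_fraction:
            continue
        regions.append(RohRegion(iv, n_sites, n_het))
    return regions


def detect_roh_chrom(
    chrom: str,
    sites: Sequence[Tuple[int, str]],
    params: RohParams = RohParams(),
) -> List[RohRegion]:
    """As :func:`detect_roh`, with the chromosome name stamped on regions."""
    return [
        RohRegion(GenomicInterval(chrom, r.interval.start, r.interval.end), r.n_sites, r.n_het)
        for r in detect_roh(sites, params)
    ]


def containing_roh(
    regions: Sequence[RohRegion], locus: GenomicInterval
) -> Optional[RohRegion]:
    """The ROH region fully containing *locus*; the longest if several."""
    best = None
    for r in regions:
        if r.interval.contains(locus):
            if best is None or r.interval.length() > best.interval.length():
                best = r
    return best


def write_roh_bed(regions: Sequence[RohRegion], path) -> None:
    """Write regions as BED (0-based half-open) with site/het counts."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}\t"
                f"sites={r.n_sites};het={r.n_het}\n"
            )
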