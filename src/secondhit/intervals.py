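"""Genomic interval arithmetic on a 1-based, fully-closed coordinate system.

All coordinates in this package are VCF/HGVS style: 1-based and inclusive at
both ends.  BED I/O converts at the file boundary (see :mod:`secondhit.vcfio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored span, 1-based and inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) on {self.chrom}"
            )

    def length(self) -> int:
        """Number of bases covered (end - start + 1); always positive."""
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Bases shared with *other*; 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment of *other* within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def padded(self, bp: int) -> "GenomicInterval":
        """Extend by *bp* on each side, clamped to position 1."""
        return GenomicInterval(self.chrom, max(1, self.start - bp), self.end + bp)

    def __str__(self) -> str:  # chr2:135165337-135511837
        return f"{self.chrom}:{self.start}-{self.end}"


def span_kb(iv: GenomicInterval) -> float:
    """Span of an interval in kb, as quoted clinically: (end - start)/1000.

    Uses the coordinate difference (not the base count) and reports one
    decimal place, which is the convention used when deletion/duplication
    sizes are quoted from their breakpoint coordinates.
    """
    return round((iv.end - iv.start) / 1000.0, 1)


@dataclass(frozen=True)
class Gene:
    """A gene body with an ordered, non-overlapping exon structure."""

    gene_id: str
    symbol: str
    body: GenomicInterval
    strand: str
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for ex in exons:
            if not self.body.contains(ex):
                raise ValueError(f"exon {ex} outside gene body {self.body}")
            if prev_end is not None and ex.start <= prev_end:
                raise ValueError("exons must be sorted by start and non-overlapping")
            prev_end = ex.end

    def window(self, pad_bp: int = 1000) -> GenomicInterval:
        """Gene body padded by *pad_bp* on both sides (the screening window)."""
        return self.body.padded(pad_bp)
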