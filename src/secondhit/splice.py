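"""Splice-consequence arithmetic: retained-intron, pseudoexon and exon-skip
lengths, and frameshift status.

Only length and reading-frame arithmetic is performed here; sequence-level
splice-site scoring is consumed from precomputed annotation (see
:mod:`secondhit.smallvar`), never computed.  Protein-level consequences
(the termination offset of a frameshift) require transcript sequence and are
out of scope: the package reports frameshift yes/no only.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional


def frameshift(n_nt: int) -> bool:
    """True iff inserting/removing *n_nt* bases shifts the reading frame."""
    if n_nt < 0:
        raise ValueError("n_nt must be non-negative")
    return n_nt % 3 != 0


@dataclass(frozen=True)
class SpliceConsequence:
    """Net coding-sequence change of a splice event."""

    inserted_or_removed_nt: int
    frameshift: bool

    def __post_init__(self) -> None:
        if self.frameshift != (self.inserted_or_removed_nt % 3 != 0):
            raise ValueError("frameshift flag inconsistent with mod-3 rule")


def acceptor_gain_retention(offset: int) -> int:
    """Retained intronic bases when a new splice acceptor is created at an
    intronic offset ``c.X-k`` upstream of an exon.

    The new acceptor's AG dinucleotide ends at intronic position ``-k``, so
    splicing now includes intronic positions ``-(k-1) .. -1``: ``k - 1``
    bases.  A variant with offset -26 therefore retains 25 bp.

    Offsets -1/-2 are the canonical acceptor dinucleotide itself and are a
    different variant category; they are rejected here.
    """
    if offset > -3:
        raise ValueError(
            f"offset {offset} is within the canonical acceptor site; "
            "acceptor-gain retention requires offset <= -3"
        )
    return -offset - 1


def pseudoexon_length(first_pos: int, last_pos: int) -> int:
    """Length of an aberrantly included intronic pseudoexon (inclusive span)."""
    if last_pos < first_pos:
        raise ValueError("last_pos must be >= first_pos")
    return last_pos - first_pos + 1


def exon_skip_consequence(c_start: int, c_end: int) -> SpliceConsequence:
    """Consequence of skipping the exon spanning cDNA positions c_start..c_end."""
    if c_start < 1 or c_end < c_start:
        raise ValueError("require c_end >= c_start >= 1")
    removed = c_end - c_start + 1
    return SpliceConsequence(removed, frameshift(removed))


class SpliceEventKind(str, enum.Enum):
    ACCEPTOR_GAIN_NEAR_EXON = "acceptor_gain_near_exon"
    PSEUDOEXON = "pseudoexon"
    EXON_SKIP = "exon_skip"


@dataclass(frozen=True)
class SpliceEvent:
    kind: SpliceEventKind
    # ACCEPTOR_GAIN_NEAR_EXON: offset (negative, <= -3)
    offset: Optional[int] = None
    # PSEUDOEXON: genomic first/last included positions; EXON_SKIP: cDNA span
    start: Optional[int] = None
    end: Optional[int] = None

    def consequence(self) -> SpliceConsequence:
        if self.kind is SpliceEventKind.ACCEPTOR_GAIN_NEAR_EXON:
            n = acceptor_gain_retention(self.offset)
            return SpliceConsequence(n, frameshift(n))
        if self.kind is SpliceEventKind.PSEUDOEXON:
            n = pseudoexon_length(self.start, self.end)
            return SpliceConsequence(n, frameshift(n))
        return exon_skip_consequence(self.start, self.end)


# Deliberately narrow HGVS c.-coordinate parsing: exactly the patterns this
# package consumes.  Anything else is rejected with a clear error.
_RE_INTRONIC_SUB = re.compile(r"^c\.(\d+)([+-])(\d+)([ACGT])>([ACGT])$")
_RE_EXONIC_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_RE_DEL_RANGE = re.compile(r"^c\.(\d+)_(\d+)del$")
_RE_INS_N = re.compile(r"^c\.(\d+)_(\d+)ins(\d+)$")


@dataclass(frozen=True)
class HgvsC:
    """Parsed cDNA-coordinate variant (restricted grammar)."""

    kind: str  # intronic_sub | exonic_sub | del_range | ins_n
    position: int
    offset: int = 0  # signed intronic offset; 0 for exonic
    end: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    ins_length: Optional[int] = None


def parse_hgvs_c(text: str) -> HgvsC:
    """Parse a cDNA HGVS string of one of the supported shapes.

    Supported: ``c.POS[+-]OFFSETREF>ALT``, ``c.POSREF>ALT``,
    ``c.START_ENDdel`` and ``c.START_ENDinsN``.  HGVS in the wild often uses
    a Unicode minus; both '-' and '−'/'–' are accepted.
    """
    s = text.strip().replace("−", "-").replace("–", "-")
    m = _RE_INTRONIC_SUB.match(s)
    if m:
        pos, sign, off, ref, alt = m.groups()
        offset = int(off) if sign == "+" else -int(off)
        return HgvsC("intronic_sub", int(pos), offset=offset, ref=ref, alt=alt)
    m = _RE_EXONIC_SUB.match(s)
    if m:
        pos, ref, alt = m.groups()
        return HgvsC("exonic_sub", int(pos), ref=ref, alt=alt)
    m = _RE_DEL_RANGE.match(s)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        return HgvsC("del_range", start, end=end)
    m = _RE_INS_N.match(s)
    if m:
        start, end, n = int(m.group(1)), int(m.group(2)), int(m.group(3))
        return HgvsC("ins_n", start, end=end, ins_length=n)
    raise ValueError(f"unsupported HGVS cDNA expression: {text!r}")
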