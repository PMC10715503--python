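"""Cross-sample, cross-caller SV aggregation and cohort-frequency rarity.

Two callers reporting the same physical SV disagree slightly on breakpoints,
so equivalence is defined by reciprocal overlap: overlap length divided by
the length of the *longer* interval.  Calls are clustered by single-linkage
transitive closure of the pairwise match relation, carriers are the distinct
samples contributing member calls, and a cluster is rare when its carrier
fraction over all cohort participants is strictly below a threshold
(default 1%).

Insertions are point-like, so reciprocal overlap is undefined for them;
they are matched instead by breakpoint proximity and inserted-length
similarity.  That rule is a package convention, configurable via
:class:`ClusterParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .intervals import GenomicInterval
from .variants import SvCall


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length over the longer of the two lengths; 0 across chromosomes."""
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return ov / max(a.length(), b.length())


@dataclass(frozen=True)
class ClusterParams:
    ro_threshold: float = 0.8
    ins_tol_bp: int = 50
    ins_len_tol: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.ro_threshold <= 1.0):
            raise ValueError("ro_threshold must lie in (0,1]")
        if self.ins_tol_bp < 0 or not (0.0 <= self.ins_len_tol < 1.0):
            raise ValueError("invalid insertion tolerances")


def calls_match(a: SvCall, b: SvCall, params: ClusterParams = ClusterParams()) -> bool:
    """Pairwise equivalence of two SV calls.

    Non-insertions: same type and reciprocal overlap >= threshold.
    Insertions: same type, breakpoints within ``ins_tol_bp`` and length
    ratio >= ``1 - ins_len_tol``.  Mixed INS/non-INS never match.
    """
    if a.svtype != b.svtype:
        return False
    if a.svtype == "INS":
        if a.locus.chrom != b.locus.chrom:
            return False
        if abs(a.locus.start - b.locus.start) > params.ins_tol_bp:
            return False
        lo, hi = sorted((a.ins_length, b.ins_length))
        return lo / hi >= 1.0 - params.ins_len_tol
    return reciprocal_overlap(a.locus, b.locus) >= params.ro_threshold


@dataclass
class SvCluster:
    """An equivalence class of SV calls across samples and callers."""

    cluster_id: str
    svtype: str
    representative: GenomicInterval
    members: List[SvCall] = field(default_factory=list)
    carriers: Set[str] = field(default_factory=set)
    cohort_frequency: Optional[float] = None
    ins_length: Optional[int] = None  # median member length, INS clusters only

    def __post_init__(self) -> None:
        if any(m.svtype != self.svtype for m in self.members):
            raise ValueError("all cluster members must share svtype")


def _lower_median(values: Sequence[int]) -> int:
    """Median with ties resolved toward the smaller value (lower median)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_sv_calls(
    calls: Sequence[SvCall], params: ClusterParams = ClusterParams()
) -> List[SvCluster]:
    """Partition calls into single-linkage connected components under
    :func:`calls_match`.

    Output order is deterministic: by chromosome, representative start,
    then svtype.  Single-linkage means chains of pairwise matches can
    connect calls whose direct reciprocal overlap is below threshold.
    """
    calls = list(calls)
    uf = _UnionFind(len(calls))
    # group indices by (chrom, svtype): matches cannot cross either
    groups: Dict[tuple, List[int]] = {}
    for i, c in enumerate(calls):
        groups.setdefault((c.locus.chrom, c.svtype), []).append(i)
    for (_, svtype), idxs in groups.items():
        idxs.sort(key=lambda i: (calls[i].locus.start, calls[i].locus.end))
        # sweep: only calls whose spans (or breakpoint windows) overlap can match
        reach = params.ins_tol_bp if svtype == "INS" else 0
        active: List[int] = []
        for i in idxs:
            ci = calls[i]
            active = [
                j
                for j in active
                if calls[j].locus.end + reach >= ci.locus.start
            ]
            for j in active:
                if calls_match(calls[j], ci, params):
                    uf.union(j, i)
            active.append(i)
    components: Dict[int, List[int]] = {}
    for i in range(len(calls)):
        components.setdefault(uf.find(i), []).append(i)
    clusters: List[SvCluster] = []
    for idxs in components.values():
        members = [calls[i] for i in idxs]
        rep_start = _lower_median([m.locus.start for m in members])
        rep_end = _lower_median([m.locus.end for m in members])
        rep = GenomicInterval(members[0].locus.chrom, rep_start, max(rep_start, rep_end))
        ins_len = None
        if members[0].svtype == "INS":
            ins_len = _lower_median([m.ins_length for m in members])
        clusters.append(
            SvCluster(
                cluster_id="",
                svtype=members[0].svtype,
                representative=rep,
                members=sorted(
                    members,
                    key=lambda m: (m.sample_id, m.caller, m.locus.start, m.locus.end),
                ),
                carriers={m.sample_id for m in members},
                ins_length=ins_len,
            )
        )
    clusters.sort(key=lambda c: (c.representative.chrom, c.representative.start, c.svtype))
    for k, c in enumerate(clusters):
        c.cluster_id = f"SVC{k + 1:05d}"
    return clusters


def cohort_frequency(cluster: SvCluster, n_participants: int) -> float:
    """Carrier fraction of a cluster over all cohort participants.

    The denominator is participants, not alleles: het and hom carriers each
    count once.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    n_carriers = len(cluster.carriers)
    if n_carriers == 0:
        raise ValueError("cluster has no carriers")
    if n_carriers > n_participants:
        raise ValueError("more carriers than participants")
    return n_carriers / n_participants


def annotate_frequencies(clusters: Iterable[SvCluster], n_participants: int) -> None:
    for c in clusters:
        c.cohort_frequency = cohort_frequency(c, n_participants)


def rare_clusters(
    clusters: Sequence[SvCluster], max_freq: float = 0.01
) -> List[SvCluster]:
    """Clusters with cohort frequency strictly below *max_freq*, order kept.

    The inequality is strict: a cluster at exactly the threshold is common.
    """
    out = []
    for c in clusters:
        if c.cohort_frequency is None:
            raise ValueError(f"cluster {c.cluster_id} has no cohort_frequency")
        if c.cohort_frequency < max_freq:
            out.append(c)
    return out


CLUSTER_COLUMNS = [
    "cluster_id",
    "chrom",
    "start",
    "end",
    "svtype",
    "ins_length",
    "n_carriers",
    "frequency",
    "carriers",
]


def clusters_to_frame(clusters: Sequence[SvCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.representative.chrom,
                "start": c.representative.start,
                "end": c.representative.end,
                "svtype": c.svtype,
                "ins_length": "" if c.ins_length is None else c.ins_length,
                "n_carriers": len(c.carriers),
                "frequency": "" if c.cohort_frequency is None else c.cohort_frequency,
                "carriers": ",".join(sorted(c.carriers)),
            }
        )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def write_cluster_tsv(clusters: Sequence[SvCluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def read_cluster_tsv(path) -> List[SvCluster]:
    """Read a cluster TSV back into summary clusters (members not restored)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).fillna("")
    clusters = []
    for row in df.itertuples(index=False):
        carriers = set(str(row.carriers).split(",")) if row.carriers else set()
        clusters.append(
            SvCluster(
                cluster_id=row.cluster_id,
                svtype=row.svtype,
                representative=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                members=[],
                carriers=carriers,
                cohort_frequency=float(row.frequency) if row.frequency != "" else None,
                ins_length=int(row.ins_length) if row.ins_length != "" else None,
            )
        )
    return clusters
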