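"""Pedigree (PED) records and trio lookup."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

PED_COLUMNS = ["family_id", "sample_id", "father_id", "mother_id", "sex", "affected"]


@dataclass(frozen=True)
class PedRecord:
    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "0"  # 1=male, 2=female, 0=unknown
    affected: bool = False


class Pedigree:
    """A set of PED records with parent references resolved at construction."""

    def __init__(self, records: List[PedRecord]):
        self._by_sample: Dict[str, PedRecord] = {}
        for rec in records:
            if rec.sample_id in self._by_sample:
                raise ValueError(f"duplicate sample {rec.sample_id} in pedigree")
            self._by_sample[rec.sample_id] = rec
        for rec in records:
            for parent in (rec.father_id, rec.mother_id):
                if parent is not None and parent not in self._by_sample:
                    raise ValueError(
                        f"parent {parent} of {rec.sample_id} not in pedigree"
                    )

    @property
    def samples(self) -> List[str]:
        return list(self._by_sample)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_sample

    def __len__(self) -> int:
        return len(self._by_sample)

    def record(self, sample_id: str) -> PedRecord:
        return self._by_sample[sample_id]

    def parents_of(self, sample_id: str) -> Tuple[Optional[str], Optional[str]]:
        """(father_id, mother_id); either may be None."""
        rec = self._by_sample.get(sample_id)
        if rec is None:
            return (None, None)
        return (rec.father_id, rec.mother_id)

    def has_trio(self, sample_id: str) -> bool:
        father, mother = self.parents_of(sample_id)
        return father is not None and mother is not None


def read_ped(path) -> Pedigree:
    """Read a 6-column tab-separated PED file."""
    df = pd.read_csv(path, sep="\t", header=None, names=PED_COLUMNS, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PedRecord(
                sample_id=row.sample_id,
                family_id=row.family_id,
                father_id=None if row.father_id in ("0", None) else row.father_id,
                mother_id=None if row.mother_id in ("0", None) else row.mother_id,
                sex=row.sex,
                affected=row.affected == "2",
            )
        )
    return Pedigree(records)


def write_ped(pedigree: Pedigree, path) -> None:
    rows = []
    for sid in pedigree.samples:
        rec = pedigree.record(sid)
        rows.append(
            [
                rec.family_id,
                rec.sample_id,
                rec.father_id or "0",
                rec.mother_id or "0",
                rec.sex,
                "2" if rec.affected else "1",
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
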