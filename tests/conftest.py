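import pytest

from secondhit.cases import (
    CaseRecord,
    FirstHit,
    FirstHitKind,
    RecruitmentStatus,
    SolvedStatus,
)
from secondhit.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but screen-valid cohort: enough samples that a planted
    variant carried by a trio stays under the 1% carrier-fraction rarity
    threshold (3 carriers / 360 samples)."""
    cfg = SimConfig(
        n_families=120,
        n_background_sv_clusters=12,
        n_planted_cases=6,
        n_genes=12,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A cohort small enough to round-trip through files quickly."""
    cfg = SimConfig(
        n_families=8,
        n_background_sv_clusters=4,
        n_planted_cases=3,
        planted_kinds=["second_hit_SV", "second_hit_intronic_SNV", "homozygous_in_ROH"],
        n_genes=4,
        roh_length_mb=6.0,
        chrom_lengths={"chr1": 30_000_000, "chr2": 30_000_000},
        seed=7,
    )
    return simulate_cohort(cfg)


def _case(i, status, solved, condition="", gene="GENE"):
    has_info = status is not RecruitmentStatus.NO_FIRST_HIT_INFO
    return CaseRecord(
        case_id=f"C{i:02d}",
        proband_id=f"S{i:02d}",
        referral_condition=condition,
        recruitment_status=status,
        first_hit=FirstHit(gene_symbol=gene, kind=FirstHitKind.NONE) if has_info else None,
        solved=solved,
    )


@pytest.fixture(scope="session")
def study_cohort_cases():
    """Case records reproducing the published cohort structure: 56 recruited,
    7 excluded, 8 without first-hit information, 10 previously solved and 8
    newly solved (4 of them cystic fibrosis) among 41 correctly recruited."""
    newly_solved_conditions = [
        "cystic fibrosis",
        "Warburg Micro syndrome",
        "pseudoxanthoma elasticum",
        "generalised arterial calcification of infancy",
        "cystic fibrosis",
        "cystic fibrosis",
        "cystic fibrosis",
        "Jeune syndrome",
    ]
    cases = []
    i = 0
    for cond in newly_solved_conditions:
        cases.append(_case(i, RecruitmentStatus.CORRECTLY_RECRUITED,
                           SolvedStatus.NEWLY_SOLVED, cond))
        i += 1
    for _ in range(10):
        cases.append(_case(i, RecruitmentStatus.CORRECTLY_RECRUITED,
                           SolvedStatus.PREVIOUSLY_SOLVED))
        i += 1
    for _ in range(23):
        cases.append(_case(i, RecruitmentStatus.CORRECTLY_RECRUITED,
                           SolvedStatus.UNSOLVED))
        i += 1
    for _ in range(7):
        cases.append(_case(i, RecruitmentStatus.EXCLUDED_MISRECRUITED,
                           SolvedStatus.UNSOLVED))
        i += 1
    for _ in range(8):
        cases.append(_case(i, RecruitmentStatus.NO_FIRST_HIT_INFO,
                           SolvedStatus.UNSOLVED))
        i += 1
    assert len(cases) == 56
    return cases
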