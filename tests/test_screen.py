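import pytest

from secondhit.cases import CaseRecord, FirstHit, FirstHitKind
from secondhit.intervals import Gene, GenomicInterval
from secondhit.pedigree import PedRecord, Pedigree
from secondhit.phasing import Phase
from secondhit.roh import detect_roh_chrom
from secondhit.screen import (
    ScreenParams,
    candidates_to_frame,
    carrier_enrichment,
    cohort_summary,
    diagnostic_yield,
    screen_case,
    sv_window_overlap,
)
from secondhit.simulate import HOMOZYGOUS_IN_ROH, MOSAIC_PARENT_SV
from secondhit.smallvar import VariantIndex, apply_annotations
from secondhit.svcluster import annotate_frequencies, cluster_sv_calls
from secondhit.variants import SmallVariant


def _gene(start=100_000, end=200_000, chrom="chr1", symbol="GENE1"):
    exons = tuple(
        GenomicInterval(chrom, s, s + 199) for s in range(start, end, 20_000)
    )
    return Gene(symbol, symbol, GenomicInterval(chrom, start, end), "+", exons)


class TestSvWindowOverlap:
    def _cluster_at(self, start, end):
        from secondhit.svcluster import SvCluster

        return SvCluster("c1", "DEL", GenomicInterval("chr1", start, end))

    def test_internal_overlap(self):
        assert sv_window_overlap(self._cluster_at(150_000, 160_000), _gene())

    def test_exact_1kb_boundary_inclusive(self):
        gene = _gene()
        assert sv_window_overlap(self._cluster_at(95_000, 99_000), gene)  # ends 1000 bp upstream
        assert not sv_window_overlap(self._cluster_at(95_000, 98_999), gene)  # 1001 bp

    def test_deletion_running_into_neighbouring_gene_still_hits(self):
        # a deletion of the last exons plus the neighbour overlaps our window
        assert sv_window_overlap(self._cluster_at(190_000, 600_000), _gene())


class _ScreenFixture:
    """Hand-built two-variant trio for targeted screen behaviour tests."""

    def __init__(self):
        self.gene = _gene()
        self.genes = {"GENE1": self.gene}
        self.pedigree = Pedigree(
            [
                PedRecord("dad", "f1", sex="1"),
                PedRecord("mum", "f1", sex="2"),
                PedRecord("kid", "f1", father_id="dad", mother_id="mum", affected=True),
            ]
        )
        self.first_hit = SmallVariant(
            "chr1", 120_050, "A", "G",
            {"kid": "0/1", "mum": "0/1"}, af_cohort=0.001,
        )
        self.case = CaseRecord(
            "c1", "kid",
            first_hit=FirstHit("GENE1", FirstHitKind.SMALL_VARIANT,
                               self.first_hit.key),
        )

    def screen(self, variants, clusters=(), roh=None, params=ScreenParams()):
        idx = VariantIndex([self.first_hit] + list(variants))
        return screen_case(
            self.case, list(clusters), idx, self.pedigree, None,
            roh or {}, self.genes, params,
        )


class TestScreenCase:
    def test_first_hit_self_excluded(self):
        fx = _ScreenFixture()
        assert fx.screen([]) == []

    def test_missing_gene_is_hard_error_naming_gene(self):
        fx = _ScreenFixture()
        fx.genes = {}
        with pytest.raises(KeyError, match="GENE1"):
            fx.screen([])

    def test_trans_candidate_ranks_above_cis(self):
        fx = _ScreenFixture()
        trans = SmallVariant("chr1", 150_000, "C", "T",
                             {"kid": "0/1", "dad": "0/1"}, af_cohort=0.001)
        cis = SmallVariant("chr1", 160_000, "G", "A",
                           {"kid": "0/1", "mum": "0/1"}, af_cohort=0.001)
        out = fx.screen([cis, trans])
        assert [c.candidate.pos for c in out] == [150_000, 160_000]
        assert out[0].phase is Phase.TRANS
        assert out[1].phase is Phase.CIS
        assert any("cis" in n for n in out[1].evidence_notes)

    def test_common_variant_not_a_candidate(self):
        fx = _ScreenFixture()
        common = SmallVariant("chr1", 150_000, "C", "T",
                              {"kid": "0/1", "dad": "0/1"}, af_gnomad=0.2)
        assert fx.screen([common]) == []

    def test_acceptor_gain_near_exon_gets_consequence(self):
        fx = _ScreenFixture()
        # 26 bp upstream of the exon starting at 140,000 on the + strand
        v = SmallVariant("chr1", 140_000 - 26, "A", "G",
                         {"kid": "0/1", "dad": "0/1"}, af_cohort=0.001,
                         splice_deltas={"AG": 0.99})
        (cand,) = fx.screen([v])
        assert cand.consequence is not None
        assert cand.consequence.inserted_or_removed_nt == 25
        assert cand.consequence.frameshift


def _roh_regions(cohort, sample):
    regions = []
    for chrom in cohort.backbone.positions:
        regions.extend(detect_roh_chrom(chrom, cohort.backbone.series(sample, chrom)))
    return regions


@pytest.fixture(scope="module")
def screened_cohort(small_cohort):
    clusters = cluster_sv_calls(small_cohort.all_calls())
    annotate_frequencies(clusters, small_cohort.n_participants)
    apply_annotations(small_cohort.rare_variants, small_cohort.annotations)
    idx = VariantIndex(small_cohort.rare_variants)
    genes = {g.symbol: g for g in small_cohort.genes}
    results = {}
    for case in small_cohort.cases[: small_cohort.config.n_planted_cases]:
        roh = {case.proband_id: _roh_regions(small_cohort, case.proband_id)}
        results[case.case_id] = screen_case(
            case, clusters, idx, small_cohort.pedigree, small_cohort.depth,
            roh, genes,
        )
    return small_cohort, results


class TestScreenOnPlantedCohort:
    def test_planted_sv_cases_top_ranked_in_trans(self, screened_cohort):
        cohort, results = screened_cohort
        for t in cohort.truth:
            if t.second_hit_kind != "sv":
                continue
            top = results[t.case_id][0]
            assert top.is_sv
            assert top.phase is Phase.TRANS
            if t.sv_svtype == "INS":
                assert abs(top.candidate.representative.start - t.sv_interval.start) <= 100
            else:
                assert top.candidate.representative.intersects(t.sv_interval)

    def test_planted_intronic_snv_cases_top_ranked_in_trans(self, screened_cohort):
        cohort, results = screened_cohort
        for t in cohort.truth:
            if t.kind != "second_hit_intronic_SNV":
                continue
            top = results[t.case_id][0]
            assert not top.is_sv
            assert top.candidate.key == t.snv_key
            assert top.phase is Phase.TRANS

    def test_homozygous_candidate_promoted_via_roh(self, screened_cohort):
        cohort, results = screened_cohort
        for t in cohort.truth:
            if t.kind != HOMOZYGOUS_IN_ROH:
                continue
            top = results[t.case_id][0]
            assert top.zygosity_path == "HOMOZYGOUS_IN_ROH"
            assert top.phase is Phase.NOT_APPLICABLE
            assert top.roh is not None
            assert top.roh.interval.contains(top.locus)
            assert top.candidate.key == t.snv_key

    def test_mosaic_parent_flagged_in_evidence(self, screened_cohort):
        cohort, results = screened_cohort
        t = next(t for t in cohort.truth if t.kind == MOSAIC_PARENT_SV)
        top = results[t.case_id][0]
        notes = " ".join(top.evidence_notes)
        assert t.mosaic_sample in notes
        import re

        m = re.search(rf"{t.mosaic_sample}: deletion in (\d+)% of cells", notes)
        assert m is not None
        assert abs(int(m.group(1)) - 44) <= 5

    def test_report_is_deterministic(self, screened_cohort):
        cohort, results = screened_cohort
        frames = [candidates_to_frame(v).to_csv() for v in results.values()]
        clusters = cluster_sv_calls(cohort.all_calls())
        annotate_frequencies(clusters, cohort.n_participants)
        idx = VariantIndex(cohort.rare_variants)
        genes = {g.symbol: g for g in cohort.genes}
        again = []
        for case in cohort.cases[: cohort.config.n_planted_cases]:
            roh = {case.proband_id: _roh_regions(cohort, case.proband_id)}
            cands = screen_case(case, clusters, idx, cohort.pedigree,
                                cohort.depth, roh, genes)
            again.append(candidates_to_frame(cands).to_csv())
        assert frames == again


class TestDiagnosticYield:
    @pytest.mark.parametrize("solved,total,expected",
                             [(10, 41, 24.4), (18, 41, 43.9), (0, 41, 0.0)])
    def test_examples(self, solved, total, expected):
        assert diagnostic_yield(solved, total) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            diagnostic_yield(1, 0)
        with pytest.raises(ValueError):
            diagnostic_yield(5, 4)


class TestCarrierEnrichment:
    def test_cohort_versus_disease_subcohort(self):
        e = carrier_enrichment(15, 75_000, 3, 11)
        assert e.pct_cohort == 0.02
        assert e.pct_sub == 27.3
        assert e.ratio == pytest.approx(1365.0)

    def test_recruited_fraction_of_carriers(self):
        assert carrier_enrichment(15, 75_000, 3, 15).pct_sub == 20.0

    def test_zero_carriers_ratio_absent(self):
        e = carrier_enrichment(0, 100, 0, 10)
        assert (e.pct_cohort, e.pct_sub, e.ratio) == (0.0, 0.0, None)

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            carrier_enrichment(2, 100, 3, 10)
        with pytest.raises(ValueError):
            carrier_enrichment(5, 10, 1, 20)
        with pytest.raises(ValueError):
            carrier_enrichment(1, 0, 1, 1)


class TestCohortSummary:
    def test_study_cohort_fixture(self, study_cohort_cases):
        s = cohort_summary(study_cohort_cases)
        assert s.n_recruited == 56
        assert s.n_excluded == 7
        assert s.n_no_first_hit_info == 8
        assert s.n_correctly_recruited == 41
        assert s.n_previously_solved == 10
        assert s.n_newly_solved == 8
        assert s.yield_before == 24.4
        assert s.yield_after == 43.9

    def test_newly_solved_breakdown(self, study_cohort_cases):
        from secondhit.cases import SolvedStatus

        newly = [c for c in study_cohort_cases if c.solved is SolvedStatus.NEWLY_SOLVED]
        assert len(newly) == 8
        cf = [c for c in newly if c.referral_condition == "cystic fibrosis"]
        assert len(cf) == 4

    def test_empty_case_list_is_hard_error(self):
        with pytest.raises(ValueError):
            cohort_summary([])
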