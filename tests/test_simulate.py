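import hashlib
from pathlib import Path

import numpy as np
import pytest

from secondhit.intervals import GenomicInterval
from secondhit.simulate import (
    HOMOZYGOUS_IN_ROH,
    SimConfig,
    default_planted_kinds,
    jitter_call,
    simulate_cohort,
    write_cohort,
)
from secondhit.svcluster import annotate_frequencies, cluster_sv_calls, reciprocal_overlap
from secondhit.variants import SvCall


class TestSimConfig:
    def test_over_planting_is_hard_error(self):
        with pytest.raises(ValueError):
            SimConfig(n_families=3, n_planted_cases=4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(planted_kinds=["not_a_kind"] * 10)

    def test_default_kinds_cover_all(self):
        kinds = default_planted_kinds(10)
        assert len(kinds) == 10
        assert set(kinds) == {
            "second_hit_SV", "second_hit_intronic_SNV",
            "homozygous_in_ROH", "mosaic_parent_SV",
        }

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_families=5, n_planted_cases=2,
                        planted_kinds=["second_hit_SV", "second_hit_intronic_SNV"],
                        seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg


class TestJitterCall:
    def _del(self, start=100_000, end=110_000):
        return SvCall("s", "A", "DEL", GenomicInterval("chr1", start, end))

    def test_zero_sd_is_identity(self):
        rng = np.random.default_rng(0)
        assert jitter_call(self._del(), 0.0, rng) == self._del()

    def test_small_interval_repair(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            out = jitter_call(SvCall("s", "A", "DEL", GenomicInterval("chr1", 5, 6)),
                              50.0, rng)
            assert 1 <= out.locus.start <= out.locus.end

    def test_insertion_stays_point_like(self):
        rng = np.random.default_rng(2)
        ins = SvCall("s", "A", "INS", GenomicInterval("chr1", 5000, 5000), ins_length=1591)
        out = jitter_call(ins, 20.0, rng)
        assert out.locus.length() == 1 and out.ins_length == 1591

    def test_jittered_10kb_deletion_keeps_high_reciprocal_overlap(self):
        # Monte-Carlo oracle: with sd=20 on a 10 kb deletion, RO against the
        # truth stays >= 0.98 essentially always
        rng = np.random.default_rng(3)
        truth = self._del()
        n, hits = 10_000, 0
        for _ in range(n):
            out = jitter_call(truth, 20.0, rng)
            if reciprocal_overlap(out.locus, truth.locus) >= 0.98:
                hits += 1
        assert hits / n > 0.99


def _mendelian_violations(cohort):
    """Count Mendelian violations over backbone sites of non-planted trios."""
    planted = {t.family_id for t in cohort.truth}
    bad = 0
    for chrom, codes in cohort.backbone.codes.items():
        for fam_i in range(cohort.config.n_families):
            fid = f"FAM{fam_i:04d}"
            if fid in planted:
                continue
            c = codes[:, 3 * fam_i].astype(int)
            f = codes[:, 3 * fam_i + 1].astype(int)
            m = codes[:, 3 * fam_i + 2].astype(int)
            viol = (
                ((f == 0) & (m == 0) & (c > 0))
                | ((f == 2) & (m == 2) & (c < 2))
                | ((f == 0) & (c == 2)) | ((m == 0) & (c == 2))
                | ((f == 2) & (c == 0)) | ((m == 2) & (c == 0))
            )
            bad += int(viol.sum())
    return bad


class TestSimulateCohort:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = dict(n_families=6, n_background_sv_clusters=3, n_planted_cases=2,
                   planted_kinds=["second_hit_SV", "homozygous_in_ROH"], n_genes=3,
                   roh_length_mb=5.0,
                   chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000}, seed=42)
        digests = []
        for run in ("a", "b"):
            cohort = simulate_cohort(SimConfig(**cfg))
            outdir = tmp_path / run
            write_cohort(cohort, outdir)
            h = hashlib.sha256()
            for p in sorted(Path(outdir).iterdir()):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_trio_genotypes_are_mendelian(self, small_cohort):
        assert _mendelian_violations(small_cohort) == 0

    def test_background_carrier_fractions_match_spectrum(self):
        # averaged over seeds, each background cluster's realized carrier
        # fraction stays within 3 binomial sd (of the mean) of its
        # configured fraction
        n_seeds = 20
        realized = None
        for seed in range(n_seeds):
            cfg = SimConfig(n_families=200, n_planted_cases=0, planted_kinds=[],
                            n_background_sv_clusters=8, seed=100 + seed)
            cohort = simulate_cohort(cfg)
            background = [sv for sv in cohort.true_svs if not sv.planted]
            assert len(background) == 8
            n = 3 * cfg.n_families
            if realized is None:
                realized = np.zeros(len(background))
                configured = np.array([sv.config_fraction for sv in background])
            realized += [len({s for s, _ in sv.carriers}) / n for sv in background]
        realized /= n_seeds
        sd_mean = np.sqrt(configured * (1 - configured) / (n * n_seeds))
        assert (np.abs(realized - configured) <= 3 * sd_mean + 1e-9).all()

    def test_common_background_cluster_not_rare_downstream(self):
        cfg = SimConfig(n_families=200, n_planted_cases=0, planted_kinds=[],
                        n_background_sv_clusters=4,
                        background_freq_spectrum=[0.05, 0.002, 0.12, 0.003],
                        caller_dropout_prob=0.0, seed=9)
        cohort = simulate_cohort(cfg)
        clusters = cluster_sv_calls(cohort.all_calls())
        annotate_frequencies(clusters, cohort.n_participants)
        by_carrier_count = sorted(clusters, key=lambda c: -len(c.carriers))
        assert by_carrier_count[0].cohort_frequency >= 0.01
        assert by_carrier_count[1].cohort_frequency >= 0.01

    def test_planted_pairs_are_genuinely_in_trans(self, small_cohort):
        ped = small_cohort.pedigree
        for t in small_cohort.truth:
            if t.phase != "trans":
                continue
            proband = f"{t.family_id}_P"
            father, mother = ped.parents_of(proband)
            fh_chrom, fh_pos, fh_ref, fh_alt = t.first_hit_desc.split(":")
            fh = next(v for v in small_cohort.rare_variants
                      if v.key == (fh_chrom, int(fh_pos), fh_ref, fh_alt))
            fh_parent = "father" if fh.is_carrier(father) else "mother"
            if t.second_hit_kind == "snv":
                sh = next(v for v in small_cohort.rare_variants if v.key == t.snv_key)
                sh_parent = "father" if sh.is_carrier(father) else "mother"
            else:
                sv = next(s for s in small_cohort.true_svs if s.planted
                          and s.interval == t.sv_interval)
                carrier_ids = {s for s, _ in sv.carriers}
                sh_parent = "father" if father in carrier_ids else "mother"
            assert fh_parent != sh_parent

    def test_mosaic_parent_depth_reduced_but_genotyped_het(self, small_cohort):
        t = next(t for t in small_cohort.truth if t.mosaic_fraction)
        sv = next(s for s in small_cohort.true_svs if s.planted and s.mosaic)
        parent = t.mosaic_sample
        assert dict(sv.carriers)[parent] == "het"
        depth = small_cohort.depth
        iv = t.sv_interval
        rows = depth[(depth.sample_id == parent) & (depth.chrom == iv.chrom)]
        mid = (rows.start + rows.end) / 2
        inside = rows[(mid >= iv.start) & (mid <= iv.end)]
        outside = rows[(rows.end < iv.start) | (rows.start > iv.end)]
        ratio = inside.mean_depth.mean() / outside.mean_depth.mean()
        expected = 1 - t.mosaic_fraction / 2  # 0.78 for a 44% mosaic
        assert ratio == pytest.approx(expected, abs=0.03)

    def test_roh_block_mostly_homozygous_with_contamination(self, small_cohort):
        t = next(t for t in small_cohort.truth if t.kind == HOMOZYGOUS_IN_ROH)
        proband = f"{t.family_id}_P"
        series = small_cohort.backbone.series(proband, t.roh_interval.chrom)
        inside = [s for p, s in series
                  if t.roh_interval.start <= p <= t.roh_interval.end]
        het_frac = sum(1 for s in inside if s == "het") / len(inside)
        assert het_frac < 0.03
        outside = [s for p, s in series
                   if not (t.roh_interval.start <= p <= t.roh_interval.end)]
        het_out = sum(1 for s in outside if s == "het") / len(outside)
        assert het_out > 0.3

    def test_planted_sv_emitted_by_both_callers_with_independent_jitter(self):
        cfg = SimConfig(n_families=40, n_planted_cases=4,
                        planted_kinds=["second_hit_SV"] * 4,
                        n_background_sv_clusters=0, caller_dropout_prob=0.0,
                        n_genes=6, seed=13)
        cohort = simulate_cohort(cfg)
        for sv in cohort.true_svs:
            for sample, _ in sv.carriers:
                mine = [c for caller in ("A", "B") for c in cohort.sv_calls[caller]
                        if c.sample_id == sample and c.svtype == sv.svtype]
                assert {c.caller for c in mine} == {"A", "B"}
        # the two callers' breakpoints disagree for at least one event
        diffs = []
        for sv in cohort.true_svs:
            sample = sv.carriers[0][0]
            a = next(c for c in cohort.sv_calls["A"] if c.sample_id == sample)
            b = next(c for c in cohort.sv_calls["B"] if c.sample_id == sample)
            diffs.append(a.locus.start - b.locus.start)
        assert any(d != 0 for d in diffs)
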