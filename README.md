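# secondhit

Hunting cryptic "second-hit" variants in autosomal-recessive rare disease.

## The problem

In many rare-disease families, standard-of-care testing finds exactly one
pathogenic variant in a gene for a suspected recessive disorder — the
*first hit* — and then stalls: the disease requires both alleles to be
damaged, but the second pathogenic variant is cryptic.  The missing allele
is often a structural variant (SV) that targeted assays straddle, or a
deep-intronic variant that creates a pseudoexon or a new splice acceptor,
classes that exon-focused pipelines systematically under-call.  Whole-genome
sequencing sees these variants; finding them requires a systematic,
gene-anchored screen.

`secondhit` implements that screen as a tested, reusable library for
analysts working with multi-sample cohort VCFs, per-caller SV call sets and
trio pedigrees:

* **SV aggregation** — calls from multiple callers and samples are merged
  into clusters by reciprocal overlap
  `RO(a,b) = |a ∩ b| / max(|a|, |b|) ≥ 0.8` (single-linkage closure), and a
  cluster is *rare* when its carrier fraction over all cohort participants
  is `< 1%` (strict).  Point-like insertions are matched by breakpoint
  proximity and inserted-length similarity instead.
* **Gene-anchored screening** — rare SV clusters and rare small variants
  carried by the proband within the first-hit gene ± 1 kb are ranked as
  candidate second hits.  Population allele frequencies are the only hard
  filter; CADD and splice delta scores (consumed from precomputed
  annotation, never recomputed) are ranking evidence only.
* **Trio phasing** — parental origin by inheritance; two variants on
  different parental alleles are *in trans* (a compound heterozygote),
  and in-trans candidates outrank unknown-phase and cis candidates.
* **Mosaic fraction** — for a heterozygous deletion present in a fraction
  *f* of a parent's cells, expected depth over the deletion is
  `flank × (1 − f/2)`, so `f = 2(1 − depth_in/depth_flank)`, clamped to
  [0, 1] and reported as a percentage.
* **Runs of homozygosity (ROH)** — sliding site-count windows (50 sites,
  ≤ 2 heterozygotes) merged into regions ≥ 2 Mb / ≥ 100 sites; a rare
  homozygous variant inside an ROH is promoted as a
  `HOMOZYGOUS_IN_ROH` candidate.
* **Splice-consequence arithmetic** — a new acceptor at intronic offset
  `c.X−k` retains `k − 1` intronic bases; pseudoexon and exon-skip lengths
  are inclusive spans; anything whose length is not divisible by 3 is a
  frameshift.
* **Synthetic cohorts** — `secondhit.simulate` generates trio cohorts
  (VCF/PED/BED/TSV) with two jittery SV callers, a background SV frequency
  spectrum, and planted compound-het, mosaic and ROH second hits with a
  truth table, so the whole pipeline is testable end to end without
  access-controlled data.

## Worked example

```python
>>> from secondhit import (GenomicInterval, span_kb, mosaic_fraction,
...                        diagnostic_yield, carrier_enrichment,
...                        acceptor_gain_retention, frameshift)
>>> span_kb(GenomicInterval("chr2", 135_165_337, 135_511_837))
346.5
>>> mosaic_fraction(39.0, 50.0)   # depth 39x in the deletion, 50x in flanks
44.0
>>> acceptor_gain_retention(-26), frameshift(25)
(25, True)
>>> diagnostic_yield(10, 41), diagnostic_yield(18, 41)
(24.4, 43.9)
>>> e = carrier_enrichment(15, 75_000, 3, 11)
>>> (e.pct_cohort, e.pct_sub)
(0.02, 27.3)
```

Reading: a 346.5 kb deletion; a parent carrying that deletion in 44% of
cells (the proband, fully heterozygous, would show ~100%); a deep intronic
variant at offset −26 retaining 25 frameshifting bases; a screen lifting a
cohort's diagnostic yield from 24.4% to 43.9%; and a variant carried by
0.02% of a large cohort but 27.3% of a disease subcohort.

End to end on synthetic data:

```bash
secondhit simulate --out cohort/ --seed 1
secondhit aggregate --sv-vcfs cohort/ --n-participants 600 --out clusters.tsv
secondhit screen --sv-vcfs cohort/ --vcf cohort/small_variants.vcf \
    --ped cohort/cohort.ped --genes cohort/genes.bed --cases cohort/cases.tsv \
    --annot cohort/annotations.tsv --depth cohort/depth.tsv --out report/
```

`report/candidates.tsv` lists ranked candidates per case (phase, zygosity
path, ROH, splice consequence, evidence notes); `report/summary.json` gives
the cohort accounting.  `cohort/truth.tsv` records what was planted, for
comparison.

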