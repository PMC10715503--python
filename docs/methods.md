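# Methods

## Coordinate conventions

All internal coordinates are 1-based and inclusive at both ends, matching
VCF and HGVS usage; BED I/O converts at the file boundary.  Interval
*spans* quoted in kb use the coordinate difference `(end − start)/1000` to
one decimal place — the convention used when an SV size is quoted from its
breakpoint coordinates — rather than the base count.

## SV aggregation

Callers disagree slightly on the breakpoints of the same physical event,
so call equivalence is defined by **reciprocal overlap**: shared length
divided by the length of the longer interval, with a default threshold of
0.8.  Dividing by the longer interval (rather than one-way overlap) is
deliberate: one-way overlap would merge a small SV nested inside a much
larger one, which is not "the same variant with slightly different
breakpoints".  The threshold is configurable (`ClusterParams.ro_threshold`).

Clusters are **single-linkage connected components** of the pairwise match
relation.  Transitivity is required to aggregate across thousands of
samples, and it has the usual single-linkage caveat, stated here as a
contract: a chain of pairwise matches can connect two calls whose direct
reciprocal overlap is below threshold.

Insertions are point-like, so reciprocal overlap is undefined for them.
They are matched when breakpoints are within 50 bp and inserted lengths
agree within 20% (`ins_tol_bp`, `ins_len_tol`).  This rule is a package
convention chosen to tolerate the same order of breakpoint noise as the
0.8 reciprocal-overlap rule does for a multi-kb deletion; both tolerances
are configurable.

The cluster representative interval is the per-coordinate **lower median**
of member breakpoints (ties resolve toward the smaller coordinate, keeping
the representative deterministic).  **Cohort frequency** is the carrier
fraction over participants — het and hom carriers each count once, and the
denominator is people, not alleles.  Rarity is strict: a cluster at
exactly the threshold (default 1%) is common.

## Small-variant prioritization

Population allele frequencies (1000 Genomes, gnomAD, cohort) are the only
hard filter: a variant is retained iff every frequency *present* is
strictly below the rarity threshold (default 1%, configurable and distinct
per deployment — there is no universally correct cutoff), and an absent
frequency is treated as novel.  CADD and splice delta scores
(acceptor/donor gain/loss) order the retained candidates but can never
exclude one.  This is a deliberate asymmetry: genuinely causal
deep-intronic variants can carry near-zero predictor scores, so treating
scores as gates would discard exactly the variants the screen exists to
find.  The package consumes these scores from a precomputed annotation
table keyed by (chrom, pos, ref, alt); it never runs the underlying
models.

## Trio phasing

Phasing is genotype-only phasing **by inheritance**: a proband-carried
variant present in exactly one parent is assigned to that parental allele;
present in both parents it is ambiguous; in neither, de novo; with a
missing parental genotype, undecidable.  Two candidates with different
single-parent origins are in trans, same origin in cis, anything else
unknown.  No read-backed or population phasing is attempted.

## Mosaic fraction from depth

A heterozygous deletion carried by a fraction `f` of cells removes one of
two copies in those cells, so mean depth over the deleted region is
`flank_depth × (1 − f/2)` and the estimator is
`f = clamp(2(1 − depth_in/depth_flank), 0, 1)`, reported as a percent.
The estimator applies to deletions only (duplication mosaicism is out of
scope), and flank depth is taken over windows of the same total length as
the SV on each side with a 1 kb guard zone at the breakpoints, where read
evidence is unreliable.  At 60× Poisson coverage over a ≥ 10 kb deletion
the sampling error of the depth ratio is well under one percentage point,
so recovery within ±5 points is expected essentially always; the test
suite asserts ≥ 95% of 1,000 replicates per planted fraction.

## Runs of homozygosity

Detection slides a window of 50 consecutive *sites* (not a fixed physical
length, making the detector robust to variant-density variation) and flags
windows with ≤ 2 heterozygotes; overlapping flagged windows are merged,
and merged regions shorter than 2 Mb, with fewer than 100 sites, or with
a heterozygote fraction above 5% are discarded.  These defaults
comfortably detect the 5–20 Mb ROH scale relevant to consanguineous
probands while tolerating sporadic genotyping errors.  Real production
pipelines often receive ROH calls from an external tool; this detector is
a self-contained stand-in with an explicit contract, not an attempt to
reproduce any specific external method.

Downstream, a rare proband-homozygous variant inside a containing ROH is
promoted as a `HOMOZYGOUS_IN_ROH` candidate even when the recorded first
hit was heterozygous — a heterozygous first hit recorded at recruitment
can be misleading in a consanguineous family, and homozygous regions
deserve explicit scrutiny.

## Splice-consequence arithmetic

Only length and reading-frame arithmetic is computed.  A new splice
acceptor created at intronic offset `c.X−k` (its AG ending at position
−k) splices in positions −(k−1)…−1, i.e. `k − 1` retained bases; offsets
−1/−2 are the canonical acceptor dinucleotide and are rejected as a
different variant category.  Pseudoexon and skipped-exon lengths are
inclusive spans; frameshift is the mod-3 rule.  Protein-level consequences
(the `fs*N` termination offset) require transcript sequence and are not
generated.  HGVS parsing is intentionally narrow — intronic/exonic
substitutions, `c.START_ENDdel`, `c.START_ENDinsN` — and anything else is
rejected with a clear error.

## Screening and ranking

For each case the screen takes the first-hit gene body padded by 1 kb
(configurable, boundary inclusive), collects rare SV clusters carried by
the proband and rare proband-carried small variants in the window
(excluding the first-hit variant itself), phases each candidate against
the first hit where a trio exists, and promotes homozygous-in-ROH
variants.  Ranking: in-trans and homozygous-in-ROH candidates first
(both are complete biallelic configurations), then unknown phase, then
cis; within a tier, descending evidence score, then SVs before small
variants (SVs are screened first in the clinical workflow), then genomic
position.  Cis candidates are flagged, never dropped: inheritance-based
phase can be wrong under ambiguity, and phase is supporting evidence, not
a gate.  Solved/unsolved adjudication (literature, ClinVar, clinical
review) is a human step outside the package; reports carry evidence, not
verdicts.

## The synthetic cohort generator

`secondhit.simulate` emulates the statistical structure the screen
assumes, on two synthetic 250 Mb chromosomes with 30 non-overlapping
genes of 10–30 exons:

* **Trios** (default 200 families) with Mendelian genotypes over a
  backbone of common biallelic sites (allele frequency 0.5) at 50
  sites/Mb — a sparse common-SNP backbone chosen so that a 5 Mb ROH block
  carries ~250 sites and a 50-site detector window spans ~1 Mb.  Real WGS
  callsets are far denser; density only sharpens ROH boundaries, so the
  sparse backbone is the conservative choice.
* **Two SV callers** ("A"/"B") each observing every true SV with
  independent breakpoint jitter, rounded Normal(0, sd), default sd 20 bp —
  enough to exercise the overlap tolerance without being tuned to any
  specific caller pair, for which no public jitter statistics exist — and
  independent per-caller dropout (default 10%).  For *planted* events one
  caller is always retained per carrier: the screen's recall contract is
  conditional on the second hit existing in the call set; caller
  sensitivity is a separate axis not under test.
* **Background SV clusters** (default 40) at configured carrier fractions
  mixing rare (0.1–0.8%) and common (5%, 12%) clusters, realized as
  Bernoulli parental carriers with Mendelian transmission.
* **Planted cases** (default 10: four SV — one of them a 1,591 bp
  insertion — three deep-intronic SNV, two homozygous-in-ROH, one mosaic
  parental deletion).  Compound-het plants are genuinely in trans by
  construction: the first hit is transmitted by one parent, the second by
  the other.  Planted intronic SNVs cycle through evidence profiles
  spanning the realistic range (acceptor gain 0.02 with CADD 1.25; 0.99
  with 18.5; donor loss 0.51 with 10), including the
  near-zero-score-but-causal profile.  The mosaic parent carries its
  deletion in 44% of cells: genotyped het, but with depth-table rows at
  `mean_depth × (1 − f/2)` over the SV and Poisson-sampled flanks.
  ROH plants force parental allele sharing over the block (parents remain
  Mendelian-consistent het carriers) with heterozygote contamination at
  the genotyping error rate (default 0.5%).
* **Private rare SNVs** (Poisson, mean 3 per sample) provide the screen's
  false-positive background.

A single seeded generator drives all randomness; a fixed seed gives
byte-identical output files.

### What the generator does *not* emulate

No read-level data (depth summaries are emitted directly, not realigned);
no sequence content (REF/ALT are placeholder nucleotides); no
caller-specific error modes (systematic breakpoint bias, genotyping error
on SVs, type confusion); no linkage disequilibrium or population
structure; no balanced/complex SV classes beyond DEL/DUP/INV/INS.
Passing the planted-recall tests therefore demonstrates that the
*pipeline logic* — aggregation, rarity, windowing, phasing, ROH promotion,
ranking — is correct under honest noise, not that the screen achieves any
particular sensitivity on real cohort data, where caller behaviour and
annotation coverage dominate.

## Problem sizes in the test suite

The end-to-end recall property runs the default 200-family cohort over 20
seeds (~2,000 planted-case screens plus ~3,800 false-positive screens);
clustering is verified against a brute-force transitive-closure oracle on
500 random instances of up to 50 calls; the mosaic estimator on 1,000
replicates per planted fraction at 60× over 10 kb; ROH recovery on 100
seeds of 5 Mb blocks.  These sizes exercise every code path at full
default parameters while keeping the suite fast enough to run on every
change.

## Known limitations

* Cohort frequency is participant-based; allele-count frequencies and
  multi-cohort stratification are out of scope.
* No BND/translocation parsing; complex multi-segment SVs appear only as
  their simple components.
* Phasing is inheritance-only: both-parent carriers and singletons yield
  unknown phase.
* The mosaic estimator has no confidence interval and assumes a clean
  diploid flank.
* Regulatory-region screening (promoters/enhancers up to ~1 Mb away) is
  deliberately not attempted; the gene window is local.
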