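# Methods

This note records the models, rules, defaults and design choices behind the
package, and what the synthetic-data tests do and do not establish about real
data.

## Coordinates and transcript identity

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted at the I/O boundary and nowhere else.  A transcript is
an ordered chain of non-overlapping, non-adjacent exons on one strand of one
chromosome; exon chains are the unit of isoform identity.

Two transcripts are the *same isoform* when chromosome, strand and the full
exon chain — terminal ends included — are equal (`exon_chain_key`).  This
matches analyses done against a fixed annotation, where identity is by
annotated transcript.  For assembled transcripts with imprecise 5'/3' ends a
`chains_match(a, b, terminal_tolerance)` helper relaxes only the first exon
start and last exon end; the default tolerance is 0 and the overlap
operations use exact keys.  Unstranded records are rejected: splice-site
semantics and sequence extraction need a strand.  Chromosome naming is taken
as-is and must be consistent across inputs.

## Expression and the expressed set

`RPKM = 10⁹·C/(N·L)` with C exon reads, N total mapped reads, L spliced
length in bases.  The expressed-set threshold is **0.1 RPKM, inclusive**
(≥ 0.1): the boundary case is retained.  Expression may be supplied
precomputed or as counts plus library size; when both are present they must
agree to 1e-6 relative error — the upstream quantifier is not re-run, so a
disagreement is a data error, not something to silently resolve.  An
*expressed gene* is a gene with at least one expressed isoform.

## Coding classes

Transcripts carry CPC-style scores (positive ⇒ coding).  A score exactly 0 is
noncoding, matching the convention that only positive scores are called
coding; the cutoff is configurable (`--coding-score-cutoff`, default 0) for
sensitivity analysis.  Long ncRNAs are noncoding transcripts **strictly longer
than 200 nt**; exactly 200 nt is short.  Bifunctionality requires a
protein-coding isoform *and a long ncRNA* among a gene's expressed isoforms —
short noncoding isoforms do not qualify, because the biological claim
concerns genes producing both proteins and long regulatory RNAs.

## Two-sample comparison

Gene-level identity is by gene id alone: a gene expressed in both samples is
"common" even if no isoform coincides — the gene/isoform discrepancy is the
result, not an error.  Isoform-level identity defaults to the exon-chain key
(robust to transcript-id drift between quantifications); a `transcript_id`
mode mirrors the shared-annotation setting.  Keys claimed by transcripts of
different genes are ambiguous and are excluded from the partition and
reported.  Percentages are rounded half-up to two decimals for report parity
with the published tables.  Exon-count and isoforms-per-gene histograms are
binned {1,2,3,4,5,≥6}.

## Splice-structure classes

Decision tree with fixed precedence, evaluated against the union of a gene's
annotated isoforms:

1. **IDENTICAL** — exon chain equals an annotated chain.
2. **INTRON_RETENTION** — an exon strictly contains an annotated intron
   (both splice sites of the intron strictly inside the exon).
3. **NOVEL_BOUNDARY_OR_EXON** — an internal boundary (all exon starts/ends
   except the transcript's first start and last end) not in the annotated
   boundary set, or an exon overlapping no annotated exon.
4. **EXON_SKIPPING** — otherwise.

Rationale for the precedence retention > novel > skipping: the published
class counts are disjoint, and intron retention is the most structurally
specific signal, so it wins when a transcript shows several features.
Terminal ends are excluded from novelty because assembled transcript ends are
unreliable and some apparent novelty reflects incomplete annotation.  The
"contains introns" phrasing for the first non-identical class is ambiguous in
the field (retention vs unspliced fragments); this package implements
retention — an exon engulfing both splice sites — and classifies unspliced
fragments whose boundaries are otherwise annotated the same way only when the
engulfing test fires.

## Conservation

Evaluated over exonic (spliced) bases only, because the objects are
transcripts.  `base_conserved_fraction` counts exonic bases with score ≥ 0.9
(configurable) over spliced length; bases missing from the track default to
score 0 (score dumps omit unscored bases), with a `missing_as_zero=False`
option that drops missing bases from the denominator instead.
`element_overlap_ratio` is exact interval arithmetic over merged elements.
"Contains a conserved element" means ≥ 1 overlapped exonic base
(configurable minimum).  No numeric "highly conserved transcript" cutoff is
imposed; the base-fraction statistic is exposed and the cutoff left to the
user.  Clades are independent tracks (46 vertebrates, 33 placental mammals,
10 primates).

## Disease screen

Probe matching is **exact and unique**: a probe represents a transcript iff
its sequence occurs as a perfect substring at exactly one position across the
whole target transcript set (occurrences are counted over all positions of
all transcripts, so two hits inside one transcript also disqualify).
Matching is against the sense spliced sequence by default; a
both-orientations flag covers array-design ambiguity, and an optional
pre-filter drops probes that already have a gene symbol.  Uniqueness is
relative to the supplied transcript set, not the genome.

The differential-expression method for the public case/control sets is not
dictated by the original analysis, so the package uses an assumption-light
conventional default: Welch two-sample t-test on log2(x+1) values with
Benjamini–Hochberg FDR at 0.05 (strict `q < α`).  Rows constant across all
samples get p = 1 by convention and are flagged.  The correlation screen uses
Pearson r with the two-sided p-value from the t transform on n−2 degrees of
freedom; a hit needs **|r| ≥ 0.4** (inclusive; the absolute value is used
because a strong negative association is equally a hit in a screen) and
**p < 0.05** (exclusive).  r is computed as `Sxy/√(Sxx·Syy)` with the product
under a single square root so exactly representable boundary correlations are
not perturbed by rounding.

## Synthetic data: what it emulates and what it does not

The generators fix every recoverable quantity by construction and record it
(`GroundTruth`); realized values are bookkept from the constructed sets, never
by running the pipeline, so recovery tests are exact.

* **Catalog** — non-overlapping gene loci on a toy chromosome; isoforms of a
  gene are distinct subsets of a shared master exon chain (exons 80–300 bp,
  introns 60–200 bp).  Defaults: annotated isoforms per gene weighted
  (0.25, 0.30, 0.20, 0.12, 0.08, 0.05) for 1..6 (mean ≈ 2.6), exons per
  isoform weighted over 1..10 with a heavy multi-exon tail, mirroring the
  shape of annotation-based quantification where ~94 % of transcripts are
  multi-exon.
* **Paired transcriptomes** — gene sharing defaults to 0.66 of the catalog
  (the "about two-thirds in common" regime) and isoform sharing to 0.35 of
  sample A's isoforms, which preserves the qualitative reversal (gene sharing
  ≫ isoform sharing) while remaining jointly feasible with the
  identical-set quota (0.3 of common genes, single-isoform genes preferred
  as hosts).  Sharing is realized by a two-template scheme on ordinary common
  genes (share one isoform vs none); requests above the achievable ceiling
  raise a constraint error, requests below the structural floor clamp to the
  floor and record the realized value.  Bifunctional genes exclusive to one
  sample are placed among that sample's exclusive genes, and category-switch
  genes use a short (≤ 200 nt) noncoding filler isoform on the opposite side
  — both choices keep the planted groups disjoint so recovery is exact.
  Splice variants are planted by explicit edits of an annotated chain
  (engulf the first intron / shift a boundary to an unannotated coordinate /
  drop the second exon) on noncoding sample-exclusive host genes, each edit
  checked against the annotated key, boundary and intron sets so the class is
  unambiguous under the module's precedence.  RPKMs are log-normal
  (median ≈ 5); each sample contains one record exactly at 0.1, and the
  sub-threshold padding contains mass at 0.0999, so the inclusive boundary is
  exercised end to end.
* **Conservation** — elements are planted inside the largest exon of a chosen
  fraction of transcripts with base score 0.95 over the element and 0.2
  elsewhere, so the ≥ 0.9 criterion selects exactly the planted bases.  When
  sibling isoforms share the host exon the sibling is covered too; the
  bookkeeping accounts for this, and exact-fraction checks use one isoform
  per locus.
* **Disease matrices** — log2(x+1) values are exactly Gaussian
  (mean 6, SD 1 by default); DE probes get a mean shift of `effect_size`
  SDs in cases; correlated gene probes are linear functions of their ncRNA
  probe plus independent noise at correlation ρ, which survives a DE shift —
  the bundle therefore attaches correlation pairs to DE probes, as the screen
  only correlates differential probes.  Note that in a case/control design
  all differential probes share the disease axis and hence correlate with all
  shifted gene probes; the screen measures association, not a specific pair.

What passing these tests shows: the operations implement their definitions
exactly (oracle equivalence, exact planted recovery) and the statistical
defaults are calibrated (null false-discovery fraction within the nominal
level, high power at large planted shifts, unbiased correlation recovery).
What they do not show: robustness to read-mapping artifacts, isoform-inference
errors, probe cross-hybridization or normalization effects — real-data
phenomena the generators deliberately do not model (no read-level
simulation; expression enters as counts/RPKM).

## Problem sizes

Defaults are chosen so each analysis and the acceptance script complete in
seconds on one CPU: catalogs of 60–120 genes (≈ 150–350 transcripts), 300–500
seeded null simulations and 150–200 power/recovery simulations at 100 probes
× 20–40 samples.  These sizes give binomial standard errors well inside the
asserted tolerances; all generators scale to larger runs by parameter.

## Known limitations

* Isoform identity is exact-chain by default; quantifications produced by
  different assemblers may need the terminal-tolerance helper.
* Cross-sample comparison assumes both samples are quantified against
  consistent chromosome naming; no liftover or alias handling.
* The DE default (Welch + BH) is deliberately simple and pluggable; count
  models (negative binomial) are out of scope because the screen consumes
  pre-normalized array matrices.
* bedGraph/wiggle score tracks are read into memory; genome-scale tracks
  should be thinned or supplied as bigWig (optional reader) before use.
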