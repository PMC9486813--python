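# Methods

## The screening model

The pipeline estimates the population burden of nonsyndromic hearing loss
(NSHL) carrier status from a genome-sequenced cohort of individuals who do
not themselves have hearing loss. Three design commitments shape everything
downstream:

* **Curation is an input, not an algorithm.** Gene–disease validity labels
  (ClinGen tiers) and final ACMG variant classes are expert judgements; the
  pipeline consumes them as tables and enforces their completeness (a
  candidate without a decision is an error, not a silent pass-through).
  Nothing in the package scores evidence.
* **Only catalogued variants are candidates.** A sequence variant absent from
  the ClinVar-style catalogue is never screened. This reproduces a known
  limitation of catalogue-restricted screens (roughly 15% of relevant alleles
  may be missed); it is intentional fidelity, not an oversight.
* **Counts are of distinct individuals.** Carrier tallies count people, not
  genotype events; homozygotes are excluded from heterozygote tallies but
  contribute two alleles to allele frequencies.

## Stage-by-stage definitions

**Sample QC.** Eight per-sample sequencing metrics with fixed comparators:
mapped reads > 98% (strict), median autosome coverage ≥ 20×, coverage
uniformity ≥ 80%, cross-contamination < 2% (strict), autosome callability
≥ 95%, Q30 bases ≥ 90%, chimeric reads < 5% (strict), duplicates < 10%
(strict). An individual fails on any violation. Affected status is HPO-term
intersection with a fixed hearing-loss term list; the unaffected remainder is
the cohort for all frequencies.

**Variant screen.** Preselection keeps catalogue records in retained panel
genes whose aggregate class is P, LP, or conflicting *with at least one P/LP
submitter* (conflicting-without-support, VUS-only, B and LB are never
candidates). Call-level QC masks genotypes below 20× depth, then drops
variants whose non-missing call fraction over the screened samples is < 0.95
(boundary kept at ≥). The call-rate denominator defaults to the QC-passing
sample set being screened; it is a parameter because reasonable analyses
could use the unaffected subset instead. Curation then keeps final classes P
and LP only. Matching everywhere is exact on (contig, pos, ref, alt) after
multi-allelic decomposition; left-alignment is assumed done upstream.

**CNV screen.** Events from the CNV caller and small unbalanced SVs from the
SV caller share one type and are deduplicated per sample on exact
coordinates, preferring the CNV-caller record. Filters, in order: cohort
membership (events of affected or QC-failed samples leave the analysis),
coding overlap (≥ 1 bp of any coding exon), size (≤ 1 Mb), syndromic critical
regions (no overlap). Coordinates are 1-based inclusive
(`size = end − start + 1`, so the recurrent STRC deletion
chr15:43600849–43658715 is 57,867 bp ≈ 57.9 kb); interval arithmetic converts
to 0-based half-open internally. Recurrence ("the same CNV in 38 people") is
exact-coordinate identity — reciprocal-overlap clustering of near-identical
breakpoints would be invented behaviour and is deliberately out of scope.
Exon-number annotation follows the supplied exon map's numbering column,
which lets minus-strand genes number exons against the coordinate direction.

**Carrier statistics.** Per variant: `AF = (het + 2·hom + hemi) / (2·N)` with
N the genotyped unaffected individuals. Per gene and mechanism
(sequence / CNV / combined): allele counts are summed before dividing —
summing per-variant AFs would double-count individuals carrying two variants
of one gene, so the allele-count path is authoritative. Carrier categories
per individual use the precedence AD-only > AD/AR-gene > AR-only (an
individual is counted once); carriers only of X-linked genes fall into
"none". The dominant-implicated set is the union of AD-only and AD/AR-gene
heterozygous sequence carriers and CNV carriers of AD or AD/AR genes.

**Hardy–Weinberg projection.** Per-gene pathogenic allele frequency *q* is
the combined (sequence + CNV) AF, so *q*² counts compound heterozygotes as
affected — the correct reading for a recessive locus with allelic
heterogeneity. The carrier relation uses *p* ≈ 1 (*q* = carrier
frequency / 2); an exact mode solving 2*q*(1−*q*) = cf is available behind a
flag for sensitivity analysis and differs from the approximation by < 5%
relative for carrier frequencies ≤ 0.05 (property-tested). Burdens sum raw
*q*² before display rounding; "1 in X" is the nearest integer of 1/Σ*q*².
Only genes with an AR mode may enter a burden; passing an AD-exclusive gene
is a contract violation. Random mating is assumed throughout — no inbreeding
(F) correction, which matters precisely for the consanguineous minority the
ROH stage identifies.

**ROH / consanguinity.** NROH and SROH count autosomal segments ≥ 1 Mb;
FROH = SROH / 2,881 Mb. The 2,881 Mb denominator is the GRCh38 autosomal
length and is configurable; it makes a mean SROH of ~30 Mb correspond to a
mean FROH of ~1.1%, consistent with published summaries. SROH classes:
> 123 Mb evidence of consanguinity, 79–123 Mb probable, < 79 Mb probable
non-consanguinity, with ≤ 22 Mb taking precedence as no evidence (the
published prose overlaps the last two rules; precedence resolves it).
Self-report reconciliation flags "yes" against the two low classes and "no"
against the two high classes; unknown reports leave the denominator.

**Reference comparison.** Per co-detected variant, a 2×2 table of alternate
vs non-alternate allele counts by cohort. The two-tailed Fisher exact p is
the point-probability definition — the sum of hypergeometric outcomes with
probability at most the observed table's, within relative tolerance 1e−7 —
computed in log space (gammaln) so cohort-scale margins do not underflow.
FDR control is Benjamini–Hochberg step-up with family size equal to the
intersection of the two cohorts' variant sets, α = 0.05. Both statistics are
implemented from first principles and cross-checked in the test suite against
independent oracles (exact-fraction enumeration, scipy, statsmodels).

## The synthetic cohorts

`simulate.generate_cohort` materializes a complete input bundle from a
configuration listing planted variants (gene, het/hom counts, catalogue and
curated classes), planted CNVs (coordinates, carrier counts, classes), decoy
families, sample-role counts, and ROH/self-report profiles. Guarantees:

* deterministic and byte-identical given a seed (one named generator, no
  global state); different seeds permute carrier assignments but not counts;
* planted carriers are placed among QC-passing unaffected individuals by
  sampling without replacement, so recovered counts are exact (a flag plants
  them among affected individuals instead, to test the exclusion path);
* every decoy is constructed to be removed by exactly one named filter
  (benign/VUS catalogue classes at preselection; low depth and low call rate
  at call QC; noncoding, oversize, syndromic and affected-sample CNVs at
  their respective filters), which the round-trip tests assert per decoy
  family via the exclusion logs;
* infeasible plans (more carriers than plantable individuals) fail before
  any file is written.

The frozen study-scale fixture (`paper_fixture`) encodes a 2,199-sample
cohort — 13 QC failures, 89 affected — whose screen reproduces the published
headline numbers of a 2,097-genome Brazilian cohort study end to end:
funnels 996 → 118 → 89 sequence variants and 5,285 → 232 → 12 CNVs, 222/54/4
carriers, the per-gene combined AFs, and the Hardy–Weinberg projections. Two
reconstruction caveats are deliberate. First, the published work prints only
headline variants and per-gene totals; the fixture pins the printed
per-variant counts and distributes the remaining carriers over plausibly
named genes so that gene-level and cohort-level totals match exactly — the
filler gene and variant identities are schematic, and panel attribute
assignments beyond the named constraints are arbitrary within the published
cross-tabulation cells. Second, two published numbers are not recomputable
from main-text data and are *not* reproduced by construction: the OTOA
c.2359G>T AF printed as 0.61% (25/4,194 = 0.596% → 0.60% here; the printed
value implies a call-rate-adjusted denominator that was not reported) and
the all-recessive burden 0.45/1,000 = 1:2,222, which depends on a
supplementary per-gene AF distribution (under this reconstruction the
pipeline computes 0.45/1,000 = 1:2,230; the top-five burden 0.42/1,000 is
exact). The reference-cohort table is likewise synthetic: counts are
frequency-matched for 12 of 13 shared variants and enriched for OTOA
c.2359G>T so that exactly one comparison is significant after FDR, mirroring
the published 12-vs-1 split without the unpublished real counts.

What passing tests do **not** show about real data: the generator plants
exact genotypes rather than calling them from reads, has no linkage
disequilibrium or haplotype structure, no population stratification, no
batch effects, and its QC metrics are drawn around the thresholds rather
than from instrument distributions. The fixture demonstrates that the
*analysis* reproduces the published arithmetic, not that variant calling
would.

## Numerical and formatting choices

* Display rounding is decimal round-half-up to two decimals (0.7153% → 0.72%);
  internal values keep full precision, and only display paths round.
* The one published table inconsistency we encountered — a combined
  unique-variant count smaller than sequence + CNV counts for one gene — is
  treated as a typo; this package always reports combined = sequence + CNV.
* Fisher p-values are clipped to [0, 1] after log-space summation; a table
  with an empty margin yields p = 1 by convention.
* The panel fixture carries 137 association rows: the 129 retained
  associations of the published inheritance summary plus 8 excluded rows
  (7 genes and one refuted gene-mode). The published prose double-counts one
  gene between its exclusion lists, which is why "129 preselected genes minus
  seven excluded" does not equal the 121 retained; the fixture encodes the
  arithmetic that is actually consistent (121 unique retained genes, 129
  retained associations).

## Problem sizes

The default test suite and the acceptance script run the full study-scale
fixture (2,199 samples × ~1,000 catalogue sites, 5,285 CNV events, ~2,100
ROH profiles) once per session — about 15 s — plus 50 small seeded
round-trip cohorts (40–80 samples each) and the property-test batteries for
the statistical primitives. These sizes were chosen because the screen's
arithmetic is exact at any scale: planted-count recovery at n = 60 and
n = 2,199 exercises identical code paths.
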