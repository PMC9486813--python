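# nshlscreen

Carrier screening for **nonsyndromic hearing loss (NSHL)** in genome cohorts.

Hearing loss is the most common sensory deficit in humans, and most prelingual
deafness is monogenic. A genome-sequenced cohort of individuals *unaffected* by
hearing loss can therefore be mined for carrier status: heterozygotes for
recessive (AR) alleles inform reproductive counselling, while heterozygotes for
dominant (AD) alleles may themselves develop postlingual hearing impairment.
`nshlscreen` implements the full screening analysis as a tested, reusable
pipeline:

1. **Gene panel curation** — a table of gene × inheritance-mode associations
   with ClinGen-style gene–disease validity labels (definitive … refuted);
   disputed/refuted associations and flagged genes are removed, per mode, so a
   gene with a refuted AR form can survive through its AD form.
2. **Sequence-variant screening** — candidates are catalogue (ClinVar-style)
   variants in panel genes classified P/LP, or conflicting with at least one
   P/LP submitter; calls below 20× depth are masked, variants with call rate
   < 95% are dropped, and an analyst curation table (final ACMG class) decides
   what is clinically relevant. Mitochondrial screening is a fixed lookup list.
3. **CNV screening** — deletions/duplications (and small unbalanced SVs) must
   overlap ≥ 1 bp of coding sequence, be ≤ 1 Mb, avoid syndromic critical
   regions, and pass curation; recurrence is exact-coordinate identity.
4. **Carrier statistics** — per-variant and per-gene allele frequencies
   (`AF = (het + 2·hom) / 2N`) split by molecular mechanism
   (sequence / CNV / combined), and per-individual inheritance-implication
   categories (AR-only, AD/AR-gene, AD-only).
5. **Hardy–Weinberg projection** — with pathogenic allele frequency *q* per
   gene (from the carrier frequency 2*pq* under *p* ≈ 1, i.e. *q* ≈ cf/2), the
   projected frequency of affected individuals is *q*²; summing *q*² over
   recessive genes gives the population burden of AR deafness.
6. **ROH consanguinity metrics** — NROH / SROH / FROH over runs of
   homozygosity ≥ 1 Mb, with SROH thresholds (22 / 79 / 123 Mb) classifying
   consanguinity evidence and reconciliation against self-report.
7. **Reference-cohort comparison** — per-variant 2×2 allele-count tables
   against a reference population, tested with a from-scratch two-tailed
   Fisher exact test and Benjamini–Hochberg FDR adjustment.

Because cohort-scale genome data cannot be redistributed, the package ships a
first-class synthetic-cohort generator (`nshlscreen.simulate`) that emits the
complete input bundle (multi-sample VCF, CNV/SV table, ROH BED, phenotype and
sample-QC tables, catalogue, curation decisions, panel, exon/syndromic BEDs,
reference counts) with exact, seeded carrier planting — including a frozen
study-scale fixture that reproduces a published 2,097-genome screen end to end.

## Worked example

```bash
nshlscreen generate --paper-fixture --seed 7 --out bundle/
nshlscreen screen --config bundle/run_config.yaml --out run/
```

The `screen` command prints the carrier summary of the unaffected cohort:

```json
{
  "ad_implicated": 104,
  "ad_implicated_pct": 4.96,
  "cnv_het_individuals": 54,
  "cnv_het_pct": 2.58,
  "combined_het_individuals": 276,
  "combined_het_pct": 13.16,
  "het_categories": {"AD_AR_gene": 89, "AD_only": 10, "AR_only": 123, "none": 0},
  "seq_het_individuals": 222,
  "seq_het_pct": 10.59,
  "seq_hom_individuals": 4,
  "seq_hom_pct": 0.19
}
```

Reading: of 2,097 unaffected individuals, 222 (10.59%) are heterozygous for a
P/LP sequence variant, 54 (2.58%) for a P/LP CNV, 4 (0.19%) are homozygous,
and 104 (4.96%) carry alleles in genes with a dominant disease form. `run/`
additionally contains `per_variant.tsv` (e.g. *GJB2* c.35del: 28 het + 1 hom,
AF 0.72%), `per_gene.tsv` (e.g. *GJB2* combined AF 0.0157, *STRC* 0.0100),
`per_cnv.tsv` (the recurrent 57.9 kb *STRC* deletion: 38 carriers, AF 0.91%,
exons 1–26 of 29), `hw_estimates.tsv` (*GJB2* 0.25 affected per 1,000; top-five
recessive burden 0.42/1,000), `roh_metrics.tsv`, `comparisons.tsv` (13 variants
shared with the reference cohort, 1 significantly different after FDR), every
exclusion log, and `summary.json` with all of the above.

The same stages are importable directly (`from nshlscreen import
fisher_exact_two_tailed, hw_affected_frequency, roh_metrics, ...`) — see the
module docstrings.

## Layout

| Module | Role |
| --- | --- |
| `nshlscreen.panel` | panel loading, validity filtering, Table-style summaries |
| `nshlscreen.variants` | catalogue preselection, call QC, curation, mito lookup |
| `nshlscreen.cnv` | coding-overlap / size / syndromic filters, annotation, recurrence |
| `nshlscreen.cohort` | sample QC, phenotype exclusion, carrier statistics |
| `nshlscreen.hw` | Hardy–Weinberg disease-frequency projection |
| `nshlscreen.roh` | ROH metrics and consanguinity classes |
| `nshlscreen.compare` | Fisher exact + BH-FDR reference comparison |
| `nshlscreen.simulate` | synthetic cohorts and the frozen study-scale fixture |
| `nshlscreen.pipeline` / `nshlscreen.cli` | orchestration, config, reports |

See `docs/methods.md` for the underlying model, parameter defaults, and the
limits of what the synthetic cohorts can show.
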