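"""Cohort definition and carrier statistics.

Sample QC keeps individuals meeting all eight sequencing-quality thresholds
(comparators follow the screening protocol exactly: mapped reads strictly
>98%, median autosome coverage >=20X, coverage uniformity >=80%,
cross-contamination strictly <2%, autosome callability >=95%, Q30 bases
>=90%, chimeric reads strictly <5%, duplicates strictly <10%). Phenotype
exclusion then removes every individual whose HPO terms intersect the
hearing-loss term set; the remaining unaffected individuals are the cohort
all allele frequencies refer to.

Allele frequency for an autosomal variant is
(het + 2*hom) / (2 * n_genotyped); carrier tallies count distinct
individuals, and homozygotes are kept out of heterozygote counts while still
contributing two alleles. Per-gene summaries aggregate allele counts over the
gene's variants split by molecular mechanism (sequence / CNV / combined);
allele-count aggregation, not AF summing, is authoritative when one
individual carries two variants of a gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .panel import GenePanelEntry, gene_modes
from .variants import GenotypeCall

QC_METRICS = (
    "mapped_read_pct",
    "autosome_median_coverage",
    "uniformity_pct",
    "contamination_pct",
    "callability_pct",
    "q30_pct",
    "chimeric_pct",
    "duplicate_pct",
)

#: (metric, comparator, threshold); comparator is the condition for PASSING.
QC_THRESHOLDS: tuple[tuple[str, str, float], ...] = (
    ("mapped_read_pct", ">", 98.0),
    ("autosome_median_coverage", ">=", 20.0),
    ("uniformity_pct", ">=", 80.0),
    ("contamination_pct", "<", 2.0),
    ("callability_pct", ">=", 95.0),
    ("q30_pct", ">=", 90.0),
    ("chimeric_pct", "<", 5.0),
    ("duplicate_pct", "<", 10.0),
)

CARRIER_CATEGORIES = ("AD_only", "AD_AR_gene", "AR_only", "none")


class CohortError(ValueError):
    """Raised on cohort-statistics contract violations."""


@dataclass(frozen=True)
class Individual:
    """One cohort member with phenotype terms, QC metrics and self-report."""

    sample_id: str
    hpo_terms: frozenset[str] = frozenset()
    qc: Mapping[str, float] = field(default_factory=dict)
    consanguinity_self_report: str = "unknown"


@dataclass
class VariantCounts:
    """Genotype tallies for one variant in the screened cohort."""

    het_count: int
    hom_count: int
    n_genotyped: int
    hemi_count: int = 0

    @property
    def allele_count(self) -> int:
        return self.het_count + 2 * self.hom_count + self.hemi_count

    @property
    def allele_frequency(self) -> float:
        return allele_frequency(
            self.het_count, self.hom_count, self.n_genotyped, self.hemi_count
        )


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal round-half-up, used only for report display."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def read_individuals(
    phenotype_path: str | Path, qc_path: str | Path
) -> list[Individual]:
    """Join the phenotype table (sample_id, hpo_terms, self_report) with QC metrics.

    hpo_terms is a semicolon-separated list (may be empty).
    """
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str, keep_default_na=False)
    qc = pd.read_csv(qc_path, sep="\t", keep_default_na=False)
    qc_by_id = {str(r["sample_id"]): r for _, r in qc.iterrows()}
    out = []
    for r in pheno.itertuples(index=False):
        qrow = qc_by_id.get(str(r.sample_id))
        if qrow is None:
            raise CohortError(f"sample {r.sample_id} missing from QC table")
        terms = frozenset(t for t in str(r.hpo_terms).split(";") if t)
        out.append(
            Individual(
                sample_id=str(r.sample_id),
                hpo_terms=terms,
                qc={m: float(qrow[m]) for m in QC_METRICS if m in qrow},
                consanguinity_self_report=getattr(r, "self_report", "unknown")
                or "unknown",
            )
        )
    return out


def sample_qc_filter(
    individuals: Iterable[Individual],
) -> tuple[list[Individual], list[tuple[Individual, list[str]]]]:
    """Split individuals into QC-passing and failing (with violated metrics).

    All eight metrics must be present; an individual fails when any threshold
    is violated, with boundary semantics exactly as printed.
    """
    passing: list[Individual] = []
    failing: list[tuple[Individual, list[str]]] = []
    for ind in individuals:
        missing = [m for m in QC_METRICS if m not in ind.qc]
        if missing:
            raise CohortError(
                f"sample {ind.sample_id} missing QC metrics: {', '.join(missing)}"
            )
        violated = []
        for metric, op, thr in QC_THRESHOLDS:
            v = ind.qc[metric]
            ok = {
                ">": v > thr,
                ">=": v >= thr,
                "<": v < thr,
            }[op]
            if not ok:
                violated.append(metric)
        if violated:
            failing.append((ind, violated))
        else:
            passing.append(ind)
    return passing, failing


def phenotype_exclude(
    individuals: Iterable[Individual], hl_terms: Iterable[str]
) -> tuple[list[Individual], list[Individual]]:
    """Split into (unaffected, affected) by HPO-term intersection."""
    terms = frozenset(hl_terms)
    if not terms:
        raise CohortError("empty hearing-loss term set")
    unaffected, affected = [], []
    for ind in individuals:
        (affected if ind.hpo_terms & terms else unaffected).append(ind)
    return unaffected, affected


def count_genotypes(
    calls: Iterable[GenotypeCall], cohort_ids: Iterable[str]
) -> VariantCounts:
    """Tally one variant's genotypes over the given cohort.

    Only non-missing genotypes are counted; hemizygous calls carry one allele
    and are book-kept separately from het/hom.
    """
    ids = set(cohort_ids)
    het = hom = hemi = genotyped = 0
    for c in calls:
        if c.sample_id not in ids:
            continue
        if c.genotype == "missing":
            continue
        genotyped += 1
        if c.genotype == "het":
            het += 1
        elif c.genotype == "hom_alt":
            hom += 1
        elif c.genotype == "hemi_alt":
            hemi += 1
    return VariantCounts(het, hom, genotyped, hemi)


def allele_frequency(
    het_count: int, hom_count: int, n_genotyped: int, hemi_count: int = 0
) -> float:
    """AF = (het + 2*hom + hemi) / (2*n_genotyped); errors on empty denominator."""
    if n_genotyped <= 0:
        raise CohortError("allele frequency undefined for n_genotyped <= 0")
    return (het_count + 2 * hom_count + hemi_count) / (2 * n_genotyped)


def af_percent(af: float) -> float:
    """Display form of an allele frequency: percent, round-half-up, 2 decimals."""
    return round_half_up(af * 100.0, 2)


def gene_combined_summary(
    variant_counts: Mapping[object, VariantCounts],
    variant_genes: Mapping[object, str],
    variant_mechanisms: Mapping[object, str],
    n_genotyped: int,
) -> pd.DataFrame:
    """Per-gene carrier summary split by mechanism (sequence / cnv / combined).

    ``variant_counts`` maps a variant key to its tallies; ``variant_genes``
    and ``variant_mechanisms`` map the same keys to gene symbol and mechanism
    label. Allele counts are summed per gene and divided by 2*n_genotyped.
    """
    if n_genotyped <= 0:
        raise CohortError("n_genotyped must be positive")
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for key, counts in variant_counts.items():
        gene = variant_genes[key]
        mech = variant_mechanisms[key]
        if mech not in ("sequence", "cnv"):
            raise CohortError(f"unknown mechanism {mech!r}")
        for m in (mech, "combined"):
            cell = rows.setdefault(
                (gene, m), {"n_variants": 0, "het": 0, "hom": 0, "alleles": 0}
            )
            cell["n_variants"] += 1
            cell["het"] += counts.het_count
            cell["hom"] += counts.hom_count
            cell["alleles"] += counts.allele_count
    out = []
    genes = sorted({g for g, _ in rows})
    for gene in genes:
        for mech in ("sequence", "cnv", "combined"):
            cell = rows.get((gene, mech), {"n_variants": 0, "het": 0, "hom": 0, "alleles": 0})
            out.append(
                {
                    "gene_symbol": gene,
                    "mechanism": mech,
                    "n_unique_plp_variants": cell["n_variants"],
                    "het_count": cell["het"],
                    "hom_count": cell["hom"],
                    "allele_count": cell["alleles"],
                    "combined_af": cell["alleles"] / (2 * n_genotyped),
                }
            )
    columns = [
        "gene_symbol", "mechanism", "n_unique_plp_variants", "het_count",
        "hom_count", "allele_count", "combined_af",
    ]
    df = pd.DataFrame(out, columns=columns)
    return df.sort_values(["gene_symbol", "mechanism"], ignore_index=True)


def classify_carriers(
    carrier_variants: Mapping[str, Iterable[str]],
    panel: Iterable[GenePanelEntry],
) -> tuple[dict[str, str], Counter]:
    """Assign each carrier individual an inheritance-implication category.

    ``carrier_variants`` maps sample_id -> gene symbols of carried P/LP
    variants (sequence and/or CNV). Precedence: AD_only (any gene is
    AD-exclusive) > AD_AR_gene (any gene has both modes) > AR_only; carriers
    of only XL genes fall into "none". Returns (per-individual category,
    category tallies).
    """
    modes = gene_modes(panel)
    assignments: dict[str, str] = {}
    tallies: Counter = Counter()
    for sample_id, genes in carrier_variants.items():
        cats = set()
        for g in genes:
            m = modes.get(g)
            if m is None:
                raise CohortError(f"carried gene {g} not on retained panel")
            if "AD" in m and "AR" in m:
                cats.add("AD_AR_gene")
            elif m == {"AD"}:
                cats.add("AD_only")
            elif m == {"AR"}:
                cats.add("AR_only")
        if "AD_only" in cats:
            cat = "AD_only"
        elif "AD_AR_gene" in cats:
            cat = "AD_AR_gene"
        elif "AR_only" in cats:
            cat = "AR_only"
        else:
            cat = "none"
        assignments[sample_id] = cat
        tallies[cat] += 1
    return assignments, tallies


def ad_implicated(
    assignments: Mapping[str, str],
) -> set[str]:
    """Individuals whose carried genes imply possible dominant expression."""
    return {s for s, c in assignments.items() if c in ("AD_only", "AD_AR_gene")}
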