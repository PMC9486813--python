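"""Sequence-variant screening.

Candidate variants come from a ClinVar-style catalogue: records carrying an
aggregate classification (P, LP, conflicting, VUS, LB, B) plus a flag saying
whether at least one submitter called the variant P/LP. Preselection keeps
catalogue records in retained panel genes whose aggregate class is P, LP, or
conflicting-with-a-P/LP-submission; benign/likely-benign and VUS-only records
are never candidates, and variants absent from the catalogue are invisible to
the screen by design.

Genotype-level QC masks calls below a read-depth floor (default 20X) and drops
variants whose call rate across the screened sample set falls below 95%.
Final clinical status comes from an analyst curation table (ACMG five-tier
class per variant); only P/LP survive. Mitochondrial screening is a plain
lookup against a fixed list of hearing-loss-associated chrM variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

AGGREGATE_CLASSES = ("P", "LP", "conflicting", "VUS", "LB", "B", "absent")
FINAL_CLASSES = ("P", "LP", "VUS", "LB", "B")
GENOTYPES = ("hom_ref", "het", "hom_alt", "hemi_alt", "missing")

VariantKey = tuple[str, int, str, str]


class ScreenError(ValueError):
    """Raised on contract violations during variant screening."""


@dataclass(frozen=True)
class VariantRecord:
    """A catalogued sequence variant (VCF-convention 1-based coordinates)."""

    contig: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    aggregate_class: str = "absent"
    any_plp_submitter: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ScreenError(f"ref == alt at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ScreenError(f"non-positive position {self.pos}")
        if self.aggregate_class not in AGGREGATE_CLASSES:
            raise ScreenError(f"unknown aggregate class {self.aggregate_class!r}")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one catalogued variant, with read depth."""

    sample_id: str
    variant: VariantRecord
    genotype: str
    depth: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ScreenError(f"unknown genotype {self.genotype!r}")
        if self.depth < 0:
            raise ScreenError(f"negative depth {self.depth}")

    @property
    def alt_alleles(self) -> int:
        """Alternate-allele dose carried by this call (missing carries none)."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "hemi_alt": 1, "missing": 0}[
            self.genotype
        ]


@dataclass(frozen=True)
class CurationDecision:
    """Final analyst ACMG class for one variant key."""

    contig: str
    pos: int
    ref: str
    alt: str
    final_class: str
    acmg_criteria: str = ""

    def __post_init__(self) -> None:
        if self.final_class not in FINAL_CLASSES:
            raise ScreenError(f"unknown final class {self.final_class!r}")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Table / VCF ingestion


def read_catalogue(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant catalogue.

    Columns: contig, pos, ref, alt, gene_symbol, hgvs_c, hgvs_p,
    aggregate_class, any_plp_submitter (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        VariantRecord(
            contig=r.contig,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            gene_symbol=r.gene_symbol,
            hgvs_c=r.hgvs_c,
            hgvs_p=r.hgvs_p,
            aggregate_class=r.aggregate_class.strip(),
            any_plp_submitter=str(r.any_plp_submitter).strip() in ("1", "true", "True"),
        )
        for r in df.itertuples(index=False)
    ]


def read_decisions(path: str | Path) -> list[CurationDecision]:
    """Read a curation-decision table (contig, pos, ref, alt, final_class, acmg_criteria)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CurationDecision(
            contig=r.contig,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            final_class=r.final_class.strip(),
            acmg_criteria=getattr(r, "acmg_criteria", ""),
        )
        for r in df.itertuples(index=False)
    ]


def read_genotype_calls(
    vcf_path: str | Path,
    variants: Iterable[VariantRecord],
    samples: Sequence[str] | None = None,
) -> dict[VariantKey, list[GenotypeCall]]:
    """Extract per-sample calls for the given catalogue variants from a VCF.

    Multi-allelic sites are decomposed into biallelic records; matching is
    exact on (contig, pos, ref, alt). FORMAT fields GT and DP are required;
    a missing genotype is "./." (phased separators accepted) and carries no
    allele count. Haploid alt calls are recorded as hemizygous.
    """
    wanted: dict[VariantKey, VariantRecord] = {v.key: v for v in variants}
    vcf = VCF(str(vcf_path), gts012=False)
    if samples is not None:
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)
    calls: dict[VariantKey, list[GenotypeCall]] = {}
    for rec in vcf:
        depths = rec.format("DP")
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            key = (rec.CHROM, rec.POS, rec.REF, alt)
            variant = wanted.get(key)
            if variant is None:
                continue
            row: list[GenotypeCall] = []
            for s_idx, sid in enumerate(sample_ids):
                gt = rec.genotypes[s_idx]
                alleles = [a for a in gt[:-1] if a is not None]
                depth = int(depths[s_idx][0]) if depths is not None else 0
                if depth < 0:
                    depth = 0
                if not alleles or any(a < 0 for a in alleles):
                    geno = "missing"
                elif len(alleles) == 1:
                    geno = "hemi_alt" if alleles[0] == alt_idx else "hom_ref"
                else:
                    dose = sum(1 for a in alleles if a == alt_idx)
                    geno = ("hom_ref", "het", "hom_alt")[dose]
                row.append(GenotypeCall(sid, variant, geno, depth))
            calls[key] = row
    vcf.close()
    return calls


# ---------------------------------------------------------------------------
# Screening operations


def preselect_variants(
    catalogue: Iterable[VariantRecord],
    panel_genes: Iterable[str],
    skipped_log: list[str] | None = None,
) -> list[VariantRecord]:
    """Keep catalogue records in panel genes with a P/LP-supporting class.

    A record survives when its gene is on the retained panel and its aggregate
    class is P, LP, or conflicting with at least one P/LP submitter. Records
    mapped to off-panel genes are skipped with a log entry.
    """
    genes = set(panel_genes)
    kept: list[VariantRecord] = []
    for v in catalogue:
        if v.gene_symbol not in genes:
            if skipped_log is not None:
                skipped_log.append(
                    f"{v.contig}:{v.pos}:{v.ref}>{v.alt} gene {v.gene_symbol} not on panel"
                )
            continue
        if v.aggregate_class in ("P", "LP") or (
            v.aggregate_class == "conflicting" and v.any_plp_submitter
        ):
            kept.append(v)
    return kept


def apply_call_qc(
    calls: dict[VariantKey, list[GenotypeCall]],
    min_depth: int = 20,
    min_call_rate: float = 0.95,
    n_samples: int | None = None,
) -> tuple[dict[VariantKey, list[GenotypeCall]], list[VariantKey]]:
    """Mask low-depth calls and drop low-call-rate variants.

    Calls with depth < ``min_depth`` are set to missing. A variant whose
    non-missing genotype fraction over ``n_samples`` is below ``min_call_rate``
    is dropped entirely (boundary kept at >=). ``n_samples`` defaults to the
    number of calls per variant, i.e. the screened sample set.
    """
    if n_samples is not None and n_samples <= 0:
        raise ScreenError(f"n_samples must be positive, got {n_samples}")
    retained: dict[VariantKey, list[GenotypeCall]] = {}
    dropped: list[VariantKey] = []
    for key, row in calls.items():
        denom = n_samples if n_samples is not None else len(row)
        if denom <= 0:
            raise ScreenError("empty call set with no n_samples given")
        masked = [
            replace(c, genotype="missing") if c.depth < min_depth else c for c in row
        ]
        n_called = sum(1 for c in masked if c.genotype != "missing")
        if denom and n_called / denom < min_call_rate:
            dropped.append(key)
        else:
            retained[key] = masked
    return retained, dropped


def apply_curation(
    preselected: Iterable[VariantRecord],
    decisions: Iterable[CurationDecision],
) -> list[VariantRecord]:
    """Keep only variants whose final curated ACMG class is P or LP.

    Every preselected variant must have a decision; a missing one is an error
    naming the variant, forcing explicit curation.
    """
    by_key: dict[VariantKey, CurationDecision] = {}
    for d in decisions:
        if d.key in by_key:
            raise ScreenError(f"duplicate curation decision for {d.key}")
        by_key[d.key] = d
    kept = []
    for v in preselected:
        d = by_key.get(v.key)
        if d is None:
            raise ScreenError(
                f"no curation decision for {v.contig}:{v.pos}:{v.ref}>{v.alt} ({v.gene_symbol})"
            )
        if d.final_class in ("P", "LP"):
            kept.append(v)
    return kept


def final_classes(
    variants: Iterable[VariantRecord], decisions: Iterable[CurationDecision]
) -> dict[VariantKey, str]:
    """Map each variant key to its curated final class."""
    by_key = {d.key: d.final_class for d in decisions}
    return {v.key: by_key[v.key] for v in variants}


def screen_mito(
    calls: Iterable[GenotypeCall], mito_list: Iterable[VariantRecord]
) -> list[GenotypeCall]:
    """Return calls exactly matching the mitochondrial lookup list.

    Only chrM variants already associated with hearing loss are searched; the
    match is exact on (position, ref, alt). Calls without an alternate allele
    do not count as detections.
    """
    keys = {(v.pos, v.ref, v.alt) for v in mito_list}
    return [
        c
        for c in calls
        if (c.variant.pos, c.variant.ref, c.variant.alt) in keys and c.alt_alleles > 0
    ]
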