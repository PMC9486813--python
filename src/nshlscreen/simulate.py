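"""Synthetic cohort generation.

Builds complete, self-consistent input bundles for the screening pipeline —
multi-sample VCF, CNV/SV table, ROH segments, phenotype and sample-QC tables,
variant catalogue, curation decisions, gene panel, exon and syndromic-region
maps, mitochondrial lookup list and reference-cohort counts — with exact,
seeded planting of carriers so every pipeline stage is testable without any
external download.

Two kinds of configuration are supported: arbitrary small cohorts for
property tests (every planted carrier count is recovered exactly by the
pipeline, and every decoy is removed by exactly one named filter), and a
frozen study-scale configuration (:func:`paper_fixture`) encoding a 2,199-
sample cohort: 13 QC failures, 89 hearing-loss-affected individuals, 89
retained P/LP sequence variants carried by 222 heterozygotes and 4
homozygotes, 12 distinct P/LP CNVs in 54 carriers, and decoy sets sized so
the screening funnels read 996 detected -> 118 P/LP-supported -> 89 curated
and 5,285 CNV events -> 232 filtered -> 12 clinically relevant.

The fixture's gene panel and variant lists are a reconstruction: published
cohort studies print only headline variants and per-gene totals, so the
remaining carrier counts are distributed over plausibly named genes to match
the gene-level and cohort-level totals exactly. Coordinates of the planted
CNVs are real genomic coordinates; sequence-variant positions are schematic.
All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .panel import GenePanelEntry, GenomicInterval, write_panel

# ---------------------------------------------------------------------------
# Configuration types


@dataclass
class VariantPlan:
    """One catalogued sequence variant to plant."""

    gene: str
    hgvs_c: str
    hgvs_p: str = ""
    het: int = 0
    hom: int = 0
    aggregate_class: str = "P"  # catalogue class
    any_plp_submitter: bool = True
    final_class: str = "P"  # curated ACMG class
    is_deletion: bool = False  # emit an indel-style REF/ALT pair
    low_depth: bool = False  # all carriers called below the depth floor
    call_rate: float = 1.0  # fraction of samples with non-missing calls
    on_panel: bool = True  # False: gene excluded from panel (skip-log decoy)


@dataclass
class CnvPlan:
    """One distinct CNV to plant (carriers share exact coordinates)."""

    gene: str
    svtype: str = "DEL"
    carriers: int = 1
    final_class: str = "P"
    source: str = "cnv_caller"
    # explicit 1-based inclusive coordinates; 0 means "cover the gene's
    # first exon with a schematic interval"
    contig: str = ""
    start: int = 0
    end: int = 0


@dataclass
class SeqDecoyCounts:
    """Detected-but-never-preselected catalogue variants, by aggregate class."""

    vus: int = 0
    conflicting_noplp: int = 0
    benign: int = 0
    likely_benign: int = 0


@dataclass
class CnvDecoyCounts:
    """CNV events removed by exactly one named filter each."""

    noncoding: int = 0  # intronic/intergenic only -> coding-overlap filter
    oversize: int = 0  # > 1 Mb -> size filter
    syndromic: int = 0  # touches a critical region -> syndromic filter
    hl_sample: int = 0  # carried by an affected individual -> cohort restriction
    vus_events: int = 0  # survive all filters, curated VUS (1 carrier each)
    sv_vus_events: int = 0  # as vus_events but from the SV caller


@dataclass
class RohProfile:
    """Per-consanguinity-class sample counts (remaining samples lack ROH data)."""

    no_evidence: int = 0
    probable_non: int = 0
    probable: int = 0
    evidence: int = 0

    @property
    def total(self) -> int:
        return self.no_evidence + self.probable_non + self.probable + self.evidence


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort bundle."""

    n_individuals: int
    seed: int
    panel_entries: list[GenePanelEntry]
    variants: list[VariantPlan] = field(default_factory=list)
    cnvs: list[CnvPlan] = field(default_factory=list)
    seq_decoys: SeqDecoyCounts = field(default_factory=SeqDecoyCounts)
    cnv_decoys: CnvDecoyCounts = field(default_factory=CnvDecoyCounts)
    n_qc_fail: int = 0
    n_hl_affected: int = 0
    roh_profile: RohProfile | None = None
    #: (gene, hgvs_c, [segment lengths in Mb]) -> fixed ROH for that variant's
    #: first heterozygous carrier
    roh_fixed: list[tuple[str, str, list[float]]] = field(default_factory=list)
    n_report_yes: int = 0
    n_report_no: int = 0
    #: (gene, hgvs_c, ref_alt_count, ref_total_alleles)
    reference_counts: list[tuple[str, str, int, int]] = field(default_factory=list)
    hl_terms: tuple[str, ...] = ()
    mito_list: list[tuple[int, str, str, str]] = field(default_factory=list)
    #: plant carriers among affected individuals instead (tests the exclusion path)
    plant_in_affected: bool = False


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


# ---------------------------------------------------------------------------
# HPO hearing-loss term set (the published 26-entry list; two duplicates)

HL_HPO_TERMS: tuple[str, ...] = (
    "HP:0000365", "HP:0000399", "HP:0000407", "HP:0008527", "HP:0008610",
    "HP:0008619", "HP:0008625", "HP:0011476", "HP:0011474", "HP:0000405",
    "HP:0040119", "HP:0008513", "HP:0012716", "HP:0000408", "HP:0008504",
    "HP:0000410", "HP:0001757", "HP:0008573", "HP:0008598", "HP:0008587",
    "HP:0008596", "HP:0005101", "HP:0000364", "HP:0008615", "HP:0009900",
)

#: chrM variants with established hearing-loss association (lookup list)
MITO_HL_VARIANTS: list[tuple[int, str, str, str]] = [
    (827, "A", "G", "MT-RNR1"),
    (961, "T", "C", "MT-RNR1"),
    (1095, "T", "C", "MT-RNR1"),
    (1494, "C", "T", "MT-RNR1"),
    (1555, "A", "G", "MT-RNR1"),
    (3243, "A", "G", "MT-TL1"),
    (7445, "A", "G", "MT-TS1"),
    (7472, "C", "CC", "MT-TS1"),
    (7510, "T", "C", "MT-TS1"),
    (7511, "T", "C", "MT-TS1"),
]

# ---------------------------------------------------------------------------
# Genome geometry

CONTIG_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrM"]
CONTIG_RANK = {c: i for i, c in enumerate(CONTIG_ORDER)}
CONTIG_LEN = 250_000_000

SYNDROMIC_REGIONS: list[tuple[str, int, int, str]] = [
    # (contig, start0, end0, label) — BED convention
    ("chr7", 72_000_000, 74_000_000, "7q11.23_williams_beuren"),
    ("chr15", 30_500_000, 32_500_000, "15q13.3_microdeletion"),
    ("chr22", 18_500_000, 21_500_000, "22q11.2_digeorge"),
]

#: Non-panel genes whose exons sit inside syndromic regions, so syndromic
#: decoy CNVs still pass the coding-overlap filter.
_SYNDROMIC_GENE_EXONS = [
    ("chr7", 72_500_000, "ELN"),
    ("chr15", 31_000_000, "CHRNA7"),
    ("chr22", 19_700_000, "TBX1"),
]

_EXON_LEN = 150


def _exon_run(nums, start1: int, step: int) -> list[tuple[int, int, int]]:
    """(start1, end1, exon_number) rows spaced ``step`` apart."""
    return [(start1 + i * step, start1 + i * step + _EXON_LEN - 1, k)
            for i, k in enumerate(nums)]


def _fixed_gene_exons() -> dict[str, tuple[str, list[tuple[int, int, int]]]]:
    """Hand-laid exon structures for the genes with real CNV coordinates.

    Numbering follows each gene's transcript direction (minus-strand genes
    number exons against the coordinate direction), chosen so the planted
    CNVs overlap exactly the reported exon ranges.
    """
    g: dict[str, tuple[str, list[tuple[int, int, int]]]] = {}
    # STRC, minus strand, 29 exons; recurrent del chr15:43600849-43658715
    # covers exons 1-26, the non-recurrent del chr15:43557296-43603898
    # covers exons 22-29.
    strc = _exon_run(range(1, 22), 43_658_000, -2_600)
    strc += _exon_run(range(22, 27), 43_603_800, -600)
    strc += _exon_run(range(27, 30), 43_600_000, -20_000)
    g["STRC"] = ("chr15", strc)
    # OTOA, plus strand, 28 exons all inside the 244.2 kb deletion.
    g["OTOA"] = ("chr16", _exon_run(range(1, 29), 21_700_000, 2_500))
    g["ABCC1"] = ("chr16", _exon_run(range(1, 11), 15_950_000, 15_000))
    # NARS2, minus strand, 14 exons; del chr11:78476555-78486991 covers 7-10.
    nars2 = _exon_run(range(1, 7), 78_520_000, -4_000)
    nars2 += _exon_run(range(7, 11), 78_486_000, -2_400)
    nars2 += _exon_run(range(11, 15), 78_474_000, -4_000)
    g["NARS2"] = ("chr11", nars2)
    g["GRAP"] = ("chr17", _exon_run(range(1, 6), 18_700_000, 10_000))
    # DMXL2, minus strand, 43 exons; del covers 36-43.
    dmxl2 = _exon_run(range(1, 36), 51_600_000, -4_000)
    dmxl2 += _exon_run(range(36, 44), 51_456_500, -2_400)
    g["DMXL2"] = ("chr15", dmxl2)
    # GSDME, minus strand, 10 exons; del covers 3-8.
    gsdme = _exon_run(range(1, 3), 24_730_000, -4_000)
    gsdme += _exon_run(range(3, 9), 24_719_500, -2_800)
    gsdme += _exon_run(range(9, 11), 24_700_000, -4_000)
    g["GSDME"] = ("chr7", gsdme)
    # OTOG, plus strand, 55 exons; del covers 33-38.
    otog = _exon_run(range(1, 33), 17_540_000, 1_800)
    otog += _exon_run(range(33, 39), 17_603_500, 1_500)
    otog += _exon_run(range(39, 56), 17_615_000, 1_800)
    g["OTOG"] = ("chr11", otog)
    # OTOGL, plus strand, 58 exons; dup covers exon 27.
    otogl = _exon_run(range(1, 27), 80_200_000, 3_000)
    otogl += [(80_293_000, 80_293_000 + _EXON_LEN - 1, 27)]
    otogl += _exon_run(range(28, 59), 80_302_000, 3_000)
    g["OTOGL"] = ("chr12", otogl)
    # TRIOBP, plus strand, 24 exons; del covers exon 5.
    triobp = _exon_run(range(1, 5), 37_700_000, 3_000)
    triobp += [(37_725_000, 37_725_000 + _EXON_LEN - 1, 5)]
    triobp += _exon_run(range(6, 25), 37_735_000, 2_000)
    g["TRIOBP"] = ("chr22", triobp)
    # TECTA, plus strand, 23 exons; del covers 16-19.
    tecta = _exon_run(range(1, 16), 121_100_000, 4_000)
    tecta += _exon_run(range(16, 20), 121_164_000, 2_500)
    tecta += _exon_run(range(20, 24), 121_176_000, 3_000)
    g["TECTA"] = ("chr11", tecta)
    return g


#: Neighbor genes of the planted CNVs; present in the exon map, not the panel.
_NEIGHBOR_GENE_EXONS = [
    ("chr15", 43_620_000, "CATSPER2"),
    ("chr15", 43_570_500, "PPIP5K1"),
    ("chr16", 21_800_000, "METTL9"),
]


class Geometry:
    """Assigns every panel gene an interval and exon layout."""

    def __init__(self, genes: list[str], xl_genes: set[str] | None = None):
        fixed = _fixed_gene_exons()
        xl_genes = xl_genes or set()
        self.exons: dict[str, tuple[str, list[tuple[int, int, int]]]] = {}
        self.intervals: dict[str, GenomicInterval] = {}
        rank = 0
        x_rank = 0
        for gene in genes:
            if gene in fixed:
                contig, exs = fixed[gene]
            else:
                if gene in xl_genes:
                    contig = "chrX"
                    base = 10_000_000 + x_rank * 1_000_000
                    x_rank += 1
                else:
                    contig = f"chr{1 + rank % 6}"
                    base = 10_000_000 + (rank // 6) * 1_000_000
                    rank += 1
                exs = [(base + 1_000, base + 1_000 + _EXON_LEN - 1, 1),
                       (base + 21_000, base + 21_000 + _EXON_LEN - 1, 2)]
            self.exons[gene] = (contig, exs)
            lo = min(s for s, _, _ in exs) - 1_000
            hi = max(e for _, e, _ in exs) + 1_000
            self.intervals[gene] = GenomicInterval(contig, lo, hi)

    def variant_site(self, gene: str, index: int) -> tuple[str, int]:
        """Schematic coding position for the gene's index-th planted variant."""
        contig, exs = self.exons[gene]
        first = min(exs, key=lambda e: e[2])
        return contig, first[0] + 20 + 3 * index

    def decoy_site(self, gene: str, index: int) -> tuple[str, int]:
        contig, exs = self.exons[gene]
        first = min(exs, key=lambda e: e[2])
        return contig, first[0] + 100 + index

    def coding_cnv(self, gene: str) -> tuple[str, int, int]:
        """Schematic interval covering the gene's first exon (1-based incl.)."""
        contig, exs = self.exons[gene]
        first = min(exs, key=lambda e: e[2])
        return contig, first[0] - 400, first[1] + 400

    def intronic_interval(self, gene: str, jitter: int = 0) -> tuple[str, int, int]:
        """Interval strictly between the gene's first two exons (no coding bp)."""
        contig, exs = self.exons[gene]
        by_pos = sorted(exs)
        gap_lo, gap_hi = by_pos[0][1] + 50, by_pos[1][0] - 50
        width = min(500, gap_hi - gap_lo - 1)
        start = gap_lo + (jitter % max(1, gap_hi - gap_lo - width))
        return contig, start, start + width


# ---------------------------------------------------------------------------
# Bundle writing helpers

_SNV_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass
class _Site:
    contig: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    aggregate_class: str
    any_plp: bool
    # genotype plan: sample -> "het"/"hom"
    carriers: dict[str, str] = field(default_factory=dict)
    depth_override: int | None = None
    missing_samples: list[str] = field(default_factory=list)

    @property
    def key(self):
        return (self.contig, self.pos, self.ref, self.alt)


def _alleles(index: int, deletion: bool) -> tuple[str, str]:
    if deletion:
        return "AC", "A"
    return _SNV_CYCLE[index % len(_SNV_CYCLE)]


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a cohort bundle; deterministic given ``config.seed``.

    Returns a dict of logical name -> written path. Raises ConfigError before
    writing anything when the plan is infeasible (more carriers than
    plantable individuals).
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)

    panel_genes = [e.gene_symbol for e in config.panel_entries]
    seen: set[str] = set()
    unique_genes = [g for g in panel_genes if not (g in seen or seen.add(g))]
    mode_sets: dict[str, set[str]] = {}
    excluded_modes: dict[str, set[str]] = {}
    for e in config.panel_entries:
        mode_sets.setdefault(e.gene_symbol, set()).add(e.inheritance_mode)
        if (e.no_valid_transcript or e.non_mendelian
                or e.validity in ("disputed", "refuted")):
            excluded_modes.setdefault(e.gene_symbol, set()).add(e.inheritance_mode)
    # genes surviving the panel filter; decoys cycle over these so that every
    # decoy is removed by its intended filter, not by panel membership
    retained_genes = [
        g for g in unique_genes if mode_sets[g] - excluded_modes.get(g, set())
    ]
    xl_only = {g for g in unique_genes if mode_sets[g] == {"XL"}}
    geometry = Geometry(unique_genes, xl_genes=xl_only)

    n = config.n_individuals
    ids = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- sample roles ------------------------------------------------------
    if config.n_qc_fail + config.n_hl_affected > n:
        raise ConfigError("more QC failures + affected than individuals")
    perm = [ids[i] for i in rng.permutation(n)]
    qc_fail = sorted(perm[: config.n_qc_fail])
    passing = [s for s in ids if s not in set(qc_fail)]
    perm_pass = [passing[i] for i in rng.permutation(len(passing))]
    affected = sorted(perm_pass[: config.n_hl_affected])
    unaffected = [s for s in passing if s not in set(affected)]

    plant_pool_src = affected if config.plant_in_affected else unaffected
    plant_pool = [plant_pool_src[i] for i in rng.permutation(len(plant_pool_src))]
    needed = sum(v.het + v.hom for v in config.variants if not v.low_depth) + sum(
        c.carriers for c in config.cnvs
    ) + sum(v.het + v.hom for v in config.variants if v.low_depth)
    if needed > len(plant_pool):
        raise ConfigError(
            f"{needed} planted carriers exceed {len(plant_pool)} plantable individuals"
        )
    pool_iter = iter(plant_pool)

    # --- sequence variant sites -------------------------------------------
    sites: list[_Site] = []
    per_gene_index: dict[str, int] = {}
    variant_site_of: dict[tuple[str, str], _Site] = {}
    for i, plan in enumerate(config.variants):
        idx = per_gene_index.get(plan.gene, 0)
        per_gene_index[plan.gene] = idx + 1
        contig, pos = geometry.variant_site(plan.gene, idx)
        ref, alt = _alleles(i, plan.is_deletion)
        site = _Site(
            contig, pos, ref, alt, plan.gene, plan.hgvs_c, plan.hgvs_p,
            plan.aggregate_class, plan.any_plp_submitter,
        )
        for _ in range(plan.hom):
            site.carriers[next(pool_iter)] = "hom"
        for _ in range(plan.het):
            site.carriers[next(pool_iter)] = "het"
        if plan.low_depth:
            site.depth_override = 10
        if plan.call_rate < 1.0:
            n_missing = math.ceil((1.0 - plan.call_rate) * len(passing))
            others = [s for s in passing if s not in site.carriers]
            pick = rng.permutation(len(others))[:n_missing]
            site.missing_samples = [others[j] for j in pick]
        sites.append(site)
        variant_site_of[(plan.gene, plan.hgvs_c)] = site

    # --- detected decoy catalogue variants --------------------------------
    decoy_specs = (
        [("VUS", False)] * config.seq_decoys.vus
        + [("conflicting", False)] * config.seq_decoys.conflicting_noplp
        + [("B", False)] * config.seq_decoys.benign
        + [("LB", False)] * config.seq_decoys.likely_benign
    )
    decoy_gene_index: dict[str, int] = {}
    for j, (agg, plp) in enumerate(decoy_specs):
        gene = retained_genes[j % len(retained_genes)]
        d = decoy_gene_index.get(gene, 0)
        decoy_gene_index[gene] = d + 1
        contig, pos = geometry.decoy_site(gene, d)
        ref, alt = _alleles(j, False)
        site = _Site(contig, pos, ref, alt, gene, f"c.{1000 + j}A>G", "",
                     agg, plp)
        carrier = passing[int(rng.integers(len(passing)))]
        site.carriers[carrier] = "het"
        sites.append(site)

    sites.sort(key=lambda s: (CONTIG_RANK.get(s.contig, 99), s.pos, s.ref, s.alt))

    # --- VCF ---------------------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in CONTIG_ORDER:
            fh.write(f"##contig=<ID={c},length={CONTIG_LEN}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        gt_of = {"het": "0/1", "hom": "1/1"}
        for site in sites:
            depth = site.depth_override if site.depth_override is not None else 35
            default = "0/0:35"
            row = [default] * n
            index_of = {s: k for k, s in enumerate(ids)}
            for sample, kind in site.carriers.items():
                row[index_of[sample]] = f"{gt_of[kind]}:{depth}"
            for sample in site.missing_samples:
                row[index_of[sample]] = "./.:0"
            fh.write(
                f"{site.contig}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t100\tPASS\t.\tGT:DP\t"
                + "\t".join(row) + "\n"
            )

    # --- catalogue + curation decisions ------------------------------------
    cat_path = out / "catalogue.tsv"
    with open(cat_path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tgene_symbol\thgvs_c\thgvs_p\t"
                 "aggregate_class\tany_plp_submitter\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.gene}\t{s.hgvs_c}\t"
                     f"{s.hgvs_p}\t{s.aggregate_class}\t{int(s.any_plp)}\n")

    dec_path = out / "decisions.tsv"
    with open(dec_path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tfinal_class\tacmg_criteria\n")
        for plan in config.variants:
            s = variant_site_of[(plan.gene, plan.hgvs_c)]
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{plan.final_class}\t\n")

    # --- CNV events ---------------------------------------------------------
    cnv_rows: list[tuple[str, str, int, int, str, str]] = []
    cnv_decisions: list[tuple[str, int, int, str, str]] = []
    for plan in config.cnvs:
        if plan.start:
            contig, start, end = plan.contig, plan.start, plan.end
        else:
            contig, start, end = geometry.coding_cnv(plan.gene)
        for _ in range(plan.carriers):
            cnv_rows.append((next(pool_iter), contig, start, end, plan.svtype,
                             plan.source))
        cnv_decisions.append((contig, start, end, plan.svtype, plan.final_class))

    dd = config.cnv_decoys
    for j in range(dd.vus_events + dd.sv_vus_events):
        gene = retained_genes[j % len(retained_genes)]
        contig, start, end = geometry.coding_cnv(gene)
        start, end = start - 20 - 2 * j // len(unique_genes), end + (j % 7)
        source = "sv_caller" if j >= dd.vus_events else "cnv_caller"
        carrier = unaffected[int(rng.integers(len(unaffected)))]
        cnv_rows.append((carrier, contig, start, end, "DUP", source))
        cnv_decisions.append((contig, start, end, "DUP", "VUS"))
    for j in range(dd.noncoding):
        gene = retained_genes[j % len(retained_genes)]
        contig, start, end = geometry.intronic_interval(gene, jitter=j)
        carrier = unaffected[int(rng.integers(len(unaffected)))]
        cnv_rows.append((carrier, contig, start, end, "DEL", "cnv_caller"))
    for j in range(dd.oversize):
        gene = retained_genes[j % len(retained_genes)]
        contig, start, end = geometry.coding_cnv(gene)
        carrier = unaffected[int(rng.integers(len(unaffected)))]
        cnv_rows.append((carrier, contig, start - 1, start + 1_200_000 + j,
                         "DEL", "cnv_caller"))
    for j in range(dd.syndromic):
        contig, base, _ = _SYNDROMIC_GENE_EXONS[j % len(_SYNDROMIC_GENE_EXONS)]
        carrier = unaffected[int(rng.integers(len(unaffected)))]
        cnv_rows.append((carrier, contig, base - 5_000 - j, base + 5_000,
                         "DEL", "cnv_caller"))
    if dd.hl_sample and not affected:
        raise ConfigError("hl_sample CNV decoys require affected individuals")
    for j in range(dd.hl_sample):
        gene = retained_genes[j % len(retained_genes)]
        contig, start, end = geometry.coding_cnv(gene)
        carrier = affected[int(rng.integers(len(affected)))]
        cnv_rows.append((carrier, contig, start - 10, end + 10 + j,
                         "DEL", "cnv_caller"))

    cnv_path = out / "cnv.tsv"
    with open(cnv_path, "w") as fh:
        fh.write("sample_id\tcontig\tstart_1based\tend_1based\tsvtype\tsource\n")
        for sample, contig, start, end, svtype, source in cnv_rows:
            fh.write(f"{sample}\t{contig}\t{start}\t{end}\t{svtype}\t{source}\n")

    cnv_dec_path = out / "cnv_decisions.tsv"
    with open(cnv_dec_path, "w") as fh:
        fh.write("contig\tstart_1based\tend_1based\tsvtype\tfinal_class\n")
        for contig, start, end, svtype, cls in cnv_decisions:
            fh.write(f"{contig}\t{start}\t{end}\t{svtype}\t{cls}\n")

    # --- panel + region maps ------------------------------------------------
    panel_path = out / "panel.tsv"
    entries = []
    for e in config.panel_entries:
        interval = e.interval or geometry.intervals[e.gene_symbol]
        entries.append(GenePanelEntry(
            gene_symbol=e.gene_symbol, inheritance_mode=e.inheritance_mode,
            validity=e.validity, onset=e.onset, hl_type=e.hl_type,
            severity=e.severity, progression=e.progression,
            frequency_band=e.frequency_band, transcript_id=e.transcript_id,
            interval=interval, no_valid_transcript=e.no_valid_transcript,
            non_mendelian=e.non_mendelian,
        ))
    write_panel(entries, panel_path)

    exon_path = out / "exons.bed"
    with open(exon_path, "w") as fh:
        rows = []
        for gene in unique_genes:
            contig, exs = geometry.exons[gene]
            for s1, e1, k in exs:
                rows.append((contig, s1 - 1, e1, f"{gene}|{k}"))
        for contig, base, gene in _SYNDROMIC_GENE_EXONS + _NEIGHBOR_GENE_EXONS:
            for k in (1, 2):
                s1 = base + (k - 1) * 2_000
                rows.append((contig, s1 - 1, s1 + _EXON_LEN - 1, f"{gene}|{k}"))
        rows.sort(key=lambda r: (CONTIG_RANK.get(r[0], 99), r[1]))
        for contig, s0, e0, label in rows:
            fh.write(f"{contig}\t{s0}\t{e0}\t{label}\n")

    synd_path = out / "syndromic.bed"
    with open(synd_path, "w") as fh:
        for contig, s0, e0, label in SYNDROMIC_REGIONS:
            fh.write(f"{contig}\t{s0}\t{e0}\t{label}\n")

    # --- phenotype and sample QC -------------------------------------------
    pheno_path = out / "phenotype.tsv"
    benign_terms = ("HP:0001250", "HP:0001263", "HP:0004322", "HP:0000750")

    # self-report assignment (set below together with ROH classes)
    report: dict[str, str] = {s: "unknown" for s in ids}

    qc_path = out / "sample_qc.tsv"
    fail_modes = [
        ("autosome_median_coverage", lambda r: 15.0 + 4.0 * r),
        ("autosome_median_coverage", lambda r: 12.0 + 7.0 * r),
        ("autosome_median_coverage", lambda r: 16.0 + 3.9 * r),
        ("mapped_read_pct", lambda r: 96.0 + 1.9 * r),
        ("contamination_pct", lambda r: 2.0 + 3.0 * r),
        ("callability_pct", lambda r: 88.0 + 6.9 * r),
    ]
    with open(qc_path, "w") as fh:
        fh.write("sample_id\tmapped_read_pct\tautosome_median_coverage\t"
                 "uniformity_pct\tcontamination_pct\tcallability_pct\t"
                 "q30_pct\tchimeric_pct\tduplicate_pct\n")
        fail_set = set(qc_fail)
        for i, s in enumerate(ids):
            u = rng.random(8)
            vals = {
                "mapped_read_pct": 98.5 + 1.2 * u[0],
                "autosome_median_coverage": 28.0 + 12.0 * u[1],
                "uniformity_pct": 88.0 + 10.0 * u[2],
                "contamination_pct": 0.1 + 1.0 * u[3],
                "callability_pct": 96.0 + 3.5 * u[4],
                "q30_pct": 91.0 + 6.0 * u[5],
                "chimeric_pct": 0.5 + 2.0 * u[6],
                "duplicate_pct": 3.0 + 4.0 * u[7],
            }
            if s in fail_set:
                metric, gen = fail_modes[qc_fail.index(s) % len(fail_modes)]
                vals[metric] = gen(rng.random())
            fh.write(s + "\t" + "\t".join(f"{vals[k]:.2f}" for k in (
                "mapped_read_pct", "autosome_median_coverage", "uniformity_pct",
                "contamination_pct", "callability_pct", "q30_pct",
                "chimeric_pct", "duplicate_pct")) + "\n")

    # --- ROH segments -------------------------------------------------------
    roh_path = out / "roh.bed"
    hl_terms = config.hl_terms or HL_HPO_TERMS
    class_ranges = {
        "no_evidence": (1.5, 21.5),
        "probable_non": (23.0, 78.0),
        "probable": (79.5, 122.5),
        "evidence": (124.0, 320.0),
    }
    fixed_samples: dict[str, list[float]] = {}
    for gene, hgvs_c, segs in config.roh_fixed:
        site = variant_site_of.get((gene, hgvs_c))
        if site is None:
            raise ConfigError(f"roh_fixed names unplanted variant {gene} {hgvs_c}")
        hets = sorted(s for s, k in site.carriers.items() if k == "het")
        if not hets:
            raise ConfigError(f"roh_fixed variant {gene} {hgvs_c} has no het carrier")
        fixed_samples[hets[0]] = segs

    roh_class_of: dict[str, str] = {}
    with open(roh_path, "w") as fh:
        profile = config.roh_profile or RohProfile()
        if profile.total > len(unaffected):
            raise ConfigError("ROH profile larger than unaffected cohort")
        candidates = [s for s in unaffected if s not in fixed_samples]
        candidates = [candidates[i] for i in rng.permutation(len(candidates))]
        assignment: list[tuple[str, str]] = []
        cursor = 0
        for cls in ("no_evidence", "probable_non", "probable", "evidence"):
            count = getattr(profile, cls)
            if cls == "no_evidence":
                count = max(0, count - len(fixed_samples))
            assignment += [(s, cls) for s in candidates[cursor:cursor + count]]
            cursor += count
        for sample, segs in sorted(fixed_samples.items()):
            for i, mb in enumerate(segs):
                start0 = 5_000_000 + i * 20_000_000
                fh.write(f"chr2\t{start0}\t{start0 + int(mb * 1e6)}\t{sample}\n")
            from .roh import classify_consanguinity
            roh_class_of[sample] = classify_consanguinity(sum(segs))
        for sample, cls in sorted(assignment):
            lo, hi = class_ranges[cls]
            target = lo + (hi - lo) * rng.random()
            remaining = target
            i = 0
            while remaining > 1e-9:
                seg = min(remaining, 2.0 + 6.0 * rng.random())
                if remaining - seg < 1.0 and remaining - seg > 1e-9:
                    seg = remaining  # avoid leaving a sub-1 Mb qualifying tail
                start0 = 5_000_000 + i * 20_000_000
                fh.write(f"chr1\t{start0}\t{start0 + int(seg * 1e6)}\t{sample}\n")
                remaining -= seg
                i += 1
            # one sub-threshold segment that must be ignored by the metrics
            if rng.random() < 0.3:
                fh.write(f"chr3\t1000000\t1500000\t{sample}\n")
            roh_class_of[sample] = cls

    # self-report: concordant for most, with genuine mismatches left in
    with_class = [s for s, c in sorted(roh_class_of.items())]
    high = [s for s in with_class if roh_class_of[s] in ("probable", "evidence")]
    low = [s for s in with_class if s not in set(high)]
    n_yes, n_no = config.n_report_yes, config.n_report_no
    yes_high = min(len(high), int(n_yes * 0.8))
    picks = [high[i] for i in rng.permutation(len(high))]
    yes = picks[:yes_high]
    low_perm = [low[i] for i in rng.permutation(len(low))]
    yes += low_perm[: n_yes - len(yes)]
    rest = [s for s in low_perm if s not in set(yes)] + picks[yes_high:]
    no = rest[:n_no]
    for s in yes:
        report[s] = "yes"
    for s in no:
        report[s] = "no"

    with open(pheno_path, "w") as fh:
        fh.write("sample_id\thpo_terms\tself_report\n")
        affected_set = set(affected)
        isolated = affected[0] if affected else None
        for i, s in enumerate(ids):
            if s in affected_set:
                terms = [hl_terms[i % len(hl_terms)]]
                if s != isolated:
                    terms.append(benign_terms[i % len(benign_terms)])
            else:
                terms = [benign_terms[i % len(benign_terms)]] if i % 3 else []
            fh.write(f"{s}\t{';'.join(terms)}\t{report[s]}\n")

    # --- mito list, reference counts, HL terms ------------------------------
    mito_path = out / "mito_list.tsv"
    with open(mito_path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tgene_symbol\thgvs_c\thgvs_p\t"
                 "aggregate_class\tany_plp_submitter\n")
        for pos, ref, alt, gene in (config.mito_list or MITO_HL_VARIANTS):
            fh.write(f"chrM\t{pos}\t{ref}\t{alt}\t{gene}\tm.{pos}{ref}>{alt}\t\tP\t1\n")

    ref_path = out / "reference_counts.tsv"
    with open(ref_path, "w") as fh:
        fh.write("contig\tpos\tref\talt\talt_allele_count\ttotal_alleles\n")
        for gene, hgvs_c, alt_count, total in config.reference_counts:
            s = variant_site_of.get((gene, hgvs_c))
            if s is None:
                raise ConfigError(f"reference count names unplanted variant {gene} {hgvs_c}")
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{alt_count}\t{total}\n")

    terms_path = out / "hl_terms.txt"
    with open(terms_path, "w") as fh:
        for t in dict.fromkeys(hl_terms):
            fh.write(t + "\n")

    paths = {
        "vcf": vcf_path, "cnv": cnv_path, "roh": roh_path,
        "phenotype": pheno_path, "sample_qc": qc_path,
        "catalogue": cat_path, "decisions": dec_path,
        "cnv_decisions": cnv_dec_path, "panel": panel_path,
        "exons": exon_path, "syndromic": synd_path,
        "reference": ref_path, "mito": mito_path, "hl_terms": terms_path,
    }

    run_cfg = {
        "inputs": {k: str(v.name) for k, v in paths.items()},
        "thresholds": {
            "min_depth": 20, "min_call_rate": 0.95,
            "max_cnv_size_bp": 1_000_000, "alpha": 0.05,
            "autosome_length_mb": 2881.0, "min_roh_len_bp": 1_000_000,
        },
        "seed": config.seed,
    }
    cfg_path = out / "run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    paths["run_config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# The frozen study-scale fixture


def _mk(gene, mode, validity, onset, band, hl_type="sensorineural",
        severity="range", progression="unknown", transcript=""):
    return GenePanelEntry(
        gene_symbol=gene, inheritance_mode=mode, validity=validity,
        onset=onset, hl_type=hl_type, severity=severity,
        progression=progression, frequency_band=band,
        transcript_id=transcript or "NM_900000.1",
    )


_AD_PRELINGUAL = [
    ("CRYM", "all"), ("GREB1L", "all"), ("KITLG", "all"), ("PLS1", "all"),
    ("SIX1", "high"), ("SLC12A2", "high"), ("WFS1", "low"),
]
#: 35 postlingual AD-exclusive genes with their predominant-frequency bands
#: (8 all / 17 high / 4 middle-high / 3 middle / 1 low-middle / 2 low).
_AD_POSTLINGUAL = [
    ("GJB6", "all"), ("KCNQ4", "all"), ("POU4F3", "all"), ("TJP2", "all"),
    ("ABCC1", "all"), ("DMXL2", "all"), ("GSDME", "all"), ("COCH", "all"),
    ("MYH14", "high"), ("MYH9", "high"), ("DIAPH1", "high"), ("ACTG1", "high"),
    ("EYA4", "high"), ("CEACAM16", "high"), ("SLC17A8", "high"),
    ("P2RX2", "high"), ("CCDC50", "high"), ("TNC", "high"), ("OSBPL2", "high"),
    ("HOMER2", "high"), ("NLRP3", "high"), ("MCM2", "high"), ("REST", "high"),
    ("PDE1C", "high"), ("MIR96", "high"),
    ("COL11A1", "middle-high"), ("SLC44A4", "middle-high"),
    ("IFNLR1", "middle-high"), ("TRRAP", "middle-high"),
    ("SCD5", "middle"), ("THOC1", "middle"), ("LMX1A", "middle"),
    ("ATP11A", "low-middle"), ("PLD3", "low"), ("CLDN23", "low"),
]

#: 65 AR-exclusive genes as (gene, band, onset); cell totals match the
#: published inheritance x frequency x onset cross-tabulation.
_AR_GENES = [
    ("STRC", "all", "prelingual"), ("OTOA", "all", "prelingual"),
    ("DCDC2", "all", "prelingual"), ("MPZL2", "high", "prelingual"),
    ("SLC26A4", "high", "prelingual"), ("OTOF", "middle-high", "prelingual"),
    ("TMPRSS3", "unknown", "postlingual"), ("PDZD7", "all", "postlingual"),
    ("GRXCR1", "middle", "prelingual"), ("GRAP", "unknown", "prelingual"),
    ("NARS2", "all", "prelingual"), ("OTOG", "all", "prelingual"),
    ("OTOGL", "all", "prelingual"), ("TRIOBP", "all", "prelingual"),
    ("CDH23", "all", "prelingual"), ("MYO15A", "all", "prelingual"),
    ("LOXHD1", "all", "prelingual"), ("TMIE", "all", "prelingual"),
    ("MARVELD2", "all", "prelingual"), ("CLDN14", "all", "prelingual"),
    ("RDX", "all", "prelingual"), ("ILDR1", "all", "prelingual"),
    ("USH1C", "all", "prelingual"), ("ESPN", "all", "prelingual"),
    ("BSND", "all", "prelingual"), ("WHRN", "all", "prelingual"),
    ("ADGRV1", "all", "prelingual"), ("LHFPL5", "all", "prelingual"),
    ("SERPINB6", "all", "prelingual"), ("GIPC3", "all", "prelingual"),
    ("MYO3A", "all", "prelingual"), ("PCDH15", "all", "prelingual"),
    ("SLC26A5", "all", "prelingual"), ("ESRRB", "all", "prelingual"),
    ("HGF", "all", "prelingual"), ("GRXCR2", "all", "prelingual"),
    ("TPRN", "all", "prelingual"), ("CLIC5", "all", "prelingual"),
    ("CIB2", "all", "prelingual"), ("ELMOD3", "all", "prelingual"),
    ("CABP2", "all", "prelingual"), ("MSRB3", "unknown", "prelingual"),
    ("KARS1", "high", "prelingual"), ("BDP1", "high", "prelingual"),
    ("EPS8", "high", "prelingual"),
    ("EPS8L2", "high", "postlingual"), ("SYNE4", "high", "postlingual"),
    ("ROR1", "high", "postlingual"), ("PJVK", "high", "postlingual"),
    ("RIPOR2", "middle-high", "prelingual"), ("S1PR2", "unknown", "prelingual"),
    ("CLDN9", "middle-high", "postlingual"),
    ("CDC14A", "all", "postlingual"), ("ESRP1", "all", "postlingual"),
    ("GAB1", "unknown", "prelingual"), ("MET", "unknown", "prelingual"),
    ("SPNS2", "unknown", "prelingual"), ("TMEM132E", "unknown", "prelingual"),
    ("CLRN2", "unknown", "prelingual"), ("COL9A1", "unknown", "prelingual"),
    ("COL9A2", "unknown", "prelingual"), ("SLITRK6", "unknown", "prelingual"),
    ("PNPT1", "unknown", "prelingual"), ("SYNJ2", "unknown", "prelingual"),
    ("EPS8L3", "unknown", "postlingual"),
]

#: 8 dual-inheritance genes: (gene, AD (band, onset), AR (band, onset)).
_DUAL_GENES = [
    ("COL11A2", ("middle", "postlingual"), ("all", "prelingual")),
    ("GJB2", ("high", "postlingual"), ("all", "prelingual")),
    ("MYO6", ("high", "postlingual"), ("all", "prelingual")),
    ("MYO7A", ("unknown", "postlingual"), ("all", "prelingual")),
    ("PTPRQ", ("high", "postlingual"), ("all", "prelingual")),
    ("TBC1D24", ("high", "postlingual"), ("all", "prelingual")),
    ("TECTA", ("middle", "prelingual"), ("middle", "prelingual")),
    ("TMC1", ("all", "postlingual"), ("unknown", "prelingual")),
]

_XL_GENES = [
    ("AIFM1", "postlingual"), ("SMPX", "postlingual"),
    ("POU3F4", "prelingual"), ("COL4A6", "prelingual"),
    ("GPRASP2", "prelingual"), ("PRPS1", "prelingual"),
]

_VALIDITY_OVERRIDES = {
    ("GJB2", "AD"): "definitive", ("GJB2", "AR"): "definitive",
    ("STRC", "AR"): "definitive", ("OTOA", "AR"): "definitive",
    ("TMPRSS3", "AR"): "definitive", ("OTOF", "AR"): "definitive",
    ("MYO7A", "AD"): "definitive", ("MYO7A", "AR"): "limited",
    ("SLC26A4", "AR"): "strong", ("MPZL2", "AR"): "strong",
    ("COL11A2", "AD"): "moderate", ("COL11A2", "AR"): "moderate",
    ("PDZD7", "AR"): "definitive", ("GJB6", "AD"): "definitive",
    ("TECTA", "AD"): "definitive", ("TECTA", "AR"): "definitive",
    ("AIFM1", "XL"): "definitive", ("POU3F4", "XL"): "definitive",
    ("SMPX", "XL"): "definitive", ("COL4A6", "XL"): "limited",
    ("GPRASP2", "XL"): "limited", ("PRPS1", "XL"): "limited",
}

_TRANSCRIPTS = {
    "GJB2": "NM_004004.6", "OTOA": "NM_144672.4", "TMPRSS3": "NM_001256317.3",
    "MPZL2": "NM_005797.4", "DCDC2": "NM_016356.5", "TBC1D24": "NM_001199107.2",
    "TJP2": "NM_004817.4", "OTOF": "NM_194248.3",
}

_VALIDITY_CYCLE = ("definitive", "strong", "moderate", "limited")


def paper_panel() -> list[GenePanelEntry]:
    """The 137-association input panel of the frozen fixture.

    129 associations survive filtering (42 AD-exclusive + 65 AR-exclusive +
    6 XL + 16 from the 8 dual-mode genes = 121 unique genes); the other 8
    rows are the excluded associations: four disputed genes, one refuted
    gene, a locus without a known gene, a gene without a valid transcript
    (also disputed), a non-Mendelian modifier, and the refuted AR mode of
    GJB6 (whose AD mode stays).
    """
    entries: list[GenePanelEntry] = []

    def validity(gene, mode, i):
        return _VALIDITY_OVERRIDES.get((gene, mode), _VALIDITY_CYCLE[i % 4])

    i = 0
    for gene, band in _AD_PRELINGUAL:
        entries.append(_mk(gene, "AD", validity(gene, "AD", i), "prelingual",
                           band, progression="progressive",
                           transcript=_TRANSCRIPTS.get(gene)))
        i += 1
    for gene, band in _AD_POSTLINGUAL:
        entries.append(_mk(gene, "AD", validity(gene, "AD", i), "postlingual",
                           band, progression="progressive",
                           transcript=_TRANSCRIPTS.get(gene)))
        i += 1
    for gene, band, onset in _AR_GENES:
        entries.append(_mk(gene, "AR", validity(gene, "AR", i), onset, band,
                           progression="stable",
                           transcript=_TRANSCRIPTS.get(gene)))
        i += 1
    for gene, (ad_band, ad_onset), (ar_band, ar_onset) in _DUAL_GENES:
        entries.append(_mk(gene, "AD", validity(gene, "AD", i), ad_onset,
                           ad_band, progression="progressive",
                           transcript=_TRANSCRIPTS.get(gene)))
        entries.append(_mk(gene, "AR", validity(gene, "AR", i), ar_onset,
                           ar_band, progression="stable",
                           transcript=_TRANSCRIPTS.get(gene)))
        i += 1
    for gene, onset in _XL_GENES:
        entries.append(_mk(gene, "XL", validity(gene, "XL", i), onset, "all",
                           progression="progressive"))
        i += 1

    # excluded associations
    entries.append(_mk("FOXI1", "AR", "disputed", "prelingual", "all"))
    entries.append(_mk("GJB3", "AD", "disputed", "postlingual", "high"))
    kcnj10 = _mk("KCNJ10", "AR", "disputed", "prelingual", "all")
    entries.append(GenePanelEntry(**{**kcnj10.__dict__, "no_valid_transcript": True}))
    entries.append(_mk("TSPEAR", "AR", "disputed", "prelingual", "all"))
    entries.append(_mk("MYO1A", "AD", "refuted", "postlingual", "high"))
    dfnx3 = _mk("DFNX3", "XL", "limited", "prelingual", "all")
    entries.append(GenePanelEntry(**{**dfnx3.__dict__, "no_valid_transcript": True}))
    atp2b2 = _mk("ATP2B2", "AD", "limited", "postlingual", "high")
    entries.append(GenePanelEntry(**{**atp2b2.__dict__, "non_mendelian": True}))
    entries.append(_mk("GJB6", "AR", "refuted", "prelingual", "all"))
    return entries


def _v(gene, hgvs_c, het, hom=0, final="P", hgvs_p="", **kw):
    return VariantPlan(gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, het=het,
                       hom=hom, final_class=final,
                       is_deletion="del" in hgvs_c, **kw)


def paper_variants() -> list[VariantPlan]:
    """The 89 retained P/LP variants (222 het + 4 hom), the 29 variants
    reclassified on curation (28 VUS + 1 LB), the call-QC decoys, and the
    frequent variant in the disputed gene GJB3 that panel filtering removes.

    Headline variants carry their published carrier counts; the rest of each
    gene's published het/hom totals are distributed over schematic variants.
    """
    plp: list[VariantPlan] = []
    # -- top ten genes by heterozygote count (final class P, 44 variants) --
    plp += [
        _v("GJB2", "c.35del", 28, 1, hgvs_p="p.(Gly12fs)"),
        _v("GJB2", "c.109G>A", 23, hgvs_p="p.(Val37Ile)",
           aggregate_class="conflicting", any_plp_submitter=True),
        _v("GJB2", "c.617A>G", 6, hgvs_p="p.(Asn206Ser)"),
        _v("GJB2", "c.167del", 2, hgvs_p="p.(Leu56fs)"),
        _v("GJB2", "c.235del", 1, hgvs_p="p.(Leu79fs)"),
        _v("GJB2", "c.269T>C", 1, hgvs_p="p.(Leu90Pro)"),
        _v("GJB2", "c.101T>C", 1, hgvs_p="p.(Met34Thr)"),
        _v("GJB2", "c.71G>A", 1, hgvs_p="p.(Trp24Ter)"),
        _v("GJB2", "c.250G>T", 1, hgvs_p="p.(Val84Leu)"),
        _v("STRC", "c.4917_4918del", 3, hgvs_p="p.(Cys1640fs)"),
        _v("OTOA", "c.2359G>T", 25, hgvs_p="p.(Glu787Ter)"),
        _v("TMPRSS3", "c.1273G>A", 13, hgvs_p="p.(Ala425Thr)"),
        _v("TMPRSS3", "c.208del", 2, hgvs_p="p.(His70fs)"),
        _v("TMPRSS3", "c.323-6G>A", 1),
        _v("TMPRSS3", "c.916G>A", 1, hgvs_p="p.(Ala306Thr)"),
        _v("OTOF", "c.2485C>T", 6, hgvs_p="p.(Gln829Ter)"),
        _v("OTOF", "c.2122C>T", 1, hgvs_p="p.(Arg708Ter)"),
        _v("OTOF", "c.5317C>T", 1, hgvs_p="p.(Arg1773Trp)"),
        _v("OTOF", "c.4799T>C", 1, hgvs_p="p.(Ile1600Thr)"),
        _v("OTOF", "c.1469C>A", 1, hgvs_p="p.(Pro490Gln)"),
        _v("OTOF", "c.4227+1G>T", 1),
        _v("OTOF", "c.3032T>C", 1, hgvs_p="p.(Leu1011Pro)"),
        _v("MYO7A", "c.6025del", 3, hgvs_p="p.(Ala2009fs)"),
        _v("MYO7A", "c.1996C>T", 1, hgvs_p="p.(Arg666Ter)"),
        _v("MYO7A", "c.4953G>A", 1),
        _v("MYO7A", "c.721C>T", 1, hgvs_p="p.(Arg241Cys)"),
        _v("MYO7A", "c.3719G>A", 1, hgvs_p="p.(Arg1240Gln)"),
        _v("MYO7A", "c.5101C>T", 1, hgvs_p="p.(Arg1701Ter)"),
        _v("MYO7A", "c.470G>A", 1, hgvs_p="p.(Arg157His)"),
        _v("SLC26A4", "c.1001+1G>A", 2),
        _v("SLC26A4", "c.707T>C", 1, hgvs_p="p.(Leu236Pro)"),
        _v("SLC26A4", "c.1246A>C", 1, hgvs_p="p.(Thr416Pro)"),
        _v("SLC26A4", "c.2168A>G", 1, hgvs_p="p.(His723Arg)"),
        _v("SLC26A4", "c.1334T>G", 1, hgvs_p="p.(Leu445Trp)"),
        _v("SLC26A4", "c.349C>T", 1, hgvs_p="p.(Leu117Phe)"),
        _v("SLC26A4", "c.919-2A>G", 1),
        _v("SLC26A4", "c.2162C>T", 1, hgvs_p="p.(Thr721Met)"),
        _v("MPZL2", "c.72del", 8, hgvs_p="p.(Ile24fs)"),
        _v("COL11A2", "c.966del", 4, hgvs_p="p.(Pro323fs)"),
        _v("COL11A2", "c.4312C>T", 3, hgvs_p="p.(Arg1438Ter)"),
        _v("PDZD7", "c.2107del", 4, hgvs_p="p.(Ser703fs)"),
        _v("PDZD7", "c.166dup", 1, hgvs_p="p.(Cys56fs)"),
        _v("PDZD7", "c.1648C>T", 1, hgvs_p="p.(Arg550Ter)"),
        _v("PDZD7", "c.490C>T", 1, hgvs_p="p.(Arg164Trp)"),
    ]
    # -- remaining dual-mode genes (final class LP) --
    plp += [
        _v("TBC1D24", "c.724C>T", 1, 1, "LP", hgvs_p="p.(Arg242Cys)"),
        _v("MYO6", "c.826C>T", 2, final="LP"),
        _v("MYO6", "c.3496C>T", 1, final="LP"),
        _v("PTPRQ", "c.1285C>T", 1, final="LP"),
        _v("PTPRQ", "c.2314C>T", 1, final="LP"),
        _v("TECTA", "c.5383+2T>C", 1, final="LP"),
        _v("TECTA", "c.5509T>G", 1, final="LP"),
        _v("TMC1", "c.100C>T", 1, final="LP"),
    ]
    # -- AD-exclusive genes (10 heterozygotes across 5 genes) --
    plp += [
        _v("GJB6", "c.689A>G", 2, final="LP"),
        _v("KCNQ4", "c.211del", 2, final="LP"),
        _v("KCNQ4", "c.827G>C", 1, final="LP"),
        _v("POU4F3", "c.603del", 2, final="LP"),
        _v("WFS1", "c.2051C>T", 2, final="LP"),
        _v("TJP2", "c.1234C>T", 0, 1, "LP", hgvs_p="p.(Arg412Ter)"),
        _v("TJP2", "c.2002A>G", 1, final="LP"),
    ]
    # -- AR-exclusive genes outside the top ten --
    plp += [
        _v("DCDC2", "c.383C>G", 1, 1, "LP", hgvs_p="p.(Ser128Ter)"),
        _v("CDH23", "c.3481C>T", 2, final="LP"),
        _v("CDH23", "c.6050-9G>A", 1, final="LP"),
        _v("CDH23", "c.719C>T", 1, final="LP"),
        _v("MYO15A", "c.10245_10247del", 2, final="LP"),
        _v("MYO15A", "c.4198G>A", 1, final="LP"),
        _v("MYO15A", "c.6371G>A", 1, final="LP"),
        _v("LOXHD1", "c.4480C>T", 2, final="LP"),
        _v("LOXHD1", "c.2008C>T", 1, final="LP"),
        _v("TMIE", "c.250C>T", 2, final="LP"),
        _v("TMIE", "c.125A>G", 1, final="LP"),
        _v("MARVELD2", "c.1331+2T>C", 2, final="LP"),
        _v("MARVELD2", "c.782G>A", 1, final="LP"),
        _v("CLDN14", "c.254T>A", 2, final="LP"),
        _v("CLDN14", "c.301G>A", 1, final="LP"),
        _v("RDX", "c.1732C>T", 2, final="LP"),
        _v("RDX", "c.463C>T", 1, final="LP"),
        _v("ILDR1", "c.942C>A", 2, final="LP"),
        _v("ILDR1", "c.1228C>T", 1, final="LP"),
        _v("USH1C", "c.216G>A", 1, final="LP"),
        _v("USH1C", "c.496+1G>A", 1, final="LP"),
        _v("ESPN", "c.1757G>A", 1, final="LP"),
        _v("ESPN", "c.2554C>T", 1, final="LP"),
        _v("BSND", "c.3G>A", 1, final="LP"),
        _v("BSND", "c.139G>A", 1, final="LP"),
        _v("WHRN", "c.1267C>T", 1, final="LP"),
        _v("WHRN", "c.2423del", 1, final="LP"),
        _v("ADGRV1", "c.17668C>T", 2, final="LP"),
        _v("LHFPL5", "c.250del", 2, final="LP"),
        _v("SERPINB6", "c.271C>T", 3, final="LP"),
    ]
    # -- reclassified on internal curation: 28 -> VUS, 1 -> LB --
    recl_genes = [
        "COCH", "MYH14", "MYH9", "DIAPH1", "ACTG1", "EYA4", "CEACAM16",
        "SLC17A8", "P2RX2", "CCDC50", "TNC", "OSBPL2", "HOMER2", "NLRP3",
        "MCM2", "REST", "PDE1C", "MIR96", "COCH", "COL11A1", "SLC44A4",
        "IFNLR1", "TRRAP", "SCD5", "THOC1", "LMX1A", "ATP11A", "PLD3",
    ]
    recl = [
        _v(g, f"c.{300 + 7 * i}C>T", 1, final="VUS", aggregate_class="LP")
        for i, g in enumerate(recl_genes)
    ]
    recl.append(_v("GIPC3", "c.903G>A", 1, final="LB", aggregate_class="LP"))
    # -- call-QC decoys (catalogue VUS so they never reach preselection) --
    qc_decoys = [
        _v("CDH23", "c.9001C>T", 1, final="VUS", aggregate_class="VUS",
           any_plp_submitter=False, call_rate=0.90),
        _v("MYO3A", "c.1777C>T", 1, final="VUS", aggregate_class="VUS",
           any_plp_submitter=False, call_rate=0.90),
        _v("PCDH15", "c.400C>T", 1, final="VUS", aggregate_class="VUS",
           any_plp_submitter=False, low_depth=True),
        _v("SLC26A5", "c.209G>A", 1, final="VUS", aggregate_class="VUS",
           any_plp_submitter=False, low_depth=True),
    ]
    # -- frequent variant in a disputed gene, removed with the gene --
    gjb3 = [_v("GJB3", "c.196_198del", 6, hgvs_p="p.(Asp66del)")]
    return plp + recl + qc_decoys + gjb3


def paper_cnvs() -> list[CnvPlan]:
    """The 12 distinct clinically relevant CNVs (54 carriers), at their
    published coordinates (1-based inclusive)."""
    return [
        CnvPlan("STRC", "DEL", 38, "P", contig="chr15",
                start=43_600_849, end=43_658_715),
        CnvPlan("STRC", "DEL", 1, "LP", contig="chr15",
                start=43_557_296, end=43_603_898),
        CnvPlan("OTOA", "DEL", 4, "P", contig="chr16",
                start=21_689_000, end=21_933_155),
        CnvPlan("ABCC1", "DEL", 2, "P", contig="chr16",
                start=15_394_361, end=16_199_828),
        CnvPlan("NARS2", "DEL", 2, "LP", contig="chr11",
                start=78_476_555, end=78_486_991),
        CnvPlan("GRAP", "DEL", 1, "P", contig="chr17",
                start=18_624_545, end=19_025_057),
        CnvPlan("DMXL2", "DEL", 1, "LP", contig="chr15",
                start=51_437_517, end=51_457_141),
        CnvPlan("GSDME", "DEL", 1, "LP", contig="chr7",
                start=24_702_446, end=24_720_157),
        CnvPlan("OTOG", "DEL", 1, "LP", contig="chr11",
                start=17_603_104, end=17_613_104),
        CnvPlan("OTOGL", "DUP", 1, "LP", contig="chr12",
                start=80_288_802, end=80_299_740),
        CnvPlan("TRIOBP", "DEL", 1, "LP", contig="chr22",
                start=37_719_702, end=37_731_543),
        CnvPlan("TECTA", "DEL", 1, "LP", contig="chr11",
                start=121_163_035, end=121_174_624),
    ]


#: Reference-cohort (elderly Brazilian genomes style) allele counts for the
#: 13 variants co-detected with the study cohort; 2,342 = 2 x 1,171 genomes.
#: All counts are frequency-matched except OTOA c.2359G>T, which is planted
#: enriched so exactly one comparison is significant after FDR.
PAPER_REFERENCE_COUNTS: list[tuple[str, str, int, int]] = [
    ("GJB2", "c.35del", 23, 2342),
    ("GJB2", "c.109G>A", 8, 2342),
    ("GJB2", "c.617A>G", 4, 2342),
    ("OTOA", "c.2359G>T", 80, 2342),
    ("TMPRSS3", "c.1273G>A", 7, 2342),
    ("MPZL2", "c.72del", 4, 2342),
    ("OTOF", "c.2122C>T", 1, 2342),
    ("OTOF", "c.2485C>T", 3, 2342),
    ("SLC26A4", "c.1001+1G>A", 1, 2342),
    ("MYO7A", "c.6025del", 2, 2342),
    ("PDZD7", "c.2107del", 2, 2342),
    ("CDH23", "c.3481C>T", 1, 2342),
    ("DCDC2", "c.383C>G", 2, 2342),
]


def paper_fixture(seed: int = 20220830) -> CohortConfig:
    """The frozen study-scale configuration.

    2,199 individuals: 13 QC failures and 89 hearing-loss-affected leave a
    2,097-strong unaffected cohort; planted carriers and decoy sets reproduce
    every published funnel count and carrier tally end to end.
    """
    return CohortConfig(
        n_individuals=2_199,
        seed=seed,
        panel_entries=paper_panel(),
        variants=paper_variants(),
        cnvs=paper_cnvs(),
        seq_decoys=SeqDecoyCounts(
            vus=400, conflicting_noplp=278, benign=100, likely_benign=100
        ),
        cnv_decoys=CnvDecoyCounts(
            noncoding=3_500, oversize=400, syndromic=311, hl_sample=800,
            vus_events=201, sv_vus_events=19,
        ),
        n_qc_fail=13,
        n_hl_affected=89,
        roh_profile=RohProfile(
            no_evidence=1_548, probable_non=300, probable=121, evidence=100
        ),
        roh_fixed=[("OTOF", "c.2122C>T", [3.0, 4.0])],
        n_report_yes=191,
        n_report_no=1_424,
        reference_counts=PAPER_REFERENCE_COUNTS,
        hl_terms=HL_HPO_TERMS,
        mito_list=MITO_HL_VARIANTS,
    )


def small_config(
    seed: int,
    n_individuals: int = 60,
    n_qc_fail: int = 2,
    n_hl_affected: int = 4,
    variants: list[VariantPlan] | None = None,
    cnvs: list[CnvPlan] | None = None,
    **overrides,
) -> CohortConfig:
    """A compact four-gene cohort for unit and property tests.

    Genes: DFNB1A (AR), DFNA9X (AD), DFNMIX (AD+AR), DFNXL (XL) plus an
    excluded disputed gene DFNBAD.
    """
    panel = [
        _mk("DFNB1A", "AR", "definitive", "prelingual", "all"),
        _mk("DFNA9X", "AD", "strong", "postlingual", "high"),
        _mk("DFNMIX", "AD", "moderate", "postlingual", "high"),
        _mk("DFNMIX", "AR", "definitive", "prelingual", "all"),
        _mk("DFNXL", "XL", "limited", "prelingual", "all"),
        _mk("DFNBAD", "AR", "disputed", "prelingual", "all"),
    ]
    if variants is None:
        variants = [
            _v("DFNB1A", "c.35del", 4, 1),
            _v("DFNMIX", "c.100C>T", 3, final="LP"),
            _v("DFNA9X", "c.7G>A", 2, final="LP"),
            _v("DFNB1A", "c.200G>A", 1, final="VUS"),
        ]
    if cnvs is None:
        cnvs = [CnvPlan("DFNB1A", "DEL", 3, "P"),
                CnvPlan("DFNMIX", "DUP", 2, "LP", source="sv_caller")]
    cfg = CohortConfig(
        n_individuals=n_individuals,
        seed=seed,
        panel_entries=panel,
        variants=variants,
        cnvs=cnvs,
        seq_decoys=SeqDecoyCounts(vus=3, conflicting_noplp=2, benign=2,
                                  likely_benign=1),
        cnv_decoys=CnvDecoyCounts(noncoding=3, oversize=2, syndromic=2,
                                  hl_sample=2, vus_events=3, sv_vus_events=1),
        n_qc_fail=n_qc_fail,
        n_hl_affected=n_hl_affected,
        roh_profile=RohProfile(no_evidence=20, probable_non=5, probable=3,
                               evidence=2),
        n_report_yes=6,
        n_report_no=20,
        reference_counts=[("DFNB1A", "c.35del", 3, 200)],
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    planted = {(v.gene, v.hgvs_c) for v in cfg.variants}
    cfg.reference_counts = [
        r for r in cfg.reference_counts if (r[0], r[1]) in planted
    ]
    return cfg
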