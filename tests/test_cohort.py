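"""Sample QC, phenotype exclusion and carrier statistics."""

import numpy as np
import pytest

from nshlscreen.cohort import (
    CohortError,
    Individual,
    VariantCounts,
    ad_implicated,
    af_percent,
    allele_frequency,
    classify_carriers,
    count_genotypes,
    gene_combined_summary,
    phenotype_exclude,
    round_half_up,
    sample_qc_filter,
)
from nshlscreen.simulate import paper_panel
from nshlscreen.panel import filter_panel
from nshlscreen.variants import GenotypeCall, VariantRecord

GOOD_QC = {
    "mapped_read_pct": 99.0, "autosome_median_coverage": 30.0,
    "uniformity_pct": 90.0, "contamination_pct": 0.5,
    "callability_pct": 98.0, "q30_pct": 93.0, "chimeric_pct": 1.0,
    "duplicate_pct": 5.0,
}


def _ind(sid="S1", terms=(), **qc_overrides):
    qc = dict(GOOD_QC)
    qc.update(qc_overrides)
    return Individual(sid, frozenset(terms), qc)


@pytest.mark.parametrize(
    "override, passes",
    [
        ({}, True),
        ({"autosome_median_coverage": 20.0}, True),   # inclusive >=
        ({"autosome_median_coverage": 19.99}, False),
        ({"mapped_read_pct": 98.0}, False),           # strict >
        ({"mapped_read_pct": 98.01}, True),
        ({"contamination_pct": 2.0}, False),          # strict <
        ({"callability_pct": 95.0}, True),
        ({"q30_pct": 89.9}, False),
        ({"chimeric_pct": 5.0}, False),
        ({"duplicate_pct": 10.0}, False),
    ],
)
def test_sample_qc_boundary_semantics(override, passes):
    passing, failing = sample_qc_filter([_ind(**override)])
    assert bool(passing) == passes


def test_sample_qc_missing_metric_is_an_error():
    ind = Individual("S1", frozenset(), {"mapped_read_pct": 99.0})
    with pytest.raises(CohortError, match="missing QC metrics"):
        sample_qc_filter([ind])


def test_phenotype_exclusion_matches_set_scan():
    rng = np.random.default_rng(6)
    hl = {"HP:0000365", "HP:0000407"}
    pool = ["HP:0000365", "HP:0000407", "HP:0001250", "HP:0004322"]
    for _ in range(20):
        inds = [
            _ind(f"S{i}", terms={pool[j] for j in rng.choice(4, rng.integers(0, 4),
                                                             replace=False)})
            for i in range(50)
        ]
        unaffected, affected = phenotype_exclude(inds, hl)
        assert [i.sample_id for i in affected] == [
            i.sample_id for i in inds if i.hpo_terms & hl]
        assert len(unaffected) + len(affected) == 50
    # all-empty term sets -> everyone unaffected
    unaffected, affected = phenotype_exclude([_ind("A"), _ind("B")], hl)
    assert len(unaffected) == 2 and affected == []


def test_genotype_tally_matches_bruteforce():
    rng = np.random.default_rng(7)
    v = VariantRecord("chr1", 100, "A", "G", "GJB2", aggregate_class="P")
    for _ in range(20):
        genos = [["hom_ref", "het", "hom_alt", "missing"][rng.integers(4)]
                 for _ in range(80)]
        calls = [GenotypeCall(f"S{i}", v, g, 30) for i, g in enumerate(genos)]
        cohort = [f"S{i}" for i in range(60)]  # last 20 out of cohort
        c = count_genotypes(calls, cohort)
        assert c.het_count == sum(1 for g in genos[:60] if g == "het")
        assert c.hom_count == sum(1 for g in genos[:60] if g == "hom_alt")
        assert c.n_genotyped == sum(1 for g in genos[:60] if g != "missing")


def test_hemizygous_calls_counted_as_single_alleles():
    v = VariantRecord("chrX", 100, "A", "G", "POU3F4", aggregate_class="P")
    calls = [GenotypeCall("S1", v, "hemi_alt", 30),
             GenotypeCall("S2", v, "het", 30)]
    c = count_genotypes(calls, ["S1", "S2"])
    assert (c.het_count, c.hom_count, c.hemi_count) == (1, 0, 1)
    assert c.allele_count == 2


@pytest.mark.parametrize(
    "het, hom, n, pct",
    [(28, 1, 2097, 0.72), (23, 0, 2097, 0.55), (0, 0, 2097, 0.0),
     (25, 0, 2097, 0.60)],
)
def test_allele_frequency_examples(het, hom, n, pct):
    af = allele_frequency(het, hom, n)
    assert af == (het + 2 * hom) / (2 * n)
    assert af_percent(af) == pct


def test_allele_frequency_requires_genotyped_samples():
    with pytest.raises(CohortError):
        allele_frequency(1, 0, 0)


def test_display_rounding_is_half_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(0.7153, 2) == 0.72
    assert round_half_up(2.5, 0) == 3.0


def test_gene_summary_aggregates_alleles_by_mechanism():
    counts = {
        "gjb2_a": VariantCounts(64, 1, 2097),
        "strc_seq": VariantCounts(3, 0, 2097),
        "strc_cnv": VariantCounts(39, 0, 2097),
    }
    genes = {"gjb2_a": "GJB2", "strc_seq": "STRC", "strc_cnv": "STRC"}
    mech = {"gjb2_a": "sequence", "strc_seq": "sequence", "strc_cnv": "cnv"}
    df = gene_combined_summary(counts, genes, mech, 2097)
    strc = df[(df.gene_symbol == "STRC") & (df.mechanism == "combined")].iloc[0]
    assert strc.allele_count == 42
    assert af_percent(strc.combined_af) == 1.0
    gjb2 = df[(df.gene_symbol == "GJB2") & (df.mechanism == "combined")].iloc[0]
    assert gjb2.allele_count == 66
    assert af_percent(gjb2.combined_af) == 1.57
    # empty mechanism rows are zero-filled
    gjb2_cnv = df[(df.gene_symbol == "GJB2") & (df.mechanism == "cnv")].iloc[0]
    assert gjb2_cnv.allele_count == 0 and gjb2_cnv.combined_af == 0.0


def test_carrier_classification_precedence_and_partition():
    retained, _ = filter_panel(paper_panel())
    carriers = {
        "S1": ["STRC"],            # AR-exclusive
        "S2": ["GJB2"],            # dual-mode
        "S3": ["GJB6"],            # AD-exclusive
        "S4": ["STRC", "GJB2"],    # precedence: dual beats AR-only
        "S5": ["GJB2", "GJB6"],    # precedence: AD-only beats dual
        "S6": ["POU3F4"],          # XL-only -> none
    }
    assign, tallies = classify_carriers(carriers, retained)
    assert assign == {"S1": "AR_only", "S2": "AD_AR_gene", "S3": "AD_only",
                      "S4": "AD_AR_gene", "S5": "AD_only", "S6": "none"}
    assert sum(tallies.values()) == len(carriers)
    assert ad_implicated(assign) == {"S2", "S3", "S4", "S5"}


def test_carrier_classification_rejects_offpanel_genes():
    retained, _ = filter_panel(paper_panel())
    with pytest.raises(CohortError, match="GJB3"):
        classify_carriers({"S1": ["GJB3"]}, retained)
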