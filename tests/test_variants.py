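"""Sequence-variant preselection, call QC, curation and mito screening."""

import numpy as np
import pytest

from nshlscreen.variants import (
    CurationDecision,
    GenotypeCall,
    ScreenError,
    VariantRecord,
    apply_call_qc,
    apply_curation,
    preselect_variants,
    read_genotype_calls,
    screen_mito,
)

GENES = ["GJB2", "STRC", "OTOF", "NOTPANEL"]
PANEL = {"GJB2", "STRC", "OTOF"}
CLASSES = ["P", "LP", "conflicting", "VUS", "LB", "B"]


def _record(i, gene, agg, plp):
    return VariantRecord("chr1", 100 + i, "A", "G", gene,
                         aggregate_class=agg, any_plp_submitter=plp)


def _random_catalogue(rng, n=200):
    return [
        _record(i, GENES[rng.integers(4)], CLASSES[rng.integers(6)],
                bool(rng.integers(2)))
        for i in range(n)
    ]


def test_preselect_matches_bruteforce_predicate_scan():
    rng = np.random.default_rng(0)
    for _ in range(20):
        catalogue = _random_catalogue(rng)
        got = preselect_variants(catalogue, PANEL)
        expected = [
            v for v in catalogue
            if v.gene_symbol in PANEL and (
                v.aggregate_class in ("P", "LP")
                or (v.aggregate_class == "conflicting" and v.any_plp_submitter))
        ]
        assert got == expected


def test_preselect_drops_benign_only_catalogue_and_logs_offpanel():
    catalogue = [_record(i, "GJB2", c, False) for i, c in enumerate(["B", "LB"])]
    assert preselect_variants(catalogue, PANEL) == []
    log: list[str] = []
    preselect_variants([_record(0, "NOTPANEL", "P", True)], PANEL, log)
    assert len(log) == 1 and "NOTPANEL" in log[0]


def _calls(variant, genotypes, depths):
    return [GenotypeCall(f"S{i}", variant, g, d)
            for i, (g, d) in enumerate(zip(genotypes, depths))]


def test_call_rate_boundary_is_inclusive_at_95_percent():
    v = _record(0, "GJB2", "P", True)
    # 94 of 100 genotyped -> dropped; 95 of 100 -> retained
    for n_called, expect_drop in ((94, True), (95, False)):
        genos = ["het"] * n_called + ["missing"] * (100 - n_called)
        calls = {v.key: _calls(v, genos, [30] * 100)}
        retained, dropped = apply_call_qc(calls, n_samples=100)
        assert (v.key in dropped) == expect_drop


def test_low_depth_calls_masked_and_survivors_match_recount():
    rng = np.random.default_rng(1)
    v = _record(0, "GJB2", "P", True)
    for _ in range(20):
        genos = [["hom_ref", "het", "hom_alt"][rng.integers(3)] for _ in range(60)]
        depths = [int(rng.integers(0, 60)) for _ in range(60)]
        retained, dropped = apply_call_qc(
            {v.key: _calls(v, genos, depths)}, min_depth=20,
            min_call_rate=0.5, n_samples=60)
        n_ok = sum(1 for d in depths if d >= 20)
        if n_ok / 60 < 0.5:
            assert dropped == [v.key]
        else:
            row = retained[v.key]
            assert all(
                (c.genotype == "missing") == (d < 20 or g == "missing")
                for c, g, d in zip(row, genos, depths)
            )


def test_zero_thresholds_make_call_qc_identity():
    v = _record(0, "GJB2", "P", True)
    calls = {v.key: _calls(v, ["het", "hom_ref", "missing"], [0, 5, 0])}
    retained, dropped = apply_call_qc(calls, min_depth=0, min_call_rate=0.0)
    assert dropped == [] and retained == calls


def test_call_qc_rejects_nonpositive_sample_count():
    with pytest.raises(ScreenError):
        apply_call_qc({}, n_samples=0)


def test_curation_keeps_only_final_plp_and_demands_decisions():
    records = [_record(i, "GJB2", "P", True) for i in range(4)]
    decisions = [
        CurationDecision("chr1", r.pos, "A", "G", c)
        for r, c in zip(records, ["P", "LP", "VUS", "LB"])
    ]
    assert apply_curation(records, decisions) == records[:2]
    all_p = [CurationDecision("chr1", r.pos, "A", "G", "P") for r in records]
    assert apply_curation(records, all_p) == records
    with pytest.raises(ScreenError, match="chr1:103"):
        apply_curation(records, decisions[:3])


def test_screen_mito_equals_bruteforce_join():
    rng = np.random.default_rng(2)
    mito = [VariantRecord("chrM", p, "A", "G", "MT-RNR1",
                          aggregate_class="P") for p in (1555, 3243, 7445)]
    for _ in range(20):
        calls = []
        for i in range(30):
            pos = int(rng.choice([1555, 3243, 7445, 999, 1234]))
            v = VariantRecord("chrM", pos, "A", "G", "MT",
                              aggregate_class="P")
            geno = ["hom_ref", "het", "hemi_alt"][rng.integers(3)]
            calls.append(GenotypeCall(f"S{i}", v, geno, 30))
        got = screen_mito(calls, mito)
        keys = {(m.pos, m.ref, m.alt) for m in mito}
        expected = [c for c in calls
                    if (c.variant.pos, c.variant.ref, c.variant.alt) in keys
                    and c.genotype in ("het", "hemi_alt")]
        assert got == expected


def test_screen_mito_empty_without_plantings():
    mito = [VariantRecord("chrM", 1555, "A", "G", "MT-RNR1",
                          aggregate_class="P")]
    ref_call = GenotypeCall(
        "S1", VariantRecord("chrM", 1555, "A", "G", "MT",
                            aggregate_class="P"), "hom_ref", 50)
    assert screen_mito([ref_call], mito) == []


def test_vcf_reading_handles_missing_hemizygous_and_multiallelic(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrX,length=1000000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD\n"
        "chrX\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:30\t./.:0\t1:25\t1|1:40\n"
        "chrX\t200\t.\tC\tT,G\t50\tPASS\t.\tGT:DP\t1/2:30\t0/0:30\t0/2:15\t2/2:22\n"
    )
    wanted = [
        VariantRecord("chrX", 100, "A", "G", "POU3F4", aggregate_class="P"),
        VariantRecord("chrX", 200, "C", "T", "SMPX", aggregate_class="P"),
        VariantRecord("chrX", 200, "C", "G", "SMPX", aggregate_class="P"),
    ]
    calls = read_genotype_calls(vcf, wanted)
    row = calls[("chrX", 100, "A", "G")]
    assert [c.genotype for c in row] == ["het", "missing", "hemi_alt", "hom_alt"]
    assert [c.depth for c in row] == [30, 0, 25, 40]
    # multi-allelic site decomposes into per-allele records
    t_row = calls[("chrX", 200, "C", "T")]
    g_row = calls[("chrX", 200, "C", "G")]
    assert [c.genotype for c in t_row] == ["het", "hom_ref", "hom_ref", "hom_ref"]
    assert [c.genotype for c in g_row] == ["het", "hom_ref", "het", "hom_alt"]


def test_filters_compose_monotonically():
    rng = np.random.default_rng(3)
    catalogue = _random_catalogue(rng, 80)
    pre = preselect_variants(catalogue, PANEL)
    decisions = [CurationDecision("chr1", v.pos, v.ref, v.alt,
                                  ["P", "VUS"][i % 2])
                 for i, v in enumerate(pre)]
    cur = apply_curation(pre, decisions)
    assert set(v.key for v in cur) <= set(v.key for v in pre)
    assert set(v.key for v in pre) <= set(v.key for v in catalogue)
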