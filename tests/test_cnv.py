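"""CNV filtering, annotation, recurrence grouping and curation."""

import numpy as np
import pytest

from nshlscreen.cnv import (
    CnvError,
    CnvEvent,
    RegionMap,
    annotate_cnv_genes,
    apply_cnv_curation,
    coding_overlap_filter,
    distinct_count,
    event_interval0,
    group_recurrent,
    merge_sources,
    syndromic_size_filter,
)


def _exon_map():
    rm = RegionMap()
    rm.add("chr1", 999, 1199, "G1|1")  # 1-based 1000-1199
    rm.add("chr1", 4999, 5199, "G1|2")
    rm.add("chr2", 99, 299, "G2|1")
    return rm


def test_intronic_event_dropped_terminal_base_kept():
    exons = _exon_map()
    intronic = CnvEvent("S1", "chr1", 1300, 4800, "DEL")
    touching = CnvEvent("S1", "chr1", 500, 1000, "DEL")  # shares exactly base 1000
    kept = coding_overlap_filter([intronic, touching], exons)
    assert kept == [touching]


def test_overlap_filter_matches_bruteforce_pairwise_scan():
    rng = np.random.default_rng(4)
    for _ in range(25):
        exons = RegionMap()
        raw = []
        for i in range(rng.integers(1, 15)):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 500))
            exons.add("chr9", s, e, f"G|{i + 1}")
            raw.append((s, e))
        events = []
        for i in range(30):
            s1 = int(rng.integers(1, 10_000))
            events.append(CnvEvent(f"S{i}", "chr9", s1,
                                   s1 + int(rng.integers(0, 800)), "DEL"))
        got = coding_overlap_filter(events, exons)
        expected = [
            ev for ev in events
            if any(max(ev.start - 1, s) < min(ev.end, e) for s, e in raw)
        ]
        assert got == expected


def test_size_boundary_and_syndromic_reason():
    syndromic = RegionMap()
    syndromic.add("chr22", 18_500_000, 21_500_000, "22q11")
    at_limit = CnvEvent("S1", "chr1", 1, 1_000_000, "DEL")  # exactly 1 Mb
    over = CnvEvent("S1", "chr1", 1, 1_000_001, "DEL")
    inside = CnvEvent("S1", "chr22", 19_000_001, 19_000_500, "DEL")
    retained, log = syndromic_size_filter([at_limit, over, inside], syndromic)
    assert retained == [at_limit]
    assert {(e.key, r) for e, r in log} == {
        (over.key, "size"), (inside.key, "syndromic")
    }


def test_coding_and_size_filters_commute():
    rng = np.random.default_rng(5)
    exons = _exon_map()
    syndromic = RegionMap()
    syndromic.add("chr1", 8_000, 9_000, "synd")
    for _ in range(10):
        events = []
        for i in range(40):
            s = int(rng.integers(1, 12_000))
            events.append(CnvEvent(f"S{i}", "chr1", s,
                                   s + int(rng.integers(0, 2_000_000)), "DEL"))
        a, _ = syndromic_size_filter(coding_overlap_filter(events, exons), syndromic)
        b = coding_overlap_filter(
            syndromic_size_filter(events, syndromic)[0], exons)
        assert a == b


def test_published_strc_deletion_size_and_exon_annotation(paper_run):
    bundle, _ = paper_run
    exons = RegionMap.from_bed(bundle / "exons.bed")
    ev = CnvEvent("S1", "chr15", 43_600_849, 43_658_715, "DEL")
    assert ev.size_bp == 57_867  # ~57.9 kb under the inclusive convention
    genes, spans = annotate_cnv_genes(ev, ["STRC", "OTOA"], exons)
    assert genes == ["STRC"]
    assert spans["STRC"] == (1, 26)
    # the non-recurrent deletion hits the other end of the gene
    ev2 = CnvEvent("S1", "chr15", 43_557_296, 43_603_898, "DEL")
    assert annotate_cnv_genes(ev2, ["STRC"], exons)[1]["STRC"] == (22, 29)


def test_large_coding_deletion_retained_when_not_syndromic(paper_run):
    bundle, _ = paper_run
    exons = RegionMap.from_bed(bundle / "exons.bed")
    syndromic = RegionMap.from_bed(bundle / "syndromic.bed")
    ev = CnvEvent("S1", "chr16", 15_394_361, 16_199_828, "DEL")  # 805.5 kb
    assert ev.size_bp == 805_468
    kept = coding_overlap_filter([ev], exons)
    retained, _ = syndromic_size_filter(kept, syndromic)
    assert retained == [ev]


def test_event_with_no_panel_overlap_returns_empty():
    exons = _exon_map()
    ev = CnvEvent("S1", "chr2", 100, 200, "DEL")
    genes, spans = annotate_cnv_genes(ev, ["G1"], exons)  # G2 not on panel
    assert genes == [] and spans == {}


def test_recurrent_grouping_aggregates_identical_coordinates():
    events = [CnvEvent(f"S{i}", "chr15", 43_600_849, 43_658_715, "DEL")
              for i in range(38)]
    events.append(CnvEvent("S99", "chr15", 43_600_849, 43_658_716, "DEL"))
    groups = group_recurrent(events)
    assert len(groups) == 2
    assert len(groups[("chr15", 43_600_849, 43_658_715, "DEL")]) == 38
    assert distinct_count(events) == 2


def test_curation_requires_decisions_and_vus_empties():
    ev = CnvEvent("S1", "chr1", 100, 200, "DEL")
    assert apply_cnv_curation([ev], {ev.key: "VUS"}) == []
    assert apply_cnv_curation([ev], {ev.key: "LP"}) == [ev]
    with pytest.raises(CnvError, match="no curation decision"):
        apply_cnv_curation([ev], {})


def test_merge_prefers_cnv_caller_on_exact_duplicates():
    a = CnvEvent("S1", "chr1", 100, 200, "DEL", source="sv_caller")
    b = CnvEvent("S1", "chr1", 100, 200, "DEL", source="cnv_caller")
    c = CnvEvent("S2", "chr1", 100, 200, "DEL", source="sv_caller")
    merged = merge_sources([a, b, c])
    assert merged == [b, c]  # per-sample dedup, other samples untouched


def test_interval_convention_round_trip():
    ev = CnvEvent("S1", "chr1", 101, 200, "DEL")
    s0, e0 = event_interval0(ev)
    assert (s0, e0) == (100, 200)
    assert e0 - s0 == ev.size_bp == 100
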