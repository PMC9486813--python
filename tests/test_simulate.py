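"""Synthetic-cohort generator: determinism, feasibility, round-trip recovery."""

import filecmp

import pytest
from cyvcf2 import VCF

from nshlscreen.pipeline import RunConfig, run_screen
from nshlscreen.simulate import (
    CnvPlan,
    CohortConfig,
    ConfigError,
    VariantPlan,
    generate_cohort,
    paper_fixture,
    small_config,
)


def _bundle_files(d):
    return sorted(p.name for p in d.iterdir())


def test_same_seed_byte_identical_different_seed_same_counts(tmp_path):
    a = generate_cohort(small_config(seed=3), tmp_path / "a")
    b = generate_cohort(small_config(seed=3), tmp_path / "b")
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), key
    c = generate_cohort(small_config(seed=4), tmp_path / "c")
    assert not filecmp.cmp(a["vcf"], c["vcf"], shallow=False)
    # different seed still recovers the same planted counts
    res_a = run_screen(RunConfig.from_yaml(a["run_config"], tmp_path / "ra"))
    res_c = run_screen(RunConfig.from_yaml(c["run_config"], tmp_path / "rc"))
    assert res_a.summary["carriers"] == res_c.summary["carriers"]
    assert res_a.summary["variants"] == res_c.summary["variants"]


def test_infeasible_config_raises_before_writing(tmp_path):
    cfg = small_config(seed=1, n_individuals=10, n_qc_fail=1, n_hl_affected=1,
                       variants=[VariantPlan("DFNB1A", "c.1A>G", het=20)],
                       cnvs=[])
    out = tmp_path / "x"
    with pytest.raises(ConfigError, match="exceed"):
        generate_cohort(cfg, out)


def test_generated_vcf_is_valid_with_full_genotype_matrix(small_run):
    bundle, _ = small_run
    vcf = VCF(str(bundle / "cohort.vcf"))
    n_samples = len(vcf.samples)
    n_records = sum(1 for _ in vcf)
    assert n_samples == 60
    assert n_records > 0
    vcf2 = VCF(str(bundle / "cohort.vcf"))
    rec = next(iter(vcf2))
    assert len(rec.genotypes) == n_samples


def test_zero_plantings_give_zero_carriers(tmp_path):
    cfg = small_config(seed=5, variants=[], cnvs=[])
    cfg.cnv_decoys.hl_sample = 0
    paths = generate_cohort(cfg, tmp_path / "z")
    res = run_screen(RunConfig.from_yaml(paths["run_config"], tmp_path / "zr"))
    carriers = res.summary["carriers"]
    assert carriers["seq_het_individuals"] == 0
    assert carriers["cnv_het_individuals"] == 0
    assert res.summary["variants"]["retained"] == 0


def test_round_trip_recovers_planted_counts_and_decoy_filters(small_run):
    bundle, res = small_run
    s = res.summary
    # planted sequence variants: 4 preselected (3 P/LP + 1 reclassified VUS)
    assert s["variants"]["preselected_plp"] == 4
    assert s["variants"]["retained"] == 3
    # detected = 4 planted + 8 catalogue decoys
    assert s["variants"]["detected"] == 12
    per_v = {r.hgvs_c: r for r in res.per_variant.itertuples(index=False)}
    assert (per_v["c.35del"].het_count, per_v["c.35del"].hom_count) == (4, 1)
    assert per_v["c.100C>T"].het_count == 3
    assert per_v["c.7G>A"].het_count == 2
    # carrier categories follow the planted genes
    assert s["carriers"]["het_categories"] == {
        "AR_only": 4, "AD_AR_gene": 3, "AD_only": 2, "none": 0}
    # CNVs: 2 planted P/LP (3 + 2 carriers) + 4 VUS events survive filters
    assert s["cnvs"]["relevant_distinct"] == 2
    assert s["cnvs"]["carrier_individuals"] == 5
    assert s["cnvs"]["after_filters_distinct"] == 6
    # each decoy family removed by its intended filter
    run_dir = res.out_dir
    def log_lines(name):
        text = (run_dir / f"log_{name}.txt").read_text()
        return [ln for ln in text.splitlines() if ln]
    assert len(log_lines("cnv_noncoding")) == 3
    size_synd = log_lines("cnv_size_syndromic")
    assert sum(1 for ln in size_synd if ln.endswith("size")) == 2
    assert sum(1 for ln in size_synd if ln.endswith("syndromic")) == 2
    assert len(log_lines("cnv_noncohort")) == 2  # affected-sample events


def test_plant_in_affected_removes_carriers_from_cohort(tmp_path):
    cfg = small_config(
        seed=6, plant_in_affected=True, n_hl_affected=12,
        variants=[VariantPlan("DFNB1A", "c.1A>G", het=5)],
        cnvs=[CnvPlan("DFNB1A", "DEL", 3, "P")])
    cfg.cnv_decoys.hl_sample = 1
    paths = generate_cohort(cfg, tmp_path / "p")
    res = run_screen(RunConfig.from_yaml(paths["run_config"], tmp_path / "pr"))
    assert res.summary["carriers"]["seq_het_individuals"] == 0
    assert res.summary["carriers"]["cnv_het_individuals"] == 0


def test_paper_fixture_is_frozen():
    cfg = paper_fixture(seed=1)
    assert cfg.n_individuals == 2199
    assert cfg.n_qc_fail == 13 and cfg.n_hl_affected == 89
    plp = [v for v in cfg.variants
           if v.final_class in ("P", "LP") and v.gene != "GJB3"]
    assert len(plp) == 89
    assert sum(v.het for v in plp) == 222
    assert sum(v.hom for v in plp) == 4
    assert sum(1 for v in plp if v.final_class == "P") == 44
    assert len({v.gene for v in plp}) == 36
    assert len(cfg.cnvs) == 12
    assert sum(c.carriers for c in cfg.cnvs) == 54
    strc = cfg.cnvs[0]
    assert (strc.contig, strc.start, strc.end, strc.carriers) == (
        "chr15", 43_600_849, 43_658_715, 38)
    gjb2 = [v for v in cfg.variants if v.hgvs_c == "c.35del" and v.gene == "GJB2"]
    assert gjb2[0].het == 28 and gjb2[0].hom == 1
    otoa_cnv = [c for c in cfg.cnvs if c.gene == "OTOA"]
    assert otoa_cnv[0].carriers == 4
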