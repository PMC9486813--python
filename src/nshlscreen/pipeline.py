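"""End-to-end screening pipeline.

Runs the stages in method order — panel filtering, sample QC, phenotype
exclusion, sequence-variant screening (preselection, call QC, curation),
CNV screening (merge, coding/size/syndromic filters, curation), carrier
statistics, Hardy-Weinberg projection, ROH consanguinity classification and
reference-cohort comparison — writing every intermediate exclusion log, the
final tables, and one machine-readable JSON summary per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cnv as cnvmod
from . import cohort as cohmod
from . import compare as cmpmod
from . import hw as hwmod
from . import roh as rohmod
from . import variants as varmod
from .panel import filter_panel, gene_modes, load_panel, summarize_panel

INPUT_KEYS = (
    "panel", "vcf", "cnv", "roh", "phenotype", "sample_qc", "catalogue",
    "decisions", "cnv_decisions", "exons", "syndromic", "reference", "mito",
    "hl_terms",
)

_THRESHOLD_RANGES = {
    "min_depth": (0, 10_000),
    "min_call_rate": (0.0, 1.0),
    "max_cnv_size_bp": (1, 1_000_000_000),
    "alpha": (0.0, 1.0),
    "autosome_length_mb": (1.0, 10_000.0),
    "min_roh_len_bp": (1, 1_000_000_000),
}


class PipelineError(RuntimeError):
    """A stage-level contract violation, carrying the stage name."""


@dataclass
class RunConfig:
    """Paths, thresholds and output location for one reproducible run."""

    inputs: dict[str, Path]
    out_dir: Path
    min_depth: int = 20
    min_call_rate: float = 0.95
    max_cnv_size_bp: int = 1_000_000
    alpha: float = 0.05
    autosome_length_mb: float = 2881.0
    min_roh_len_bp: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        inputs = {k: base / v for k, v in raw.get("inputs", {}).items()}
        thresholds = raw.get("thresholds", {})
        return cls(
            inputs=inputs,
            out_dir=Path(out_dir),
            seed=int(raw.get("seed", 0)),
            **{k: thresholds[k] for k in _THRESHOLD_RANGES if k in thresholds},
        )


def validate_config(config: RunConfig) -> list[str]:
    """All detectable problems (missing inputs, out-of-range thresholds)."""
    problems = []
    for key in INPUT_KEYS:
        p = config.inputs.get(key)
        if p is None:
            problems.append(f"missing input path: {key}")
        elif not Path(p).exists():
            problems.append(f"input file not found: {key} ({p})")
    for key, (lo, hi) in _THRESHOLD_RANGES.items():
        v = getattr(config, key)
        if not lo <= v <= hi:
            problems.append(f"threshold {key}={v} outside [{lo}, {hi}]")
    return problems


@dataclass
class ScreenResult:
    """Everything a run computed, plus where it was written."""

    summary: dict[str, Any]
    per_variant: pd.DataFrame
    per_gene: pd.DataFrame
    hw_estimates: pd.DataFrame
    roh_metrics: pd.DataFrame
    comparisons: pd.DataFrame
    out_dir: Path = field(default_factory=Path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_screen(config: RunConfig) -> ScreenResult:
    """Execute the full screen; raises PipelineError naming the failing stage."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs: dict[str, list[str]] = {}
    summary: dict[str, Any] = {"thresholds": {
        k: getattr(config, k) for k in _THRESHOLD_RANGES}, "seed": config.seed}

    # --- stage 1: gene panel ----------------------------------------------
    try:
        panel_entries = load_panel(config.inputs["panel"])
        retained_panel, exclusion_log = filter_panel(panel_entries)
        panel_summary = summarize_panel(retained_panel)
    except Exception as exc:
        raise PipelineError(f"panel: {exc}") from exc
    logs["panel_exclusions"] = [f"{g}\t{m}\t{r}" for g, m, r in exclusion_log]
    retained_genes = sorted({e.gene_symbol for e in retained_panel})
    modes = gene_modes(retained_panel)
    summary["panel"] = {
        "input_associations": len(panel_entries),
        "retained_associations": panel_summary.n_associations,
        "retained_genes": panel_summary.n_unique_genes,
        "class_gene_counts": panel_summary.class_gene_counts,
        "excluded_associations": len(exclusion_log),
    }

    # --- stage 2: sample QC and phenotype exclusion ------------------------
    try:
        individuals = cohmod.read_individuals(
            config.inputs["phenotype"], config.inputs["sample_qc"])
        passing, failing = cohmod.sample_qc_filter(individuals)
        hl_terms = [
            t.strip() for t in open(config.inputs["hl_terms"]) if t.strip()
        ]
        unaffected, affected = cohmod.phenotype_exclude(passing, hl_terms)
    except Exception as exc:
        raise PipelineError(f"samples: {exc}") from exc
    logs["sample_qc_failures"] = [
        f"{ind.sample_id}\t{','.join(metrics)}" for ind, metrics in failing
    ]
    logs["hl_affected"] = [ind.sample_id for ind in affected]
    unaffected_ids = [ind.sample_id for ind in unaffected]
    passing_ids = [ind.sample_id for ind in passing]
    n_unaffected = len(unaffected_ids)
    summary["samples"] = {
        "preselected": len(individuals),
        "qc_fail": len(failing),
        "qc_pass": len(passing),
        "hl_affected": len(affected),
        "unaffected": n_unaffected,
    }

    # --- stage 3: sequence variants ----------------------------------------
    try:
        catalogue = varmod.read_catalogue(config.inputs["catalogue"])
        skipped: list[str] = []
        preselected = varmod.preselect_variants(catalogue, retained_genes, skipped)
        panel_catalogue = [v for v in catalogue if v.gene_symbol in set(retained_genes)]
        calls = varmod.read_genotype_calls(
            config.inputs["vcf"], panel_catalogue, samples=passing_ids)
        qc_calls, qc_dropped = varmod.apply_call_qc(
            calls, min_depth=config.min_depth,
            min_call_rate=config.min_call_rate, n_samples=len(passing_ids))
        detected_keys = {
            key for key, row in qc_calls.items()
            if any(c.alt_alleles > 0 for c in row)
        }
        preselected = [v for v in preselected if v.key not in set(qc_dropped)]
        decisions = varmod.read_decisions(config.inputs["decisions"])
        curated = varmod.apply_curation(preselected, decisions)
        classes = varmod.final_classes(curated, decisions)
        mito_list = varmod.read_catalogue(config.inputs["mito"])
        mito_calls = [
            c
            for row in varmod.read_genotype_calls(
                config.inputs["vcf"], mito_list, samples=passing_ids
            ).values()
            for c in row
        ]
        mito_hits = varmod.screen_mito(mito_calls, mito_list)
    except Exception as exc:
        raise PipelineError(f"variants: {exc}") from exc
    logs["offpanel_variants"] = skipped
    logs["call_rate_dropped"] = [f"{c}:{p}:{r}>{a}" for c, p, r, a in qc_dropped]
    summary["variants"] = {
        "detected": len(detected_keys),
        "preselected_plp": len(preselected),
        "curation_excluded": len(preselected) - len(curated),
        "retained": len(curated),
        "final_p": sum(1 for v in classes.values() if v == "P"),
        "final_lp": sum(1 for v in classes.values() if v == "LP"),
        "genes_with_variants": len({v.gene_symbol for v in curated}),
        "mito_detected": len(mito_hits),
    }

    # --- stage 4: per-variant carrier counts -------------------------------
    try:
        counts: dict[tuple, cohmod.VariantCounts] = {}
        for v in curated:
            counts[v.key] = cohmod.count_genotypes(
                qc_calls.get(v.key, []), unaffected_ids)
        per_variant = pd.DataFrame([
            {
                "gene_symbol": v.gene_symbol,
                "hgvs_c": v.hgvs_c,
                "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "final_class": classes[v.key],
                "het_count": counts[v.key].het_count,
                "hom_count": counts[v.key].hom_count,
                "allele_count": counts[v.key].allele_count,
                "af": counts[v.key].allele_frequency
                if counts[v.key].n_genotyped else 0.0,
                "af_pct": cohmod.af_percent(counts[v.key].allele_frequency)
                if counts[v.key].n_genotyped else 0.0,
            }
            for v in curated
        ])
    except Exception as exc:
        raise PipelineError(f"carrier_counts: {exc}") from exc

    # --- stage 5: CNV screen ------------------------------------------------
    try:
        events = cnvmod.read_cnv_table(config.inputs["cnv"])
        events = cnvmod.merge_sources(events)
        n_events_input = len(events)
        unaffected_set = set(unaffected_ids)
        cohort_events = [e for e in events if e.sample_id in unaffected_set]
        exons = cnvmod.RegionMap.from_bed(config.inputs["exons"])
        syndromic = cnvmod.RegionMap.from_bed(config.inputs["syndromic"])
        coding = cnvmod.coding_overlap_filter(cohort_events, exons)
        filtered, cnv_log = cnvmod.syndromic_size_filter(
            coding, syndromic, max_size_bp=config.max_cnv_size_bp)
        cnv_dec_df = pd.read_csv(
            config.inputs["cnv_decisions"], sep="\t", keep_default_na=False)
        cnv_decisions = {
            (r.contig, int(r.start_1based), int(r.end_1based), r.svtype):
                r.final_class
            for r in cnv_dec_df.itertuples(index=False)
        }
        relevant = cnvmod.apply_cnv_curation(filtered, cnv_decisions)
        groups = cnvmod.group_recurrent(relevant)
    except Exception as exc:
        raise PipelineError(f"cnv: {exc}") from exc
    logs["cnv_noncohort"] = [
        f"{e.sample_id}\t{e.contig}:{e.start}-{e.end}" for e in events
        if e.sample_id not in unaffected_set
    ]
    logs["cnv_noncoding"] = [
        f"{e.sample_id}\t{e.contig}:{e.start}-{e.end}" for e in cohort_events
        if e not in set(coding)
    ]
    logs["cnv_size_syndromic"] = [
        f"{e.sample_id}\t{e.contig}:{e.start}-{e.end}\t{reason}"
        for e, reason in cnv_log
    ]
    cnv_rows = []
    cnv_carriers: set[str] = set()
    for key, carriers in sorted(groups.items()):
        genes_hit, spans = cnvmod.annotate_cnv_genes(
            cnvmod.CnvEvent(carriers[0], *key), retained_genes, exons)
        cnv_carriers.update(carriers)
        cnv_rows.append({
            "contig": key[0], "start_1based": key[1], "end_1based": key[2],
            "svtype": key[3], "size_bp": key[2] - key[1] + 1,
            "final_class": cnv_decisions[key],
            "carriers": len(carriers),
            "panel_genes": ";".join(genes_hit),
            "exon_spans": ";".join(f"{g}:{a}-{b}" for g, (a, b) in spans.items()),
            "af": len(carriers) / (2 * n_unaffected) if n_unaffected else 0.0,
            "af_pct": cohmod.af_percent(len(carriers) / (2 * n_unaffected))
            if n_unaffected else 0.0,
        })
    per_cnv = pd.DataFrame(cnv_rows)
    summary["cnvs"] = {
        "events_input": n_events_input,
        "events_in_cohort": len(cohort_events),
        "after_filters_distinct": cnvmod.distinct_count(filtered),
        "relevant_distinct": len(groups),
        "relevant_p": sum(1 for r in cnv_rows if r["final_class"] == "P"),
        "relevant_lp": sum(1 for r in cnv_rows if r["final_class"] == "LP"),
        "carrier_individuals": len(cnv_carriers),
    }

    # --- stage 6: per-gene combined summaries -------------------------------
    try:
        variant_genes: dict = {v.key: v.gene_symbol for v in curated}
        mechanisms: dict = {v.key: "sequence" for v in curated}
        all_counts: dict = dict(counts)
        for key, carriers in groups.items():
            genes_hit, _ = cnvmod.annotate_cnv_genes(
                cnvmod.CnvEvent(carriers[0], *key), retained_genes, exons)
            for g in genes_hit:
                k = key + (g,)
                all_counts[k] = cohmod.VariantCounts(
                    het_count=len(carriers), hom_count=0,
                    n_genotyped=n_unaffected)
                variant_genes[k] = g
                mechanisms[k] = "cnv"
        per_gene = cohmod.gene_combined_summary(
            all_counts, variant_genes, mechanisms, n_unaffected)
    except Exception as exc:
        raise PipelineError(f"gene_summary: {exc}") from exc

    # --- stage 7: carrier categories ----------------------------------------
    try:
        seq_het_carriers: dict[str, list[str]] = {}
        seq_hom_carriers: dict[str, list[str]] = {}
        unaffected_id_set = set(unaffected_ids)
        for v in curated:
            for c in qc_calls.get(v.key, []):
                if c.sample_id not in unaffected_id_set:
                    continue
                if c.genotype == "het":
                    seq_het_carriers.setdefault(c.sample_id, []).append(
                        v.gene_symbol)
                elif c.genotype == "hom_alt":
                    seq_hom_carriers.setdefault(c.sample_id, []).append(
                        v.gene_symbol)
        het_assign, het_tallies = cohmod.classify_carriers(
            seq_het_carriers, retained_panel)
        cnv_carrier_genes: dict[str, list[str]] = {}
        for key, carriers in groups.items():
            genes_hit, _ = cnvmod.annotate_cnv_genes(
                cnvmod.CnvEvent(carriers[0], *key), retained_genes, exons)
            for s in carriers:
                cnv_carrier_genes.setdefault(s, []).extend(genes_hit)
        cnv_assign, _ = cohmod.classify_carriers(cnv_carrier_genes, retained_panel)
        ad_implicated = cohmod.ad_implicated(het_assign) | cohmod.ad_implicated(
            cnv_assign)
    except Exception as exc:
        raise PipelineError(f"carrier_classes: {exc}") from exc
    seq_het_individuals = len(seq_het_carriers)
    combined_het = set(seq_het_carriers) | cnv_carriers
    pct = (lambda k: round(100.0 * k / n_unaffected, 2) if n_unaffected else 0.0)
    summary["carriers"] = {
        "seq_het_individuals": seq_het_individuals,
        "seq_het_pct": pct(seq_het_individuals),
        "seq_hom_individuals": len(seq_hom_carriers),
        "seq_hom_pct": pct(len(seq_hom_carriers)),
        "cnv_het_individuals": len(cnv_carriers),
        "cnv_het_pct": pct(len(cnv_carriers)),
        "combined_het_individuals": len(combined_het),
        "combined_het_pct": pct(len(combined_het)),
        "het_categories": {k: het_tallies.get(k, 0)
                           for k in cohmod.CARRIER_CATEGORIES},
        "ad_implicated": len(ad_implicated),
        "ad_implicated_pct": pct(len(ad_implicated)),
    }

    # --- stage 8: Hardy-Weinberg projection ---------------------------------
    try:
        combined = per_gene[per_gene.mechanism == "combined"]
        estimates = []
        for r in combined.itertuples(index=False):
            if "AR" not in modes.get(r.gene_symbol, set()):
                continue
            estimates.append(hwmod.hw_affected_frequency(
                float(r.combined_af), gene_symbol=r.gene_symbol))
        estimates.sort(key=lambda e: -e.q)
        hw_df = pd.DataFrame([
            {"gene_symbol": e.gene_symbol, "q": e.q, "q_squared": e.q_squared,
             "per_1000": e.per_1000, "one_in_x": e.one_in_x}
            for e in estimates
        ])
        top5 = estimates[:5]
        top5_burden, top5_one_in_x = hwmod.combined_recessive_burden(top5, modes)
        all_burden, all_one_in_x = hwmod.combined_recessive_burden(
            estimates, modes)
    except Exception as exc:
        raise PipelineError(f"hardy_weinberg: {exc}") from exc
    summary["hardy_weinberg"] = {
        "per_gene_per_1000": {
            e.gene_symbol: e.per_1000 for e in estimates[:10]},
        "top5_per_1000": top5_burden,
        "top5_one_in_x": top5_one_in_x,
        "all_ar_per_1000": all_burden,
        "all_ar_one_in_x": all_one_in_x,
    }

    # --- stage 9: ROH consanguinity -----------------------------------------
    try:
        roh_by_sample = rohmod.read_roh_bed(config.inputs["roh"])
        metrics = []
        for sid in unaffected_ids:
            segs = roh_by_sample.get(sid)
            if segs is None:
                continue
            metrics.append(rohmod.roh_metrics(
                segs, sample_id=sid, min_len_bp=config.min_roh_len_bp,
                autosome_length_mb=config.autosome_length_mb))
        roh_df = pd.DataFrame([
            {"sample_id": m.sample_id, "nroh": m.nroh, "sroh_mb": m.sroh_mb,
             "froh": m.froh, "consanguinity_class": m.consanguinity_class}
            for m in metrics
        ])
        reports = {ind.sample_id: ind.consanguinity_self_report
                   for ind in unaffected}
        mismatches, mismatch_rate = rohmod.reconcile_self_report(metrics, reports)
    except Exception as exc:
        raise PipelineError(f"roh: {exc}") from exc
    class_counts = (roh_df.consanguinity_class.value_counts().to_dict()
                    if len(roh_df) else {})
    summary["roh"] = {
        "samples_with_data": len(roh_df),
        "mean_sroh_mb": round(float(roh_df.sroh_mb.mean()), 2) if len(roh_df) else 0.0,
        "mean_nroh": round(float(roh_df.nroh.mean()), 2) if len(roh_df) else 0.0,
        "mean_froh_pct": round(100 * float(roh_df.froh.mean()), 2) if len(roh_df) else 0.0,
        "class_counts": {k: int(class_counts.get(k, 0))
                         for k in rohmod.CONSANGUINITY_CLASSES},
        "self_report_mismatches": len(mismatches),
        "self_report_mismatch_rate": round(mismatch_rate, 4),
    }

    # --- stage 10: reference-cohort comparison ------------------------------
    try:
        study_counts = {
            v.key: (counts[v.key].allele_count, 2 * counts[v.key].n_genotyped)
            for v in curated if counts[v.key].n_genotyped
        }
        reference = cmpmod.read_reference_counts(config.inputs["reference"])
        skipped_cmp: list[str] = []
        comparisons = cmpmod.compare_cohorts(
            study_counts, reference, alpha=config.alpha,
            skipped_log=skipped_cmp)
        gene_of = {v.key: v.gene_symbol for v in curated}
        cmp_df = pd.DataFrame([
            {"contig": c.variant_key[0], "pos": c.variant_key[1],
             "ref": c.variant_key[2], "alt": c.variant_key[3],
             "gene_symbol": gene_of.get(c.variant_key, ""),
             "study_alt": c.study_alt_alleles,
             "study_total": c.study_total_alleles,
             "ref_alt": c.ref_alt_alleles, "ref_total": c.ref_total_alleles,
             "p_value": c.p_value, "p_adjusted": c.p_adjusted,
             "significant": c.significant}
            for c in comparisons
        ])
    except Exception as exc:
        raise PipelineError(f"comparison: {exc}") from exc
    logs["comparison_skipped"] = skipped_cmp
    summary["comparison"] = {
        "shared_variants": len(comparisons),
        "significant": int(sum(c.significant for c in comparisons)),
        "significant_genes": sorted(
            gene_of.get(c.variant_key, "") for c in comparisons if c.significant),
    }

    # --- write outputs -------------------------------------------------------
    _write_tsv(per_variant, out / "per_variant.tsv")
    _write_tsv(per_gene, out / "per_gene.tsv")
    _write_tsv(per_cnv, out / "per_cnv.tsv")
    _write_tsv(hw_df, out / "hw_estimates.tsv")
    _write_tsv(roh_df, out / "roh_metrics.tsv")
    _write_tsv(cmp_df, out / "comparisons.tsv")
    for name, lines in logs.items():
        with open(out / f"log_{name}.txt", "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("nshlscreen run\n")
        for k, v in summary["thresholds"].items():
            fh.write(f"threshold {k} = {v}\n")
        fh.write(f"seed = {config.seed}\n")
        for entity in ("samples", "variants", "cnvs"):
            fh.write(f"{entity}: {json.dumps(summary[entity], sort_keys=True)}\n")

    return ScreenResult(
        summary=summary, per_variant=per_variant, per_gene=per_gene,
        hw_estimates=hw_df, roh_metrics=roh_df, comparisons=cmp_df,
        out_dir=out)
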