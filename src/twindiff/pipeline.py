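"""End-to-end orchestration of the co-twin comparison arms.

Runs, in dependency order: small-variant discordance funnels (unique and
zygosity modes), SV/CNV screening, differential methylation with spike-in QC,
regulatory feature annotation of the DMCs, and candidate-gene assembly. Each
arm is skipped with a warning when its inputs are absent; outputs land under a
single run directory and the combined run report is returned and written as
JSON.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Set

from . import annotation, methylation, prioritize, svcnv
from . import variants as variants_mod
from .model import (
    ThresholdConfig,
    logger,
    read_expression_tables,
    read_feature_bed,
    read_gene_list,
    read_gene_models,
    read_methylation_counts,
    read_vcf_records,
)

SV_TYPES = ("DEL", "DUP", "INS", "INV", "BND")


@dataclass
class RunConfig:
    """Input paths, thresholds and mode flags for a full pipeline run."""

    outdir: str
    vcf: Optional[str] = None
    sample_affected: str = "TWIN_TOF"
    sample_healthy: str = "TWIN_H"
    genes: Optional[str] = None
    cgi_bed: Optional[str] = None
    tfbs_bed: Optional[str] = None
    cardiac_tfbs_bed: Optional[str] = None
    enhancer_bed: Optional[str] = None
    sv_table: Optional[str] = None
    cnv_table: Optional[str] = None
    common_sv_beds: Dict[str, str] = field(default_factory=dict)  # sv_type -> path
    meth_affected: Optional[str] = None
    meth_healthy: Optional[str] = None
    lambda_cov: Optional[str] = None
    expression: Optional[str] = None
    gene_lists: Dict[str, str] = field(default_factory=dict)  # evidence label -> path
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    promoter_orientation: str = "minus500_plus2k"
    strict_absence: bool = False
    strict_quality: bool = False
    merge_symmetric: bool = False
    require_expression: bool = True

    def validate(self) -> None:
        for name in ("vcf", "genes", "cgi_bed", "tfbs_bed", "cardiac_tfbs_bed",
                     "enhancer_bed", "sv_table", "cnv_table", "meth_affected",
                     "meth_healthy", "lambda_cov", "expression"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_dataset_dir(cls, dataset: str, outdir: str, **overrides) -> "RunConfig":
        """Point every input at the files a simulated dataset directory emits."""
        from .prioritize import EVIDENCE_LABELS

        def p(name):
            path = os.path.join(dataset, name)
            return path if os.path.exists(path) else None

        common = {}
        for t in SV_TYPES:
            path = p(f"common_sv_{t}.bed")
            if path:
                common[t] = path
        lists = {}
        for label in EVIDENCE_LABELS:
            path = p(os.path.join("gene_lists", f"{label}.txt"))
            if path:
                lists[label] = path
        cfg = cls(
            outdir=outdir,
            vcf=p("twins.vcf"),
            genes=p("genes.tsv"),
            cgi_bed=p("cgi.bed"),
            tfbs_bed=p("tfbs.bed"),
            cardiac_tfbs_bed=p("cardiac_tfbs.bed"),
            enhancer_bed=p("enhancer.bed"),
            sv_table=p("svs.tsv"),
            cnv_table=p("cnvs.tsv"),
            common_sv_beds=common,
            meth_affected=p("methylation.affected.cov"),
            meth_healthy=p("methylation.healthy.cov"),
            lambda_cov=p("lambda.cov"),
            expression=p("expression.tsv"),
            gene_lists=lists,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all available arms and write the run report.

    Returns the report dict: per-arm funnels and survivor listings, the
    feature-overlap summary of the DMCs, QC, and the ranked candidate list.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    thr = cfg.thresholds
    report: dict = {"thresholds": dataclasses.asdict(thr)}
    nominations: Dict[str, Set[str]] = {}

    def nominate(gene: str, source: str) -> None:
        nominations.setdefault(gene, set()).add(source)

    genes = read_gene_models(cfg.genes) if cfg.genes else None

    # ----- variant arm -----------------------------------------------------
    if cfg.vcf:
        calls = list(
            read_vcf_records(cfg.vcf, cfg.sample_affected, cfg.sample_healthy)
        )
        trace = variants_mod.run_variant_funnel(
            calls, mode="unique", cfg=thr,
            strict_absence=cfg.strict_absence, strict_quality=cfg.strict_quality,
        )
        ztrace = variants_mod.run_variant_funnel(
            calls, mode="zygosity", cfg=thr, strict_quality=cfg.strict_quality
        )
        variants_mod.write_survivors_tsv(
            trace, os.path.join(cfg.outdir, "variant_survivors.tsv")
        )
        report["variant_funnel"] = trace.to_dict()
        report["zygosity_funnel"] = ztrace.to_dict()
        report["variant_survivors"] = sorted(
            (c.site.chrom, c.site.start) for c in trace.survivors
        )
        report["zygosity_survivors"] = sorted(
            (c.site.chrom, c.site.start) for c in ztrace.survivors
        )
        report["variant_funnel_pct"] = prioritize.funnel_percentage(
            trace.counts[-1], trace.counts[0]
        ) if trace.counts[0] else None
        if genes:
            for c in trace.survivors:
                for gname, _d in annotation.nearest_gene(c.site, genes):
                    nominate(gname, "variant")
    else:
        logger.warning("variant arm skipped: no VCF input")

    # ----- SV / CNV arm ----------------------------------------------------
    if cfg.sv_table:
        svs = svcnv.read_sv_table(cfg.sv_table)
        common_set = {
            t: read_feature_bed(path, t) for t, path in cfg.common_sv_beds.items()
        }
        sv_survivors = svcnv.filter_svs(svs, common_set, thr)
        svcnv.write_sv_table(
            sv_survivors, os.path.join(cfg.outdir, "sv_survivors.tsv")
        )
        report["sv_survivors"] = sorted(s.record_id for s in sv_survivors)
        if genes:
            sv_genes = svcnv.genes_affected(sv_survivors, genes)
            report["sv_genes"] = {g: sorted(v) for g, v in sorted(sv_genes.items())}
            for gname in sv_genes:
                nominate(gname, "sv")
    else:
        logger.warning("SV arm skipped: no SV table")

    if cfg.cnv_table:
        cnvs = svcnv.read_cnv_table(cfg.cnv_table)
        kept = svcnv.filter_cnvs(cnvs)
        report["cnv_classes"] = {
            "gain": sum(1 for c in kept if svcnv.classify_cnv(c) == "gain"),
            "loss": sum(1 for c in kept if svcnv.classify_cnv(c) == "loss"),
        }
        if genes:
            cnv_genes = svcnv.genes_affected(kept, genes)
            report["cnv_genes"] = {g: sorted(v) for g, v in sorted(cnv_genes.items())}
            for gname in cnv_genes:
                nominate(gname, "cnv")
    else:
        logger.warning("CNV arm skipped: no CNV table")

    # ----- methylome arm ---------------------------------------------------
    dmcs = None
    if cfg.meth_affected and cfg.meth_healthy:
        aff = read_methylation_counts(cfg.meth_affected)
        heal = read_methylation_counts(cfg.meth_healthy)
        if cfg.merge_symmetric:
            aff = methylation.merge_symmetric_cpgs(aff)
            heal = methylation.merge_symmetric_cpgs(heal)
        dmcs = methylation.call_dmcs(aff, heal, thr)
        methylation.write_dmc_tsv(dmcs, os.path.join(cfg.outdir, "dmc.tsv"))
        report["n_dmcs"] = len(dmcs)
        report["n_hyper"] = sum(1 for d in dmcs if d.direction == "hyper")
        report["n_hypo"] = sum(1 for d in dmcs if d.direction == "hypo")
        summary = methylation.global_methylation_summary(
            read_methylation_counts(cfg.meth_affected)
        )
        report["mean_cpg_methylation_affected"] = summary.mean_level
        qc = None
        if cfg.lambda_cov:
            qc = methylation.bisulfite_conversion_rate(
                read_methylation_counts(cfg.lambda_cov)
            )
            report["conversion_rate"] = qc.conversion_rate
        with open(os.path.join(cfg.outdir, "qc.json"), "w") as fh:
            json.dump(
                {
                    "conversion_rate": qc.conversion_rate if qc else None,
                    "mean_cpg_methylation_affected": summary.mean_level,
                    "n_sites_affected": summary.n_sites,
                },
                fh, indent=2,
            )
    else:
        logger.warning("methylome arm skipped: missing methylation inputs")

    # ----- annotation arm --------------------------------------------------
    if dmcs is not None and genes and cfg.cgi_bed:
        pdef = annotation.PromoterDefinition.from_orientation(cfg.promoter_orientation)
        cgis = read_feature_bed(cfg.cgi_bed, "cgi")
        promoters = annotation.build_promoters(genes, pdef)
        shores = annotation.build_cgi_shores(cgis, thr)
        prom_cgis = annotation.build_promoter_cgis(promoters, cgis)
        tracks = [promoters, cgis, prom_cgis, shores]
        for name, path in (
            ("tfbs", cfg.tfbs_bed),
            ("cardiac_tfbs", cfg.cardiac_tfbs_bed),
            ("enhancer", cfg.enhancer_bed),
        ):
            if path:
                tracks.append(read_feature_bed(path, name))
        sites = [d.site for d in dmcs]
        annotated = annotation.overlap_sites(sites, tracks, genes=genes)
        counts = annotation.summarize_feature_counts(annotated)
        locations = annotation.summarize_locations(annotated)
        annotation.write_feature_summary_tsv(
            counts, os.path.join(cfg.outdir, "feature_summary.tsv")
        )
        report["feature_counts"] = counts
        report["location_counts"] = locations
        for ann in annotated:
            if "promoter_cgi" in ann.feature_hits:
                for gname, _d in ann.nearest_genes:
                    nominate(gname, "dmc_promoter_cgi")
            if ("tfbs_in_promoter" in ann.feature_hits
                    or "cardiac_tfbs_in_promoter" in ann.feature_hits):
                for gname, _d in ann.nearest_genes:
                    nominate(gname, "dmc_tfbs_promoter")
    elif dmcs is not None:
        logger.warning("annotation arm skipped: missing gene models or CGI track")

    # ----- prioritization arm ----------------------------------------------
    if nominations and cfg.expression:
        tables = read_expression_tables(cfg.expression)
        lists = prioritize.normalize_gene_lists(
            {label: read_gene_list(path) for label, path in cfg.gene_lists.items()}
        )
        candidates = prioritize.assemble_candidates(
            nominations, tables, lists, thr,
            require_expression=cfg.require_expression,
        )
        prioritize.write_candidate_report(
            candidates,
            os.path.join(cfg.outdir, "candidates.tsv"),
            os.path.join(cfg.outdir, "candidates.json"),
        )
        report["candidates"] = sorted(c.gene for c in candidates)
        report["nominations"] = {g: sorted(s) for g, s in sorted(nominations.items())}
    elif nominations:
        logger.warning("prioritization arm skipped: no expression table")

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
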