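"""Evidence intersection and full-pipeline orchestration.

Four evidence streams nominate candidate genes: (1) genes with a
significant cis-eQTL, (2) genes whose significant cis-eQTLs colocalize
with the GWAS support interval, (3) critical genes of trait-linked
co-expression modules, (4) genes correlated with the trait after
covariate adjustment. The candidate report ranks genes by how many
streams support them (the Venn logic); the 4-way intersection is the
headline candidate set. The "pQTL mapping" stream is operationalized as
colocalization: genes whose significant cis-eQTLs fall inside the
2-LOD-drop support interval.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import __version__, coexpr, correl, dataio, eqtl, exprnorm, pqtl, synthio

logger = logging.getLogger(__name__)

__all__ = ["CandidateReport", "PipelineConfig", "intersect_evidence", "run_pipeline"]

STREAMS = ("cis_eqtl", "pqtl_coloc", "critical_module", "correlation")


@dataclass
class CandidateReport:
    table: pd.DataFrame  # gene_id, four boolean flags, tier
    venn: dict[str, int]  # exclusive region counts keyed by joined stream names

    @property
    def four_way(self) -> list[str]:
        return self.table.loc[self.table["tier"] == 4, "gene_id"].tolist()


def intersect_evidence(
    eqtl_genes,
    coloc_genes,
    critical_genes,
    corr_genes,
    corr_table: pd.DataFrame | None = None,
) -> CandidateReport:
    """Exact set intersections of the four evidence streams.

    Genes are sorted by tier (number of supporting streams, descending)
    then by correlation q when ``corr_table`` is given, then by id. The
    Venn dictionary holds exclusive region counts whose inclusion-
    exclusion sums reproduce each stream's size.
    """
    sets = {
        "cis_eqtl": set(eqtl_genes),
        "pqtl_coloc": set(coloc_genes),
        "critical_module": set(critical_genes),
        "correlation": set(corr_genes),
    }
    union = set().union(*sets.values())
    if not union:
        logger.warning("all evidence streams are empty")
    qmap: dict[str, float] = {}
    if corr_table is not None and not corr_table.empty:
        qmap = dict(zip(corr_table["gene_id"], corr_table["q"]))
    rows = []
    for g in union:
        flags = {s: g in sets[s] for s in STREAMS}
        rows.append({"gene_id": g, **flags, "tier": sum(flags.values())})
    table = pd.DataFrame(rows, columns=["gene_id", *STREAMS, "tier"])
    if not table.empty:
        table["_q"] = table["gene_id"].map(lambda g: qmap.get(g, np.inf))
        table = (
            table.sort_values(["tier", "_q", "gene_id"], ascending=[False, True, True], kind="mergesort")
            .drop(columns="_q")
            .reset_index(drop=True)
        )
    venn: dict[str, int] = {}
    for r in range(1, len(STREAMS) + 1):
        for combo in combinations(STREAMS, r):
            inside = set(union)
            for s in combo:
                inside &= sets[s]
            for s in STREAMS:
                if s not in combo:
                    inside -= sets[s]
            venn["&".join(combo)] = len(inside)
    return CandidateReport(table=table, venn=venn)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for a full run.

    Either the five input paths are given, or ``simulate`` carries a
    :class:`~imfscan.synthio.SimulationConfig` and the pipeline writes
    and re-reads a synthetic dataset (exercising the file formats).
    """

    outdir: str
    # inputs
    vcf: str | None = None
    expression: str | None = None
    annotation: str | None = None
    covariates: str | None = None
    gwas: str | None = None
    simulate: synthio.SimulationConfig | None = None
    # stage parameters
    min_fpkm: float = 0.1
    min_fraction: float = 0.5
    cis_window: int = eqtl.CIS_WINDOW
    p_genomewide: float = eqtl.P_GENOMEWIDE
    p_suggestive: float = eqtl.P_SUGGESTIVE
    lod_drop: float = 2.0
    r2_min: float = 0.90
    n_perm: int = 10_000
    perm_seed: int = 2024
    max_perm_snps: int = 50
    outlier_cut_height: float | None = None
    soft_power: int | None = None
    min_module_size: int = 30
    module_cut_height: float = 0.98
    merge_height: float = 0.25
    mtr_p_max: float = 0.01
    gs_mm_p_max: float = 0.01
    corr_q_max: float = 0.05
    log2_pseudocount: float = 1.0

    def input_paths(self) -> dict[str, str | None]:
        return {
            "vcf": self.vcf,
            "expression": self.expression,
            "annotation": self.annotation,
            "covariates": self.covariates,
            "gwas": self.gwas,
        }


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> dict:
    """normalize -> eQTL -> GWAS/pQTL -> colocalization -> co-expression
    -> correlation -> intersection; per-stage TSVs, a provenance
    manifest and a human-readable summary are written under ``outdir``.

    Returns a dict with the in-memory stage results (tables, intervals,
    the candidate report and output paths).
    """
    os.makedirs(config.outdir, exist_ok=True)
    t0 = time.perf_counter()

    if config.simulate is not None:
        datadir = os.path.join(config.outdir, "data")
        paths = synthio.make_dataset(config.simulate, datadir)
        cfg = dataclasses.replace(
            config,
            vcf=paths["vcf"], expression=paths["expression"],
            annotation=paths["annotation"], covariates=paths["covariates"],
            gwas=paths["gwas"],
        )
    else:
        cfg = config
    missing = [k for k, v in cfg.input_paths().items() if k != "gwas" and v is None]
    if missing:
        raise ValueError(f"missing pipeline inputs: {missing}")

    try:
        geno = dataio.read_genotypes(cfg.vcf)
        fpkm = dataio.read_expression(cfg.expression, annotation=cfg.annotation, scale="fpkm")
        cov = dataio.read_covariates(cfg.covariates)
        if cov.trait is None:
            raise ValueError("covariates table must include the trait column")
        geno, fpkm, cov = dataio.align_samples(geno, fpkm, cov)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    t0 = _stage("load", t0)

    out: dict = {"paths": {}}

    def save(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(config.outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        out["paths"][name] = path

    try:
        fpkm_kept, norm_report = exprnorm.filter_expressed(fpkm, cfg.min_fpkm, cfg.min_fraction)
        tpm = exprnorm.fpkm_to_tpm(fpkm).subset_genes(
            [fpkm.gene_index(g) for g in fpkm_kept.gene_ids]
        )
        normalized = exprnorm.rank_inverse_normal(tpm)
        out["normalization_report"] = norm_report
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    t0 = _stage("normalize", t0)

    try:
        geno_qc, qc_report = eqtl.qc_genotypes(geno)
        eqtl_table = eqtl.run_scan(
            normalized, geno_qc, cov,
            window=cfg.cis_window,
            p_genomewide=cfg.p_genomewide, p_suggestive=cfg.p_suggestive,
        )
        out["qc_report"] = qc_report
        out["eqtl"] = eqtl_table
        save(eqtl_table, "eqtl.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'eqtl' failed: {exc}") from exc
    t0 = _stage("eqtl", t0)

    try:
        if cfg.gwas is not None:
            gwas = dataio.read_gwas(cfg.gwas)
        else:
            gwas = pqtl.gwas_scan(geno_qc, cov)
        peak_i = int(np.argmin(gwas.p_value))
        peak_chrom = str(gwas.chrom[peak_i])
        profile = pqtl.lod_profile_from_summary(gwas, peak_chrom)
        interval = pqtl.lod_drop_interval(profile, drop=cfg.lod_drop)
        blocks = pqtl.find_ld_blocks(geno_qc, region=interval, r2_min=cfg.r2_min)
        out["gwas"] = gwas
        out["pqtl_interval"] = interval
        out["ld_blocks"] = blocks
        dataio.write_intervals([interval], os.path.join(config.outdir, "pqtl_interval.bed"))
        save(
            pd.DataFrame(
                [
                    {
                        "chrom": b.chrom, "start": b.start, "end": b.end,
                        "n_snps": b.n_snps, "min_r2": b.min_r2,
                        "snp_ids": ",".join(b.snp_ids),
                    }
                    for b in blocks
                ],
                columns=["chrom", "start", "end", "n_snps", "min_r2", "snp_ids"],
            ),
            "ld_blocks.tsv",
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'pqtl' failed: {exc}") from exc
    t0 = _stage("pqtl", t0)

    try:
        coloc_table = pqtl.colocalize(interval, eqtl_table, p_max=cfg.p_suggestive)
        out["coloc"] = coloc_table
        save(coloc_table, "coloc.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'coloc' failed: {exc}") from exc
    t0 = _stage("coloc", t0)

    try:
        perm_table = pd.DataFrame(columns=["snp_id", "t_obs", "p_perm", "p_perm_family"])
        stratified = None
        if not coloc_table.empty and coloc_table.iloc[0]["n_eqtls_in_interval"] > 0:
            top_gene = coloc_table.iloc[0]["gene_id"]
            snp_ids = coloc_table.iloc[0]["snp_ids"].split(",")[: cfg.max_perm_snps]
            snp_idx = [geno_qc.snp_ids.index(s) for s in snp_ids if s in geno_qc.snp_ids]
            if snp_idx:
                perm_table = pqtl.permutation_assoc(
                    geno_qc, snp_idx, cov, n_perm=cfg.n_perm, seed=cfg.perm_seed
                )
                best = int(np.argmin(perm_table["p_perm"].to_numpy()))
                try:
                    stratified = pqtl.genotype_stratified_test(
                        geno_qc.dosage[:, snp_idx[best]], cov.trait
                    )
                    stratified["snp_id"] = perm_table.iloc[best]["snp_id"]
                    stratified["gene_id"] = top_gene
                except ValueError as exc:
                    logger.warning("genotype-stratified test skipped: %s", exc)
        out["permutation"] = perm_table
        out["stratified"] = stratified
        save(perm_table, "permutation.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'permtest' failed: {exc}") from exc
    t0 = _stage("permtest", t0)

    try:
        log2_expr = correl.log2_transform(fpkm_kept, cfg.log2_pseudocount)
        assignment, gene_stats, crit, coexpr_info = coexpr.coexpression_analysis(
            log2_expr, cov.trait,
            outlier_cut_height=cfg.outlier_cut_height,
            soft_power=cfg.soft_power,
            min_module_size=cfg.min_module_size,
            cut_height=cfg.module_cut_height,
            merge_height=cfg.merge_height,
            mtr_p_max=cfg.mtr_p_max,
            gs_mm_p_max=cfg.gs_mm_p_max,
        )
        out["modules"] = assignment
        out["gene_stats"] = gene_stats
        out["critical_genes"] = crit
        out["coexpr_info"] = coexpr_info
        save(gene_stats, "gene_stats.tsv")
        save(
            pd.DataFrame(
                [
                    {"module": m, "n_genes": len(assignment.members(m)),
                     "mtr_r": assignment.mtr[m][0], "mtr_p": assignment.mtr[m][1]}
                    for m in assignment.modules
                ],
                columns=["module", "n_genes", "mtr_r", "mtr_p"],
            ),
            "module_trait.tsv",
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'coexpr' failed: {exc}") from exc
    t0 = _stage("coexpr", t0)

    try:
        corr_table = correl.correlate_all(log2_expr, cov, q_max=cfg.corr_q_max)
        out["correlation"] = corr_table
        save(corr_table, "correlation.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc
    t0 = _stage("correlate", t0)

    try:
        eqtl_genes = set(
            eqtl_table.loc[
                eqtl_table["significant_sugg"] & (eqtl_table["relation"] == "cis"),
                "gene_id",
            ]
        )
        coloc_genes = set(
            coloc_table.loc[coloc_table["n_eqtls_in_interval"] > 0, "gene_id"]
        )
        corr_genes = set(corr_table.loc[corr_table["significant"], "gene_id"])
        report = intersect_evidence(
            eqtl_genes, coloc_genes, crit, corr_genes, corr_table=corr_table
        )
        out["report"] = report
        save(report.table, "candidates.tsv")
        with open(os.path.join(config.outdir, "venn.json"), "w") as fh:
            json.dump(report.venn, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'intersect' failed: {exc}") from exc
    t0 = _stage("intersect", t0)

    manifest = {
        "imfscan_version": __version__,
        "thresholds": {
            k: getattr(cfg, k)
            for k in (
                "min_fpkm", "min_fraction", "cis_window", "p_genomewide",
                "p_suggestive", "lod_drop", "r2_min", "n_perm", "perm_seed",
                "min_module_size", "module_cut_height", "merge_height",
                "mtr_p_max", "gs_mm_p_max", "corr_q_max", "log2_pseudocount",
            )
        },
        "inputs": cfg.input_paths(),
        "simulated": config.simulate is not None,
        "sim_seed": None if config.simulate is None else int(config.simulate.seed),
        "n_samples": len(cov.sample_ids),
        "coexpr": coexpr_info,
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    four_way = report.four_way
    lines = [
        "imfscan pipeline summary",
        f"samples: {len(cov.sample_ids)}; genes tested: {fpkm_kept.n_genes} "
        f"(of {fpkm.n_genes}); SNPs after QC: {geno_qc.n_snps}",
        f"cis-eQTL pairs fitted: {len(eqtl_table)}; suggestive (p<{cfg.p_suggestive:g}): "
        f"{int(eqtl_table['significant_sugg'].sum())}; genome-wide (p<{cfg.p_genomewide:g}): "
        f"{int(eqtl_table['significant_gw'].sum())}",
        f"pQTL support interval: {interval.chrom}:{interval.start}-{interval.end} "
        f"({len(blocks)} LD block(s) with r2>{cfg.r2_min:g})",
        f"colocalized genes: {sorted(coloc_genes)}",
        f"modules: {len(assignment.modules)}; critical genes: {len(crit)}",
        f"correlation-significant genes (q<={cfg.corr_q_max:g}): {len(corr_genes)}",
        f"4-way candidates: {four_way}",
    ]
    summary = "\n".join(lines) + "\n"
    with open(os.path.join(config.outdir, "summary.txt"), "w") as fh:
        fh.write(summary)
    out["summary"] = summary
    return out
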