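"""Synthetic cohort generator with the statistical structure the
analysis assumes.

The generator emulates a Laiwu-pig-like design: 79 individuals (58:21
sex split, 11 slaughter batches, carcass weight about 100 kg),
LD-blocked biallelic genotypes, gene expression following the additive
forward model

    g = beta * S + bw + se + ba + eps        (latent log scale)

with planted cis effects, three co-expression modules driven by latent
per-sample factors, one designated regulator gene whose expression is
negatively linked to the quantitative trait (intramuscular fat, %), and
an FPKM-like non-negative abundance scale obtained by an invertible
exp-shift of the latent values. LD is modelled by haplotype copying: all
SNPs in a block copy a block master haplotype, each allele flipped
independently with probability (1 - ld_within_r)/2, which yields tunable
pairwise dosage r^2 (r^2 = 1 when ld_within_r = 1) without a coalescent
simulator.

All randomness flows from the single config seed; equal configs give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .dataio import (
    ExpressionMatrix,
    GenotypeMatrix,
    SampleCovariates,
    write_covariates,
    write_expression,
    write_gwas,
    write_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EqtlEffect",
    "CovariateEffects",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_trait",
    "mask_missing",
    "latent_expression",
    "make_dataset",
]

# per-stage RNG stream tags so each stage is independently reproducible
_STREAM = {"geno": 1, "cov": 2, "expr": 3, "trait": 4, "missing": 5, "layout": 6}


@dataclass(frozen=True)
class EqtlEffect:
    """One planted genotype->expression effect.

    The SNP is the middle SNP of block ``block`` on ``chrom``; ``cis``
    controls whether the target gene's TSS is placed inside (True) or
    beyond (False) the 1-Mb cis window around that SNP.
    """

    chrom: str
    block: int
    gene: str
    beta: float
    cis: bool = True


@dataclass(frozen=True)
class CovariateEffects:
    """Effect sizes of sex/batch/weight on expression (latent scale) and
    on the trait (trait units)."""

    sex_expr: float = 0.3
    batch_expr_sd: float = 0.2
    weight_expr: float = 0.02  # per kg deviation from the weight mean
    sex_trait: float = 0.5
    batch_trait_sd: float = 0.3
    weight_trait: float = 0.05


@dataclass
class SimulationConfig:
    """Forward-model parameters. ``seed`` is mandatory.

    Defaults reflect the emulated cohort: 79 samples, 58:21 sex ratio,
    11 slaughter batches, ~100 kg carcass weight, 5-SNP LD blocks with
    high within-block correlation, MAF well clear of the 0.05 QC bound,
    three 100-gene co-expression modules, one regulator gene on
    chromosome 9 (block centred near 25.5 Mb) with a strong cis effect
    and a negative effect on the trait.
    """

    seed: int
    n_samples: int = 79
    sex_proportions: tuple[int, int] = (58, 21)
    n_batches: int = 11
    weight_mean: float = 100.0
    weight_sd: float = 8.0
    # genotypes
    chromosomes: tuple[str, ...] = ("1", "2", "9", "13")
    blocks_per_chrom: int = 20
    ld_block_sizes: int = 5
    ld_within_r: float = 0.99
    maf_range: tuple[float, float] = (0.2, 0.45)
    chrom_start: int = 20_000_000
    block_spacing: int = 300_000
    snp_spacing: int = 5_000
    missing_rate: float = 0.01
    on_monomorphic: str = "regenerate"  # or "error"
    # expression
    n_genes: int = 400
    n_unexpressed: int = 20
    module_sizes: tuple[int, ...] = (100, 100, 100)
    loading_range: tuple[float, float] = (0.7, 1.0)
    noise_sd: float = 0.5
    eqtl_plan: tuple[EqtlEffect, ...] | None = None
    covariate_effect_sizes: CovariateEffects = field(default_factory=CovariateEffects)
    fpkm_log_scale: float = 0.5
    fpkm_log_shift: float = 3.0
    n_outliers: int = 0
    outlier_shift: float = 6.0
    # trait
    regulator_gene: str = "G0001"
    regulator_effect: float = -1.5
    regulator_loading: float = 0.9
    trait_intercept: float = 5.0
    trait_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.ld_within_r <= 1.0:
            raise ValueError("ld_within_r must lie in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.eqtl_plan is None:
            self.eqtl_plan = self.default_eqtl_plan()

    # ------------------------------------------------------------------
    # deterministic layout helpers
    # ------------------------------------------------------------------

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    @property
    def regulator_block(self) -> tuple[str, int]:
        # block centred near 25.5 Mb on chromosome "9" with default
        # spacing; clamped to the configured genome otherwise
        chrom = "9" if "9" in self.chromosomes else self.chromosomes[0]
        return (chrom, min(18, self.blocks_per_chrom - 1))

    def default_eqtl_plan(self) -> tuple[EqtlEffect, ...]:
        reg_chrom, reg_block = self.regulator_block
        plan = [EqtlEffect(reg_chrom, reg_block, self.regulator_gene, beta=1.6, cis=True)]
        # further cis effects on non-trait-linked genes, one per other
        # chromosome, plus one deliberately trans-positioned pair
        others = [c for c in self.chromosomes if c != reg_chrom]
        targets = ["G0150", "G0250", "G0350"]
        mid_block = min(5, self.blocks_per_chrom - 1)
        for chrom, gene in zip(others, targets):
            if gene in self.gene_ids():
                plan.append(EqtlEffect(chrom, mid_block, gene, beta=1.2, cis=True))
        trans_block = min(9, self.blocks_per_chrom - 1)
        if "G0360" in self.gene_ids() and others:
            plan.append(EqtlEffect(others[-1], trans_block, "G0360", beta=1.2, cis=False))
        return tuple(plan)

    def gene_ids(self) -> list[str]:
        n = self.n_genes + self.n_unexpressed
        return [f"G{i + 1:04d}" for i in range(n)]

    def module_of(self) -> dict[str, int | None]:
        """Gene -> module index (0-based) or None for background genes."""
        out: dict[str, int | None] = {}
        bounds = np.cumsum((0,) + tuple(self.module_sizes))
        for i, g in enumerate(self.gene_ids()):
            if i >= self.n_genes:
                out[g] = None  # unexpressed
                continue
            m = np.searchsorted(bounds, i, side="right") - 1
            out[g] = int(m) if m < len(self.module_sizes) else None
        return out

    def block_positions(self, chrom: str, block: int) -> np.ndarray:
        start = self.chrom_start + block * self.block_spacing
        return start + np.arange(self.ld_block_sizes) * self.snp_spacing

    def snp_table(self) -> list[tuple[str, str, int, int, int]]:
        """(snp_id, chrom, pos, block_index, index_in_block) in map order."""
        rows = []
        for chrom in self.chromosomes:
            for b in range(self.blocks_per_chrom):
                for s, pos in enumerate(self.block_positions(chrom, b)):
                    rows.append((f"snp_{chrom}_{b:02d}_{s}", chrom, int(pos), b, s))
        return rows

    def planted_snp_id(self, eff: EqtlEffect) -> str:
        mid = self.ld_block_sizes // 2
        return f"snp_{eff.chrom}_{eff.block:02d}_{mid}"

    def planted_snp_pos(self, eff: EqtlEffect) -> int:
        mid = self.ld_block_sizes // 2
        return int(self.block_positions(eff.chrom, eff.block)[mid])

    def gene_annotation(self) -> dict[str, tuple[str, int, int, str]]:
        """Gene -> (chrom, start, end, strand), TSS-consistent.

        Non-planted genes are spread across the SNP blocks (so the cis
        scan has null pairs); planted genes sit 200 kb from their SNP
        (cis) or 1.5 Mb away (trans positives for window testing).
        """
        span = 20_000
        ann: dict[str, tuple[str, int, int, str]] = {}
        planted = {e.gene: e for e in self.eqtl_plan}
        genes = self.gene_ids()
        n_chrom = len(self.chromosomes)
        for i, g in enumerate(genes):
            if g in planted:
                e = planted[g]
                pos = self.planted_snp_pos(e)
                tss = pos + (200_000 if e.cis else 1_500_000)
                chrom = e.chrom
            else:
                chrom = self.chromosomes[i % n_chrom]
                block = (i // n_chrom) % self.blocks_per_chrom
                tss = int(self.block_positions(chrom, block)[0]) + 37_000 + (i % 7) * 1_000
            strand = "-" if i % 5 == 0 else "+"
            if strand == "+":
                ann[g] = (chrom, tss, tss + span, "+")
            else:
                ann[g] = (chrom, tss - span, tss, "-")
        return ann


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw LD-blocked dosages (complete; missingness is applied
    separately by :func:`mask_missing`).

    Each block draws an allele frequency from ``maf_range``; haplotypes
    copy a per-haplotype master allele with flip probability
    (1 - ld_within_r)/2. Blocks carrying a planted effect are redrawn
    (bounded retries) if the planted SNP comes out monomorphic, or raise
    if ``on_monomorphic='error'``.
    """
    rng = config.rng("geno")
    n = config.n_samples
    n_hap = 2 * n
    flip = (1.0 - config.ld_within_r) / 2.0
    planted_blocks = {(e.chrom, e.block) for e in config.eqtl_plan}
    mid = config.ld_block_sizes // 2

    snps = config.snp_table()
    cols: dict[tuple[str, int], np.ndarray] = {}
    for chrom in config.chromosomes:
        for b in range(config.blocks_per_chrom):
            for attempt in range(50):
                p = rng.uniform(*config.maf_range)
                master = rng.random(n_hap) < p
                alleles = np.empty((n_hap, config.ld_block_sizes), dtype=bool)
                for s in range(config.ld_block_sizes):
                    flips = rng.random(n_hap) < flip
                    alleles[:, s] = master ^ flips
                dos = (alleles[0::2].astype(np.int8) + alleles[1::2].astype(np.int8)).astype(float)
                if (chrom, b) not in planted_blocks:
                    break
                maf_mid = min(dos[:, mid].mean() / 2, 1 - dos[:, mid].mean() / 2)
                if maf_mid >= 0.05:
                    break
                if config.on_monomorphic == "error":
                    raise ValueError(f"planted SNP monomorphic in block {chrom}:{b}")
            else:  # pragma: no cover - vanishingly unlikely with default MAF range
                raise ValueError(f"could not realize polymorphic planted block {chrom}:{b}")
            cols[(chrom, b)] = dos

    dosage = np.column_stack([cols[(c, b)][:, s] for (_, c, _, b, s) in snps])
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        snp_ids=[r[0] for r in snps],
        chrom=np.asarray([r[1] for r in snps], dtype=object),
        pos=np.asarray([r[2] for r in snps]),
        dosage=dosage,
        ref=np.full(len(snps), "A", dtype=object),
        alt=np.full(len(snps), "G", dtype=object),
    )


def mask_missing(geno: GenotypeMatrix, config: SimulationConfig) -> GenotypeMatrix:
    """Set each dosage to missing independently with ``missing_rate``."""
    if config.missing_rate <= 0:
        return geno
    rng = config.rng("missing")
    out = geno.subset_snps(slice(None))
    mask = rng.random(out.dosage.shape) < config.missing_rate
    out.dosage = out.dosage.copy()
    out.dosage[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# covariates, expression, trait
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimulationConfig) -> SampleCovariates:
    """Sex (configurable proportions), slaughter batch (uniform over
    ``n_batches``) and carcass weight (normal)."""
    rng = config.rng("cov")
    n = config.n_samples
    p_male = config.sex_proportions[0] / sum(config.sex_proportions)
    sex = np.where(rng.random(n) < p_male, "M", "F").astype(object)
    batch = np.asarray([f"B{b + 1:02d}" for b in rng.integers(0, config.n_batches, n)], dtype=object)
    weight = rng.normal(config.weight_mean, config.weight_sd, n)
    return SampleCovariates(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        sex=sex,
        batch=batch,
        carcass_weight=weight,
    )


def _covariate_latent_terms(cov: SampleCovariates, config: SimulationConfig, rng: np.random.Generator):
    """Per-sample covariate contribution to latent expression, shared by
    all genes (fixed sex/batch/weight effects)."""
    ces = config.covariate_effect_sizes
    sex_term = np.where(cov.sex == "F", ces.sex_expr, 0.0)
    levels = sorted(set(cov.batch.tolist()))
    batch_eff = {b: rng.normal(0.0, ces.batch_expr_sd) for b in levels}
    batch_term = np.asarray([batch_eff[b] for b in cov.batch])
    weight_term = ces.weight_expr * (cov.carcass_weight - config.weight_mean)
    return sex_term + batch_term + weight_term


def simulate_expression(
    geno: GenotypeMatrix,
    cov: SampleCovariates,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Forward model on the latent log scale, mapped to an FPKM-like
    non-negative scale by the invertible transform
    FPKM = exp(fpkm_log_scale * latent + fpkm_log_shift).

    Each gene receives its module factor (if any), its planted SNP
    effect (if any), the shared covariate terms and N(0, noise_sd^2)
    noise. ``n_unexpressed`` trailing genes are written on a barely
    detectable scale so the expressed-gene filter has work to do.
    Outlier samples (if configured) receive a global latent shift.
    """
    rng = config.rng("expr")
    n = cov.n_samples
    genes = config.gene_ids()
    module_of = config.module_of()
    planted = {e.gene: e for e in config.eqtl_plan}
    snp_col = {sid: j for j, sid in enumerate(geno.snp_ids)}

    factors = rng.standard_normal((len(config.module_sizes), n))
    cov_term = _covariate_latent_terms(cov, config, rng)
    loadings = {
        g: (config.regulator_loading if g == config.regulator_gene else rng.uniform(*config.loading_range))
        for g in genes
        if module_of[g] is not None
    }

    latent = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        val = cov_term + rng.normal(0.0, config.noise_sd, n)
        m = module_of[g]
        if m is not None:
            val = val + loadings[g] * factors[m]
        if g in planted:
            e = planted[g]
            S = geno.dosage[:, snp_col[config.planted_snp_id(e)]]
            if np.isnan(S).any():
                raise ValueError("expression must be simulated from complete genotypes")
            val = val + e.beta * S
        latent[i] = val

    if config.n_outliers > 0:
        out_idx = config.rng("layout").choice(n, size=config.n_outliers, replace=False)
        latent[: config.n_genes, out_idx] += config.outlier_shift

    fpkm = np.exp(config.fpkm_log_scale * latent + config.fpkm_log_shift)
    # unexpressed genes: rescale far below the 0.1 FPKM detection bound
    if config.n_unexpressed > 0:
        lat_u = latent[config.n_genes:]
        fpkm[config.n_genes:] = np.exp(0.2 * lat_u - 4.0)

    ann = config.gene_annotation()
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=list(cov.sample_ids),
        values=fpkm,
        scale="fpkm",
        chrom=np.asarray([ann[g][0] for g in genes], dtype=object),
        start=np.asarray([ann[g][1] for g in genes]),
        end=np.asarray([ann[g][2] for g in genes]),
        strand=np.asarray([ann[g][3] for g in genes], dtype=object),
    )


def latent_expression(expr: ExpressionMatrix, config: SimulationConfig) -> np.ndarray:
    """Invert the FPKM transform back to the latent log scale (expressed
    genes only; the transform is recorded in the config)."""
    if expr.scale != "fpkm":
        raise ValueError("latent inversion applies to the FPKM-scale matrix")
    return (np.log(expr.values) - config.fpkm_log_shift) / config.fpkm_log_scale


def simulate_trait(
    expr: ExpressionMatrix,
    cov: SampleCovariates,
    config: SimulationConfig,
) -> SampleCovariates:
    """Trait = intercept + regulator_effect * (regulator latent
    expression) + sex/batch/weight terms + N(0, trait_noise_sd^2).

    With ``regulator_effect < 0`` the regulator is negatively correlated
    with the trait after covariate adjustment.
    """
    if config.regulator_gene not in expr.gene_ids:
        raise ValueError(f"regulator gene {config.regulator_gene} not simulated")
    rng = config.rng("trait")
    ces = config.covariate_effect_sizes
    reg_latent = latent_expression(
        expr.subset_genes([expr.gene_index(config.regulator_gene)]), config
    )[0]
    levels = sorted(set(cov.batch.tolist()))
    batch_eff = {b: rng.normal(0.0, ces.batch_trait_sd) for b in levels}
    trait = (
        config.trait_intercept
        + config.regulator_effect * (reg_latent - reg_latent.mean())
        + np.where(cov.sex == "F", ces.sex_trait, 0.0)
        + np.asarray([batch_eff[b] for b in cov.batch])
        + ces.weight_trait * (cov.carcass_weight - config.weight_mean)
        + rng.normal(0.0, config.trait_noise_sd, cov.n_samples)
    )
    return SampleCovariates(
        sample_ids=list(cov.sample_ids),
        sex=cov.sex,
        batch=cov.batch,
        carcass_weight=cov.carcass_weight,
        trait=trait,
    )


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------


def make_dataset(config: SimulationConfig, outdir: str) -> dict[str, str]:
    """Write the full synthetic dataset: VCF, expression + annotation
    TSVs, covariates TSV (with trait), a GWAS summary TSV produced by the
    single-SNP trait scan on the simulated cohort, and a ground-truth
    JSON (planted pairs, regulator, retained-SNP flags, truth interval).
    """
    from .pqtl import gwas_scan  # deferred: pqtl imports eqtl machinery

    os.makedirs(outdir, exist_ok=True)
    geno = simulate_genotypes(config)
    cov = simulate_covariates(config)
    expr = simulate_expression(geno, cov, config)
    cov_t = simulate_trait(expr, cov, config)
    gwas = gwas_scan(geno, cov_t)
    geno_out = mask_missing(geno, config)

    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "gwas": os.path.join(outdir, "gwas_summary.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(geno_out, paths["vcf"])
    write_expression(expr, paths["expression"], annotation_path=paths["annotation"])
    write_covariates(cov_t, paths["covariates"])
    write_gwas(gwas, paths["gwas"])

    maf = geno.maf()
    block_pos = config.block_positions(*config.regulator_block)
    truth = {
        "schema_version": 1,
        "seed": int(config.seed),
        "regulator_gene": config.regulator_gene,
        "regulator_effect": config.regulator_effect,
        "planted_pairs": [
            {
                "snp_id": config.planted_snp_id(e),
                "chrom": e.chrom,
                "pos": config.planted_snp_pos(e),
                "gene": e.gene,
                "beta": e.beta,
                "cis": e.cis,
            }
            for e in config.eqtl_plan
        ],
        "regulator_block": {
            "chrom": config.regulator_block[0],
            "start": int(block_pos[0]),
            "end": int(block_pos[-1]),
            "snp_ids": [
                f"snp_{config.regulator_block[0]}_{config.regulator_block[1]:02d}_{s}"
                for s in range(config.ld_block_sizes)
            ],
        },
        "snp_retained": {sid: bool(m >= 0.05) for sid, m in zip(geno.snp_ids, maf)},
        "modules": {g: m for g, m in config.module_of().items() if m is not None},
        "unexpressed_genes": config.gene_ids()[config.n_genes:],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
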