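"""Shared in-memory data model and readers/writers for external formats.

Internal genomic coordinates are 1-based inclusive throughout (the VCF
convention); only BED export converts to 0-based half-open. Missing
genotype dosages are represented as ``numpy.nan``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "SampleCovariates",
    "GwasSummary",
    "GenomicInterval",
    "read_genotypes",
    "write_vcf",
    "read_expression",
    "read_annotation",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_gwas",
    "write_gwas",
    "write_intervals",
    "align_samples",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix (alt-allele counts 0/1/2, NaN = missing).

    ``chrom``/``pos`` give per-SNP 1-based map positions, sorted ascending
    within each chromosome.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # per-SNP, dtype object/str
    pos: np.ndarray  # per-SNP, int, 1-based
    dosage: np.ndarray  # (n_samples, n_snps) float, NaN = missing
    ref: np.ndarray | None = None  # per-SNP reference allele (optional)
    alt: np.ndarray | None = None  # per-SNP alternative allele (optional)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids are not unique")
        if self.pos.size and self.pos.min() < 1:
            raise ValueError("positions must be >= 1 (1-based)")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"dosage not in {{0,1,2,NaN}} at {tuple(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_alt = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset_snps(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.arange(self.n_snps)[mask_or_idx]
        return replace(
            self,
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx],
            ref=None if self.ref is None else self.ref[idx],
            alt=None if self.alt is None else self.alt[idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), dosage=self.dosage[idx, :])


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with per-gene TSS annotation.

    ``scale`` tags the measurement scale ('counts', 'fpkm', 'tpm', 'log2',
    'normalized'); raw scales must be non-negative. The TSS is the gene
    start for '+' strand genes and the gene end for '-' strand genes.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_genes, n_samples)
    scale: str = "fpkm"
    chrom: np.ndarray | None = None  # per-gene
    start: np.ndarray | None = None  # per-gene, 1-based
    end: np.ndarray | None = None
    strand: np.ndarray | None = None  # '+'/'-'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if self.scale in ("counts", "fpkm", "tpm") and np.nanmin(self.values, initial=0) < 0:
            raise ValueError(f"negative values on raw scale '{self.scale}'")
        for name in ("chrom", "start", "end", "strand"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=object if name in ("chrom", "strand") else np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_annotation(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    def tss(self) -> np.ndarray:
        """Per-gene transcription start site: start on '+', end on '-'."""
        if not self.has_annotation:
            raise ValueError("expression matrix carries no gene annotation")
        strand = self.strand if self.strand is not None else np.full(self.n_genes, "+", dtype=object)
        return np.where(strand == "-", self.end, self.start).astype(np.int64)

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.arange(self.n_genes)[mask_or_idx]
        sub = lambda a: None if a is None else a[idx]
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx, :],
            chrom=sub(self.chrom),
            start=sub(self.start),
            end=sub(self.end),
            strand=sub(self.strand),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[:, idx])

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


@dataclass
class SampleCovariates:
    """Per-sample fixed effects (sex, slaughter batch), carcass weight and
    optionally the quantitative trait (intramuscular fat content, %)."""

    sample_ids: list[str]
    sex: np.ndarray  # categorical labels
    batch: np.ndarray  # categorical labels
    carcass_weight: np.ndarray  # kg, continuous
    trait: np.ndarray | None = None  # IMF %, optional

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.sex = np.asarray(self.sex, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        self.carcass_weight = np.asarray(self.carcass_weight, dtype=float)
        if self.trait is not None:
            self.trait = np.asarray(self.trait, dtype=float)
        for name in ("sex", "batch", "carcass_weight"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != {n} samples")
        if self.trait is not None and len(self.trait) != n:
            raise ValueError(f"trait length != {n} samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "SampleCovariates":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in sample_ids]
        return SampleCovariates(
            sample_ids=list(sample_ids),
            sex=self.sex[idx],
            batch=self.batch[idx],
            carcass_weight=self.carcass_weight[idx],
            trait=None if self.trait is None else self.trait[idx],
        )

    def design_matrix(self, include_weight: bool = True) -> tuple[np.ndarray, list[str]]:
        """Covariate design: intercept, dummy(sex), dummy(batch), weight.

        Dummies drop the first (reference) level; collinear columns are the
        caller's concern. Returns (matrix, column names).
        """
        cols: list[np.ndarray] = [np.ones(self.n_samples)]
        names = ["intercept"]
        for label, values in (("sex", self.sex), ("batch", self.batch)):
            levels = sorted(set(values.tolist()))
            for lev in levels[1:]:
                cols.append((values == lev).astype(float))
                names.append(f"{label}[{lev}]")
        if include_weight:
            cols.append(self.carcass_weight.astype(float))
            names.append("carcass_weight")
        return np.column_stack(cols), names


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics: chromosome, 1-based position, p."""

    chrom: np.ndarray
    pos: np.ndarray
    p_value: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.p_value = np.asarray(self.p_value, dtype=float)
        if not ((self.p_value > 0) & (self.p_value <= 1)).all():
            raise ValueError("p-values must lie in (0, 1]")
        # stable sort by (chrom, pos)
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.p_value = self.p_value[order]
        if self.snp_ids is not None:
            self.snp_ids = [self.snp_ids[i] for i in order]

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c))
        return list(seen)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int | np.ndarray):
        """Inclusive membership test; vectorized over ``pos``."""
        same = np.asarray(chrom, dtype=object) == self.chrom
        return same & (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_genotypes(path: str) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    Dosage is the alternative-allele count (0/1/2); missing calls become
    NaN. Multiallelic records are skipped with a warning. Raises on files
    with no biallelic records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic record(s) in %s", n_multi, path)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions),
        dosage=np.column_stack(rows),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write a dosage matrix as a minimal GT-only VCF (uncompressed)."""
    ref = geno.ref if geno.ref is not None else np.full(geno.n_snps, "A", dtype=object)
    alt = geno.alt if geno.alt is not None else np.full(geno.n_snps, "G", dtype=object)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    contigs: dict[str, None] = {}
    for c in geno.chrom:
        contigs.setdefault(str(c))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.sample_ids) + "\n")
        for j in range(geno.n_snps):
            calls = [
                "./." if np.isnan(d) else gt_of[d] for d in geno.dosage[:, j]
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# expression / annotation
# ---------------------------------------------------------------------------


def read_expression(path: str, annotation: str | None = None, scale: str = "fpkm") -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column gene id).

    If ``annotation`` is given (TSV: gene_id, chrom, start, end, strand),
    genes are aligned to it by id; genes absent from the annotation are
    dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    expr = ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        scale=scale,
    )
    if annotation is not None:
        ann = read_annotation(annotation)
        have = [g for g in expr.gene_ids if g in ann.index]
        missing = expr.n_genes - len(have)
        if missing:
            logger.warning("%d gene(s) absent from annotation dropped", missing)
        expr = expr.subset_genes([expr.gene_index(g) for g in have])
        sub = ann.loc[expr.gene_ids]
        expr.chrom = sub["chrom"].to_numpy(dtype=object)
        expr.start = sub["start"].to_numpy(dtype=np.int64)
        expr.end = sub["end"].to_numpy(dtype=np.int64)
        expr.strand = sub["strand"].to_numpy(dtype=object)
    return expr


def read_annotation(path: str) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, start, end, strand)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation missing columns: {sorted(required - set(ann.columns))}")
    return ann.set_index("gene_id")


def write_expression(expr: ExpressionMatrix, path: str, annotation_path: str | None = None) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if annotation_path is not None:
        if not expr.has_annotation:
            raise ValueError("expression matrix carries no annotation to write")
        strand = expr.strand if expr.strand is not None else np.full(expr.n_genes, "+", dtype=object)
        ann = pd.DataFrame(
            {
                "gene_id": expr.gene_ids,
                "chrom": expr.chrom,
                "start": expr.start,
                "end": expr.end,
                "strand": strand,
            }
        )
        ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# covariates / trait
# ---------------------------------------------------------------------------


def read_covariates(path: str) -> SampleCovariates:
    """Read covariates TSV: sample_id, sex, batch, carcass_weight[, trait]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str, "batch": str})
    required = {"sample_id", "sex", "batch", "carcass_weight"}
    if not required <= set(df.columns):
        raise ValueError(f"covariates missing columns: {sorted(required - set(df.columns))}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in covariates")
    return SampleCovariates(
        sample_ids=df["sample_id"].tolist(),
        sex=df["sex"].to_numpy(dtype=object),
        batch=df["batch"].to_numpy(dtype=object),
        carcass_weight=df["carcass_weight"].to_numpy(dtype=float),
        trait=df["trait"].to_numpy(dtype=float) if "trait" in df.columns else None,
    )


def write_covariates(cov: SampleCovariates, path: str) -> None:
    data = {
        "sample_id": cov.sample_ids,
        "sex": cov.sex,
        "batch": cov.batch,
        "carcass_weight": cov.carcass_weight,
    }
    if cov.trait is not None:
        data["trait"] = cov.trait
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GWAS summary / intervals
# ---------------------------------------------------------------------------


def read_gwas(path: str) -> GwasSummary:
    """Read GWAS summary TSV (chrom, pos, p[, snp_id]).

    Duplicate (chrom, pos) records keep the first occurrence with a
    warning. p outside (0, 1] is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"GWAS summary missing columns: {sorted(required - set(df.columns))}")
    bad = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} GWAS p-value(s) outside (0, 1]")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        logger.warning("dropping %d duplicate (chrom,pos) GWAS record(s), keeping first", int(dup.sum()))
        df = df[~dup]
    return GwasSummary(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        p_value=df["p"].to_numpy(dtype=float),
        snp_ids=df["snp_id"].tolist() if "snp_id" in df.columns else None,
    )


def write_gwas(gwas: GwasSummary, path: str) -> None:
    data = {"chrom": gwas.chrom, "pos": gwas.pos, "p": gwas.p_value}
    if gwas.snp_ids is not None:
        data["snp_id"] = gwas.snp_ids
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_intervals(intervals: list[GenomicInterval], path: str) -> None:
    """Write intervals as BED (0-based half-open converted from 1-based)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_samples(*objs):
    """Subset all objects to their common samples, in sorted id order.

    Accepts any mix of GenotypeMatrix / ExpressionMatrix / SampleCovariates.
    """
    common: set[str] | None = None
    for o in objs:
        ids = set(o.sample_ids)
        common = ids if common is None else (common & ids)
    if not common:
        raise ValueError("no samples shared by all inputs")
    ordered = sorted(common)
    return tuple(o.subset_samples(ordered) for o in objs)
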