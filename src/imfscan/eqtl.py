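"""SNP/sample QC and per-pair genotype-expression association.

The association model is the additive covariate-adjusted linear model

    g = beta * S + bw + se + ba + eps

where ``g`` is the rank-normalized expression of one gene, ``S`` the SNP
dosage (0/1/2 alternative-allele count), ``bw`` carcass weight (continuous),
``se`` sex and ``ba`` slaughter batch (dummy-coded fixed effects), and
``eps`` the residual. Each gene-SNP pair is fitted by OLS; the SNP t
statistic on residual degrees of freedom gives a two-sided p-value, and
Benjamini-Hochberg q-values are computed over all fitted pairs.

SNPs within 1 Mb (inclusive) of a gene's transcription start site are
cis; all others trans. By default only cis pairs are fitted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, GenotypeMatrix, SampleCovariates

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "QcReport",
    "qc_genotypes",
    "fit_association",
    "classify_relation",
    "bh_fdr",
    "run_scan",
    "CIS_WINDOW",
    "P_GENOMEWIDE",
    "P_SUGGESTIVE",
]

CIS_WINDOW = 1_000_000
P_GENOMEWIDE = 5e-8
P_SUGGESTIVE = 5e-6

# standard chromosome labels: autosomes and sex chromosomes, optional "chr"
# prefix; everything else (MT, scaffolds, contigs) is non-chromosomal
_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYZW])$", re.IGNORECASE)


@dataclass
class AssociationRecord:
    """One SNP x gene (or SNP x trait) test result."""

    snp_id: str
    gene_id: str  # "TRAIT" for trait associations
    beta: float
    se_beta: float
    t_stat: float
    p_value: float
    n_used: int
    q_value: float = np.nan
    relation: str | None = None  # 'cis' / 'trans' when the gene has a TSS


@dataclass
class QcReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    n_removed_ind_missing: int
    n_removed_nonchrom: int
    n_removed_snp_missing: int
    n_removed_maf: int

    def __post_init__(self) -> None:
        if self.n_samples_in - self.n_removed_ind_missing != self.n_samples_out:
            raise ValueError("sample counts inconsistent")
        removed = self.n_removed_nonchrom + self.n_removed_snp_missing + self.n_removed_maf
        if self.n_snps_in - removed != self.n_snps_out:
            raise ValueError("SNP counts inconsistent")


def is_chromosomal(chrom: str) -> bool:
    return _CHROM_RE.match(str(chrom)) is not None


def qc_genotypes(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_miss_max: float = 0.1,
    ind_miss_max: float = 0.1,
    drop_nonchrom: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply sample and SNP quality filters.

    Individuals with missing rate > ``ind_miss_max`` are excluded first;
    SNP filters (non-chromosomal contigs, missing rate > ``snp_miss_max``,
    MAF < ``maf_min``) are then evaluated on the retained individuals.
    All inequalities are strict, so boundary values are retained. MAF is
    computed from non-missing dosages.
    """
    miss = np.isnan(geno.dosage)
    ind_rate = miss.mean(axis=1)
    keep_ind = ind_rate <= ind_miss_max
    if not keep_ind.any():
        raise ValueError("all samples removed by individual missing-rate filter")
    kept_samples = [s for s, k in zip(geno.sample_ids, keep_ind) if k]
    g = geno.subset_samples(kept_samples)

    n_in = g.n_snps
    alive = np.ones(n_in, dtype=bool)
    if drop_nonchrom:
        chromosomal = np.fromiter((is_chromosomal(c) for c in g.chrom), bool, n_in)
    else:
        chromosomal = np.ones(n_in, dtype=bool)
    n_nonchrom = int((~chromosomal).sum())
    alive &= chromosomal

    snp_rate = np.isnan(g.dosage).mean(axis=0)
    miss_ok = snp_rate <= snp_miss_max
    n_snp_miss = int((alive & ~miss_ok).sum())
    alive &= miss_ok

    maf = g.maf()
    maf_ok = np.nan_to_num(maf, nan=-1.0) >= maf_min
    n_maf = int((alive & ~maf_ok).sum())
    alive &= maf_ok

    report = QcReport(
        n_samples_in=geno.n_samples,
        n_samples_out=g.n_samples,
        n_snps_in=n_in,
        n_snps_out=int(alive.sum()),
        n_removed_ind_missing=int((~keep_ind).sum()),
        n_removed_nonchrom=n_nonchrom,
        n_removed_snp_missing=n_snp_miss,
        n_removed_maf=n_maf,
    )
    return g.subset_snps(alive), report


def _ols_with_pivot(X: np.ndarray, y: np.ndarray, protect: int):
    """OLS that drops collinear columns (never column ``protect``).

    Returns (coef on kept columns, kept column indices, df_resid, sigma2,
    XtX_inv) or None if the protected column itself is collinear with the
    rest.
    """
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    keep = np.arange(k)
    if rank < k:
        # greedily keep columns that raise the rank, protected column first
        keep_list: list[int] = []
        cur = np.empty((n, 0))
        # protected and intercept-like columns first so they are never dropped
        order = [protect] + [j for j in range(k) if j != protect]
        for j in order:
            trial = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(trial) > cur.shape[1]:
                cur = trial
                keep_list.append(j)
        if protect not in keep_list:
            return None
        keep = np.array(sorted(keep_list))
        logger.warning("dropped %d collinear design column(s)", k - len(keep))
        X = X[:, keep]
        k = X.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - k
    if df <= 0:
        return None
    sigma2 = float(resid @ resid) / df
    return coef, keep, df, sigma2, XtX_inv


def fit_association(
    g: np.ndarray,
    S: np.ndarray,
    cov: SampleCovariates,
    snp_id: str = "",
    gene_id: str = "",
    missing: str = "mean_impute",
) -> AssociationRecord | None:
    """OLS of expression (or trait) on [1, S, carcass weight, sex, batch].

    Missing dosages are mean-imputed per SNP by default (``missing=
    'complete_case'`` drops those samples instead). Returns None when the
    SNP is constant in the usable samples or the fit is degenerate; design
    columns collinear with the rest (e.g. a batch confounded with sex) are
    dropped with a warning.
    """
    g = np.asarray(g, dtype=float)
    S = np.asarray(S, dtype=float)
    mask = ~np.isnan(g)
    if missing == "complete_case":
        mask &= ~np.isnan(S)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete samples, got {n}")
    idx = np.flatnonzero(mask)
    s_use = S[idx].copy()
    if np.isnan(s_use).any():
        m = np.nanmean(s_use)
        if np.isnan(m):
            return None
        s_use[np.isnan(s_use)] = m
    if np.ptp(s_use) == 0:
        logger.warning("constant dosage for %s, pair skipped", snp_id or "SNP")
        return None
    C, _ = cov.subset_samples([cov.sample_ids[i] for i in idx]).design_matrix()
    X = np.column_stack([C[:, :1], s_use, C[:, 1:]])  # [1, S, covariates]
    fit = _ols_with_pivot(X, g[idx], protect=1)
    if fit is None:
        logger.warning("degenerate design for %s x %s, pair skipped", snp_id, gene_id)
        return None
    coef, keep, df, sigma2, XtX_inv = fit
    j = int(np.flatnonzero(keep == 1)[0])
    beta = float(coef[j])
    se = float(np.sqrt(sigma2 * XtX_inv[j, j]))
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationRecord(
        snp_id=snp_id,
        gene_id=gene_id,
        beta=beta,
        se_beta=se,
        t_stat=float(t),
        p_value=max(p, np.nextafter(0, 1)),
        n_used=n,
    )


def classify_relation(
    snp: tuple[str, int],
    tss: tuple[str, int],
    window: int = CIS_WINDOW,
) -> str:
    """'cis' iff same chromosome and |pos - tss| <= window (inclusive)."""
    (c1, p1), (c2, p2) = snp, tss
    return "cis" if str(c1) == str(c2) and abs(int(p1) - int(p2)) <= window else "trans"


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    cov: SampleCovariates,
    mode: str = "cis_only",
    window: int = CIS_WINDOW,
    p_genomewide: float = P_GENOMEWIDE,
    p_suggestive: float = P_SUGGESTIVE,
    missing: str = "mean_impute",
) -> pd.DataFrame:
    """Fit the additive model for every (cis) gene-SNP pair.

    Returns a table with one row per fitted pair: effect size, t, p, BH q
    over all fitted pairs, cis/trans relation, and strict-threshold flags
    ``significant_gw`` (p < ``p_genomewide``) and ``significant_sugg``
    (p < ``p_suggestive``).
    """
    if mode not in ("cis_only", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if expr.n_genes == 0:
        raise ValueError("empty expression matrix")
    if list(expr.sample_ids) != list(geno.sample_ids) or list(expr.sample_ids) != list(cov.sample_ids):
        raise ValueError("inputs must be sample-aligned (use dataio.align_samples)")
    tss = expr.tss()
    rows: list[dict] = []
    for gi, gene in enumerate(expr.gene_ids):
        gene_chrom = str(expr.chrom[gi])
        same = np.fromiter((str(c) == gene_chrom for c in geno.chrom), bool, geno.n_snps)
        is_cis = same & (np.abs(geno.pos - tss[gi]) <= window)
        snp_idx = np.flatnonzero(is_cis) if mode == "cis_only" else np.arange(geno.n_snps)
        for sj in snp_idx:
            rec = fit_association(
                expr.values[gi], geno.dosage[:, sj], cov,
                snp_id=geno.snp_ids[sj], gene_id=gene, missing=missing,
            )
            if rec is None:
                continue
            rows.append(
                {
                    "snp_id": rec.snp_id,
                    "gene_id": gene,
                    "chrom_snp": str(geno.chrom[sj]),
                    "pos_snp": int(geno.pos[sj]),
                    "chrom_gene": gene_chrom,
                    "tss": int(tss[gi]),
                    "beta": rec.beta,
                    "se": rec.se_beta,
                    "t": rec.t_stat,
                    "p": rec.p_value,
                    "n_used": rec.n_used,
                    "relation": "cis" if is_cis[sj] else "trans",
                }
            )
    if not rows:
        logger.warning("no fittable %s pairs", "cis" if mode == "cis_only" else "")
        return pd.DataFrame(
            columns=[
                "snp_id", "gene_id", "chrom_snp", "pos_snp", "chrom_gene", "tss",
                "beta", "se", "t", "p", "n_used", "relation", "q",
                "significant_gw", "significant_sugg",
            ]
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant_gw"] = table["p"] < p_genomewide
    table["significant_sugg"] = table["p"] < p_suggestive
    return table
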