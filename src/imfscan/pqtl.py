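"""GWAS-side machinery: trait association, 2-LOD support intervals, LD
blocks, colocalization with cis-eQTLs, permutation tests and
genotype-stratified trait comparison.

The support interval follows the 2-LOD drop convention where one unit of
-log10(p) approximates one LOD unit: SNPs whose LOD exceeds the
chromosome peak minus the drop are retained, and the interval spans the
contiguous retained run containing the peak. LD r^2 is the squared
Pearson correlation of genotype dosages (composite LD), and blocks are
maximal contiguous runs with all pairwise r^2 above threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenomicInterval, GenotypeMatrix, GwasSummary, SampleCovariates
from .eqtl import P_SUGGESTIVE, fit_association

logger = logging.getLogger(__name__)

__all__ = [
    "LodProfile",
    "LdBlock",
    "gwas_scan",
    "lod_profile_from_summary",
    "lod_drop_interval",
    "ld_r2",
    "find_ld_blocks",
    "colocalize",
    "permutation_assoc",
    "genotype_stratified_test",
]


@dataclass
class LodProfile:
    """Per-chromosome LOD (= -log10 p) profile in map order."""

    chrom: str
    pos: np.ndarray
    lod: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.lod = np.asarray(self.lod, dtype=float)
        if self.pos.size == 0:
            raise ValueError("empty LOD profile")
        if self.pos.size != self.lod.size:
            raise ValueError("pos and lod lengths differ")
        if (self.lod < 0).any():
            raise ValueError("LOD scores must be >= 0")
        order = np.argsort(self.pos, kind="mergesort")
        self.pos = self.pos[order]
        self.lod = self.lod[order]

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.lod))


@dataclass
class LdBlock:
    """Contiguous run of SNPs with all pairwise dosage r^2 above threshold."""

    chrom: str
    snp_indices: list[int]  # indices into the source GenotypeMatrix, contiguous
    snp_ids: list[str]
    start: int
    end: int
    min_r2: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def gwas_scan(
    geno: GenotypeMatrix,
    cov: SampleCovariates,
    missing: str = "mean_impute",
) -> GwasSummary:
    """Per-SNP linear association of the trait with dosage, adjusting for
    sex, batch and carcass weight (the same additive model as the eQTL
    scan with the trait as response)."""
    if cov.trait is None:
        raise ValueError("covariates carry no trait")
    if np.ptp(cov.trait) == 0:
        raise ValueError("constant trait")
    if list(geno.sample_ids) != list(cov.sample_ids):
        raise ValueError("inputs must be sample-aligned")
    chroms, positions, pvals, ids = [], [], [], []
    for j in range(geno.n_snps):
        rec = fit_association(
            cov.trait, geno.dosage[:, j], cov,
            snp_id=geno.snp_ids[j], gene_id="TRAIT", missing=missing,
        )
        if rec is None:
            continue
        chroms.append(str(geno.chrom[j]))
        positions.append(int(geno.pos[j]))
        pvals.append(rec.p_value)
        ids.append(geno.snp_ids[j])
    if not pvals:
        raise ValueError("no SNP could be tested against the trait")
    return GwasSummary(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions),
        p_value=np.asarray(pvals),
        snp_ids=ids,
    )


def lod_profile_from_summary(gwas: GwasSummary, chrom: str) -> LodProfile:
    """LOD profile for one chromosome: LOD = -log10(p)."""
    mask = np.fromiter((str(c) == str(chrom) for c in gwas.chrom), bool, gwas.n_snps)
    if not mask.any():
        raise ValueError(f"no GWAS records on chromosome {chrom}")
    return LodProfile(chrom=str(chrom), pos=gwas.pos[mask], lod=-np.log10(gwas.p_value[mask]))


def lod_drop_interval(
    profile: LodProfile,
    drop: float = 2.0,
    span_all: bool = False,
) -> GenomicInterval:
    """Support interval from the LOD-drop rule.

    SNPs with LOD strictly above (peak LOD - drop) are retained. By
    default the interval spans the maximal contiguous retained run
    containing the peak; ``span_all=True`` spans every retained SNP on
    the chromosome instead.
    """
    peak = profile.peak_index
    retained = profile.lod > profile.lod[peak] - drop
    if span_all:
        pos = profile.pos[retained]
        lo, hi = int(pos.min()), int(pos.max())
    else:
        lo_i = peak
        while lo_i > 0 and retained[lo_i - 1]:
            lo_i -= 1
        hi_i = peak
        while hi_i < retained.size - 1 and retained[hi_i + 1]:
            hi_i += 1
        lo, hi = int(profile.pos[lo_i]), int(profile.pos[hi_i])
    return GenomicInterval(
        chrom=profile.chrom, start=lo, end=hi,
        label=f"lod_drop_{drop:g}@peak={int(profile.pos[peak])}",
    )


def ld_r2(geno: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of two SNPs' dosage vectors
    (pairwise-complete samples). NaN for monomorphic SNPs."""
    a = geno.dosage[:, snp_i]
    b = geno.dosage[:, snp_j]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def find_ld_blocks(
    geno: GenotypeMatrix,
    region: GenomicInterval | None = None,
    r2_min: float = 0.90,
) -> list[LdBlock]:
    """Greedy contiguous LD blocks: scanning left to right in map order, a
    block is extended while the next SNP has r^2 > ``r2_min`` with every
    current member. Monomorphic SNPs are excluded with a warning; only
    blocks of two or more SNPs are reported.
    """
    if region is not None:
        in_region = region.contains(region.chrom, geno.pos) & np.fromiter(
            (str(c) == region.chrom for c in geno.chrom), bool, geno.n_snps
        )
        candidates = np.flatnonzero(in_region)
    else:
        candidates = np.arange(geno.n_snps)
    poly = []
    for j in candidates:
        col = geno.dosage[:, j]
        col = col[~np.isnan(col)]
        if col.size >= 2 and np.ptp(col) > 0:
            poly.append(int(j))
        else:
            logger.warning("monomorphic SNP %s excluded from LD blocks", geno.snp_ids[j])
    blocks: list[LdBlock] = []
    i = 0
    while i < len(poly):
        members = [poly[i]]
        k = i + 1
        while k < len(poly):
            # contiguity in map order: candidate must be the next retained SNP
            cand = poly[k]
            r2s = [ld_r2(geno, m, cand) for m in members]
            if all(r2 > r2_min for r2 in r2s):
                members.append(cand)
                k += 1
            else:
                break
        if len(members) >= 2:
            pair_r2 = [
                ld_r2(geno, a, b)
                for ai, a in enumerate(members)
                for b in members[ai + 1:]
            ]
            blocks.append(
                LdBlock(
                    chrom=str(geno.chrom[members[0]]),
                    snp_indices=members,
                    snp_ids=[geno.snp_ids[m] for m in members],
                    start=int(geno.pos[members[0]]),
                    end=int(geno.pos[members[-1]]),
                    min_r2=float(min(pair_r2)),
                )
            )
        i += len(members) if len(members) >= 2 else 1
    return blocks


def colocalize(
    pqtl: GenomicInterval,
    eqtl_records: pd.DataFrame,
    p_max: float = P_SUGGESTIVE,
) -> pd.DataFrame:
    """Per-gene overlap of significant cis-eQTLs with a pQTL interval.

    For each gene with at least one significant cis-eQTL (p < ``p_max``),
    reports the count and ids of its significant cis-eQTL SNPs inside the
    interval (inclusive ends), the spanning eQTL region [min, max] of all
    its significant cis-eQTL positions on the interval's chromosome, and
    that span's overlap (bp) with the pQTL. Sorted by in-interval count.
    """
    cols = ["gene_id", "n_eqtls_in_interval", "snp_ids", "span_start", "span_end", "span_overlap_bp"]
    if eqtl_records.empty:
        return pd.DataFrame(columns=cols)
    sig = eqtl_records[
        (eqtl_records["relation"] == "cis") & (eqtl_records["p"] < p_max)
    ]
    rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        on_chrom = grp[grp["chrom_snp"].astype(str) == pqtl.chrom]
        if on_chrom.empty:
            continue
        inside = on_chrom[
            (on_chrom["pos_snp"] >= pqtl.start) & (on_chrom["pos_snp"] <= pqtl.end)
        ]
        span_start = int(on_chrom["pos_snp"].min())
        span_end = int(on_chrom["pos_snp"].max())
        overlap = max(0, min(span_end, pqtl.end) - max(span_start, pqtl.start) + 1)
        if inside.empty and overlap == 0:
            continue
        rows.append(
            {
                "gene_id": gene,
                "n_eqtls_in_interval": int(len(inside)),
                "snp_ids": ",".join(inside["snp_id"].astype(str)),
                "span_start": span_start,
                "span_end": span_end,
                "span_overlap_bp": overlap,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    if not out.empty:
        out = out.sort_values(
            ["n_eqtls_in_interval", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def _covariate_residual_maker(cov: SampleCovariates) -> tuple[np.ndarray, int]:
    C, _ = cov.design_matrix()
    # drop collinear covariate columns so the projector is well defined
    if np.linalg.matrix_rank(C) < C.shape[1]:
        keep, cur = [], np.empty((C.shape[0], 0))
        for j in range(C.shape[1]):
            trial = np.column_stack([cur, C[:, j]])
            if np.linalg.matrix_rank(trial) > cur.shape[1]:
                cur, keep = trial, keep + [j]
        C = C[:, keep]
    M = np.eye(C.shape[0]) - C @ np.linalg.solve(C.T @ C, C.T)
    return M, C.shape[1]


def permutation_assoc(
    geno: GenotypeMatrix,
    snp_indices: list[int],
    cov: SampleCovariates,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation association of selected SNPs with the trait.

    The observed statistic is |t| from the additive trait ~ S + covariates
    model. Covariate-adjusted trait residuals are permuted (Freedman-Lane
    style), the model refitted, and the add-one empirical p computed both
    pointwise and family-wise (per-permutation max |t| over the SNP set).
    """
    if cov.trait is None:
        raise ValueError("covariates carry no trait")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = cov.trait.astype(float)
    n = y.size
    M, k_cov = _covariate_residual_maker(cov)
    e = M @ y
    df = n - k_cov - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    # residualized, mean-imputed dosages for the selected SNPs
    U = []
    for j in snp_indices:
        s = geno.dosage[:, j].copy()
        if np.isnan(s).any():
            s[np.isnan(s)] = np.nanmean(s)
        U.append(M @ s)
    U = np.column_stack(U)  # n x k
    norm_u = np.linalg.norm(U, axis=0)
    if (norm_u == 0).any():
        raise ValueError("selected SNP constant after covariate adjustment")

    def tstats(resid_cols: np.ndarray) -> np.ndarray:
        """|t| of each SNP against each residual column: (k, B)."""
        dots = U.T @ resid_cols  # k x B
        ss_y = (resid_cols ** 2).sum(axis=0)  # B
        b = dots / (norm_u[:, None] ** 2)
        ss_res = ss_y[None, :] - (dots ** 2) / (norm_u[:, None] ** 2)
        ss_res = np.maximum(ss_res, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b * norm_u[:, None] / np.sqrt(ss_res / df)
        t[~np.isfinite(t)] = np.inf
        return np.abs(t)

    t_obs = tstats(e[:, None])[:, 0]  # k
    # permute residuals in manageable chunks to bound memory
    count_point = np.zeros(len(snp_indices))
    max_perm = np.empty(n_perm)
    done = 0
    chunk = max(1, min(n_perm, 20_000))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        P = np.empty((n, b))
        for c in range(b):
            P[:, c] = e[rng.permutation(n)]
        t_perm = tstats(M @ P)  # k x b
        count_point += (t_perm >= t_obs[:, None]).sum(axis=1)
        max_perm[done:done + b] = t_perm.max(axis=0)
        done += b
    p_point = (1.0 + count_point) / (n_perm + 1.0)
    p_family = (1.0 + (max_perm[None, :] >= t_obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "snp_id": [geno.snp_ids[j] for j in snp_indices],
            "t_obs": t_obs,
            "p_perm": p_point,
            "p_perm_family": p_family,
        }
    )


def genotype_stratified_test(
    S: np.ndarray,
    trait: np.ndarray,
    equal_var: bool = True,
) -> dict:
    """Raw (unadjusted) per-genotype trait means +/- SE and a two-group t-test.

    Classes are the dosage levels present (0/1/2). SE = sd/sqrt(n) with
    sample sd (ddof=1); singleton classes are reported mean-only. The
    unpaired two-tailed t-test compares the two largest classes (ties
    broken toward lower dosage).
    """
    S = np.asarray(S, dtype=float)
    trait = np.asarray(trait, dtype=float)
    ok = ~(np.isnan(S) | np.isnan(trait))
    S, trait = S[ok], trait[ok]
    classes = {}
    for level in (0.0, 1.0, 2.0):
        vals = trait[S == level]
        if vals.size == 0:
            continue
        classes[int(level)] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else None,
            "values": vals,
        }
    testable = [g for g, c in classes.items() if c["n"] >= 2]
    if len(testable) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 members")
    top2 = sorted(classes, key=lambda g: (-classes[g]["n"], g))[:2]
    if any(classes[g]["n"] < 2 for g in top2):
        top2 = sorted(testable, key=lambda g: (-classes[g]["n"], g))[:2]
    t, p = stats.ttest_ind(
        classes[top2[0]]["values"], classes[top2[1]]["values"], equal_var=equal_var
    )
    out = {
        "classes": {
            g: {k: v for k, v in c.items() if k != "values"} for g, c in classes.items()
        },
        "compared": tuple(sorted(top2)),
        "t": float(t),
        "p": float(p),
    }
    return out
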