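"""Covariate-adjusted expression-trait correlation screen.

Both the trait and each gene's log2 expression are adjusted by OLS on
fixed effects (sex, slaughter batch) and the carcass-weight covariate;
Pearson correlation of the residuals, with a t-distribution p-value on
n - 2 degrees of freedom and Benjamini-Hochberg q across genes, flags
trait-associated genes at q <= 0.05. The trait is adjusted once globally
and reused across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, SampleCovariates
from .eqtl import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["CorrelationRecord", "adjust", "correlate_all", "log2_transform"]

Q_SIGNIFICANT = 0.05


@dataclass
class CorrelationRecord:
    gene_id: str
    r: float
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1 for {self.gene_id}")
        if self.significant != (self.q <= Q_SIGNIFICANT):
            raise ValueError("significance flag inconsistent with q")


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); the pseudocount avoids -inf at zero."""
    out = expr.subset_genes(slice(None))
    out.values = np.log2(expr.values + pseudocount)
    out.scale = "log2"
    return out


def adjust(values: np.ndarray, cov: SampleCovariates) -> np.ndarray:
    """Residuals of OLS on [1, dummy(sex), dummy(batch), carcass weight].

    Collinear dummy columns are dropped with a warning; residuals have
    mean zero by construction.
    """
    y = np.asarray(values, dtype=float)
    if y.size != cov.n_samples:
        raise ValueError("values not aligned to covariates")
    X, _ = cov.design_matrix()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep, cur = [], np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            trial = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(trial) > cur.shape[1]:
                cur, keep = trial, keep + [j]
        logger.warning("dropped %d collinear covariate column(s)", X.shape[1] - len(keep))
        X = X[:, keep]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _pearson_resid(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), 1.0
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, np.nextafter(0, 1)
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def correlate_all(
    expr: ExpressionMatrix,
    cov: SampleCovariates,
    q_max: float = Q_SIGNIFICANT,
) -> pd.DataFrame:
    """Adjusted Pearson correlation of every gene with the trait.

    ``expr`` is expected on the log2 scale (see :func:`log2_transform`).
    The p-value uses n - 2 degrees of freedom (plain Pearson test on
    residuals). Returns a table sorted by q then gene id.
    """
    if cov.trait is None:
        raise ValueError("covariates carry no trait")
    n = expr.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    if list(expr.sample_ids) != list(cov.sample_ids):
        raise ValueError("inputs must be sample-aligned")
    trait_resid = adjust(cov.trait, cov)
    df = n - 2
    rs, ps = [], []
    for i in range(expr.n_genes):
        gene_resid = adjust(expr.values[i], cov)
        r, p = _pearson_resid(gene_resid, trait_resid, df)
        rs.append(r)
        ps.append(p)
    table = pd.DataFrame({"gene_id": expr.gene_ids, "r": rs, "p": ps})
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] <= q_max
    return table.sort_values(["q", "gene_id"], kind="mergesort").reset_index(drop=True)
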