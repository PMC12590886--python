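"""Expression-level filtering and normalization preceding eQTL mapping.

The pipeline keeps genes expressed above 0.1 FPKM in a strict majority of
samples, then replaces each retained gene's TPM values by their rank-based
inverse-normal transform, which is the response entering the additive
eQTL model. Rank normalization makes downstream association invariant to
any strictly monotone per-gene rescaling of abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix

__all__ = [
    "NormalizationReport",
    "filter_expressed",
    "rank_inverse_normal",
    "compute_fpkm",
    "compute_tpm",
    "fpkm_to_tpm",
]


@dataclass
class NormalizationReport:
    n_genes_in: int
    n_genes_retained: int
    transform_name: str
    retained: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes_retained > self.n_genes_in:
            raise ValueError("retained more genes than supplied")

    def to_dict(self) -> dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_retained": self.n_genes_retained,
            "transform_name": self.transform_name,
            "retained": self.retained,
        }


def filter_expressed(
    expr: ExpressionMatrix,
    min_fpkm: float = 0.1,
    min_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Keep genes with abundance strictly above ``min_fpkm`` in strictly
    more than ``min_fraction`` of samples.

    Both comparisons are strict: a gene at exactly 0.1 FPKM everywhere is
    dropped, and with 80 samples "more than half" means at least 41.
    """
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise ValueError("empty expression matrix")
    n_above = (expr.values > min_fpkm).sum(axis=1)
    keep = n_above > min_fraction * expr.n_samples
    report = NormalizationReport(
        n_genes_in=expr.n_genes,
        n_genes_retained=int(keep.sum()),
        transform_name=f"expressed_filter(>{min_fpkm} in >{min_fraction} of samples)",
        retained={g: bool(k) for g, k in zip(expr.gene_ids, keep)},
    )
    return expr.subset_genes(keep), report


def rank_inverse_normal(expr: ExpressionMatrix, offset: float = 0.5) -> ExpressionMatrix:
    """Per-gene rank-based inverse-normal transform across samples.

    Each gene's values are replaced by Phi^-1((r - offset)/n) where r is
    the average rank (ties share their average), so an all-tied gene maps
    to zeros and any strictly monotone per-gene transform of the input
    yields identical output. Offset 0.5 is the default; Blom's 3/8 is the
    common alternative.
    """
    n = expr.n_samples
    if n < 3:
        raise ValueError(f"need >= 3 samples for rank normalization, got {n}")
    ranks = stats.rankdata(expr.values, axis=1, method="average")
    transformed = stats.norm.ppf((ranks - offset) / n)
    out = expr.subset_genes(slice(None))
    out.values = transformed
    out.scale = "normalized"
    return out


def _check_lengths(gene_lengths: np.ndarray) -> np.ndarray:
    gl = np.asarray(gene_lengths, dtype=float)
    if (gl <= 0).any():
        raise ValueError("gene lengths must be positive")
    return gl


def compute_fpkm(
    counts: ExpressionMatrix,
    gene_lengths: np.ndarray,
    library_sizes: np.ndarray | None = None,
) -> ExpressionMatrix:
    """FPKM = 1e9 * c / (L * N): fragments per kb of model per million mapped.

    ``library_sizes`` defaults to per-sample column sums of counts.
    """
    gl = _check_lengths(gene_lengths)
    if library_sizes is None:
        library_sizes = counts.values.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out = counts.subset_genes(slice(None))
    out.values = 1e9 * counts.values / (gl[:, None] * lib[None, :])
    out.scale = "fpkm"
    return out


def compute_tpm(counts: ExpressionMatrix, gene_lengths: np.ndarray) -> ExpressionMatrix:
    """TPM: length-normalized rates rescaled so each sample sums to 1e6."""
    gl = _check_lengths(gene_lengths)
    rate = counts.values / gl[:, None]
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("zero library size (all-zero sample)")
    out = counts.subset_genes(slice(None))
    out.values = 1e6 * rate / denom[None, :]
    out.scale = "tpm"
    return out


def fpkm_to_tpm(fpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM columns to sum to 1e6 (the standard FPKM->TPM identity)."""
    denom = fpkm.values.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("all-zero sample in FPKM matrix")
    out = fpkm.subset_genes(slice(None))
    out.values = 1e6 * fpkm.values / denom[None, :]
    out.scale = "tpm"
    return out
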