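"""Weighted co-expression network analysis, implemented from scratch.

The stage follows the classic weighted-network recipe: outlier samples
are removed by cutting an average-linkage sample dendrogram at a height;
a soft-threshold power is chosen by approximate scale-free topology fit;
adjacency |cor|^power is smoothed into a topological overlap matrix
(TOM); modules are clusters of the 1-TOM dendrogram (static height cut,
followed by iterative merging of modules with highly correlated
eigengenes); each module is summarized by its eigengene (first principal
component of the standardized module expression). Module-trait
relationships (MTR), per-gene gene significance (GS, gene-trait
correlation) and module membership (MM, gene-eigengene correlation)
identify critical genes: GS p and MM p both below 0.01 inside modules
with MTR p below 0.01.

Deviation from the reference recipe: the dynamic tree cut is replaced by
a static height cut plus eigengene merging, which recovers planted
module structure and keeps the stage dependency-free and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .dataio import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "detect_outlier_samples",
    "pick_soft_power",
    "adjacency_matrix",
    "tom_similarity",
    "cut_modules",
    "module_eigengene",
    "module_trait_relationships",
    "gene_statistics",
    "critical_genes",
    "coexpression_analysis",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    """Gene -> module labels with eigengenes and trait statistics."""

    labels: dict[str, str]  # gene_id -> module label (UNASSIGNED allowed)
    modules: list[str] = field(default_factory=list)
    eigengenes: dict[str, np.ndarray] = field(default_factory=dict)  # per-sample
    mtr: dict[str, tuple[float, float]] = field(default_factory=dict)  # (r, p)
    gene_stats: pd.DataFrame | None = None  # gs_r, gs_p, mm_r, mm_p, critical

    def members(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def detect_outlier_samples(
    expr: ExpressionMatrix,
    cut_height: float | None = None,
) -> tuple[list[str], float]:
    """Retain the largest sample cluster at a dendrogram cut.

    Samples are clustered by average linkage on Euclidean distance of
    expression profiles. When ``cut_height`` is not given it is placed
    inside the largest gap of the sorted merge heights above the median,
    provided that gap is large relative to the typical height (outliers
    join the tree far above the bulk); otherwise no sample is removed.
    Returns (retained sample ids, height used); raises if every cluster
    is a singleton at that height.
    """
    if expr.n_samples < 10:
        raise ValueError("need >= 10 samples for outlier detection")
    d = pdist(expr.values.T, metric="euclidean")
    Z = linkage(d, method="average")
    heights = Z[:, 2]
    if cut_height is None:
        hs = np.sort(heights)
        med = float(np.median(hs))
        gaps = np.diff(hs)
        upper = hs[:-1] >= med
        if upper.any() and gaps[upper].max() > 0.5 * med:
            i = int(np.flatnonzero(upper)[np.argmax(gaps[upper])])
            cut_height = float(hs[i] + 0.5 * gaps[i])
        else:
            cut_height = float(hs[-1] * 1.05)
    clusters = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(clusters).value_counts()
    if sizes.max() < 2:
        raise ValueError(
            f"all samples are singletons at height {cut_height:g}; use a larger cut height"
        )
    biggest = sizes.idxmax()
    retained = [s for s, c in zip(expr.sample_ids, clusters) if c == biggest]
    n_out = expr.n_samples - len(retained)
    if n_out:
        logger.info("removed %d outlier sample(s) at height %.4g", n_out, cut_height)
    return retained, float(cut_height)


def _drop_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    sd = expr.values.std(axis=1)
    if (sd == 0).any():
        logger.warning("excluding %d constant gene(s)", int((sd == 0).sum()))
        expr = expr.subset_genes(sd > 0)
    return expr


def adjacency_matrix(expr: ExpressionMatrix, power: float) -> np.ndarray:
    """Unsigned adjacency |cor(g_i, g_j)|^power with zero diagonal."""
    corr = np.corrcoef(expr.values)
    A = np.abs(corr) ** power
    np.fill_diagonal(A, 0.0)
    return A


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) vs log10(mean k) over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if kb.size == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(kb.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    if slope > 0:  # scale-free topology requires decreasing freq with k
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_soft_power(
    expr: ExpressionMatrix,
    candidate_powers=range(1, 21),
    r2_target: float = 0.8,
    fallback_power: int = 6,
    min_median_connectivity: float = 5.0,
) -> int:
    """Smallest power whose scale-free fit R^2 reaches ``r2_target``
    while the network keeps a workable mean connectivity.

    The fit R^2 is signed (zero when connectivity frequency increases
    with k), and powers whose median connectivity falls below
    ``min_median_connectivity`` are rejected: at such powers the typical
    gene is isolated (even when a well-connected core inflates the mean)
    and the apparent scale-free fit is an artifact of the empty graph. When no admissible candidate reaches the target —
    common for strongly modular expression, whose degree distribution
    is not scale-free — the reference tool's recommended unsigned
    default (``fallback_power``) is used rather than chasing the R^2
    argmax, which drifts to degenerate high powers. Deterministic.
    """
    if expr.n_genes < 50:
        raise ValueError("need >= 50 genes to assess scale-free topology")
    expr = _drop_constant_genes(expr)
    corr_abs = np.abs(np.corrcoef(expr.values))
    np.fill_diagonal(corr_abs, 0.0)
    for power in candidate_powers:
        k = (corr_abs ** power).sum(axis=1)
        if float(np.median(k)) < min_median_connectivity:
            break  # connectivity only shrinks with larger powers
        if _scale_free_r2(k) >= r2_target:
            return int(power)
    logger.info("no admissible power reached scale-free R2 %.2f; using %d", r2_target, fallback_power)
    return int(fallback_power)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), diagonal 1."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(values: np.ndarray) -> np.ndarray:
    """First principal component (per-sample, unit norm) of a module.

    Rows (genes) are standardized first; the sign is fixed so the mean
    correlation with member genes is positive.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("module needs >= 2 genes")
    sd = X.std(axis=1)
    if (sd == 0).all():
        raise ValueError("rank-0 module (all genes constant)")
    Xs = (X[sd > 0] - X[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0, None]
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    v = vt[0]
    if (Xs @ v).mean() < 0:
        v = -v
    return v


def cut_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.98,
    merge_height: float = 0.25,
    expr: ExpressionMatrix | None = None,
) -> ModuleAssignment:
    """Static-height cut of the 1-TOM dendrogram into modules.

    Clusters below ``min_module_size`` become UNASSIGNED. When ``expr``
    is supplied, modules whose eigengenes correlate above
    ``1 - merge_height`` are merged iteratively. Modules are labelled
    M1, M2, ... by decreasing size.
    """
    n = tom.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match TOM")
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d)", n, min_module_size)
        return ModuleAssignment(labels={g: UNASSIGNED for g in gene_ids})
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    clusters = fcluster(Z, t=cut_height, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(int(c), []).append(i)
    module_sets = [idx for idx in groups.values() if len(idx) >= min_module_size]

    if expr is not None and len(module_sets) > 1:
        module_sets = _merge_by_eigengene(module_sets, expr, merge_height)

    # canonical labels: by decreasing size, ties by smallest member index
    module_sets.sort(key=lambda idx: (-len(idx), min(idx)))
    labels = {g: UNASSIGNED for g in gene_ids}
    for m, idx in enumerate(module_sets, start=1):
        for i in idx:
            labels[gene_ids[i]] = f"M{m}"
    return ModuleAssignment(
        labels=labels, modules=[f"M{m}" for m in range(1, len(module_sets) + 1)]
    )


def _merge_by_eigengene(
    module_sets: list[list[int]],
    expr: ExpressionMatrix,
    merge_height: float,
) -> list[list[int]]:
    threshold = 1.0 - merge_height
    sets = [list(s) for s in module_sets]
    while len(sets) > 1:
        eg = [module_eigengene(expr.values[idx]) for idx in sets]
        best, best_r = None, threshold
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                r = float(np.corrcoef(eg[a], eg[b])[0, 1])
                if r > best_r:
                    best, best_r = (a, b), r
        if best is None:
            break
        a, b = best
        sets[a] = sorted(sets[a] + sets[b])
        del sets[b]
    return sets


def module_trait_relationships(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    trait: np.ndarray,
) -> ModuleAssignment:
    """Eigengene per module and its Pearson correlation with the trait."""
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("constant trait")
    if len(trait) != expr.n_samples:
        raise ValueError("trait not aligned to samples")
    gi = {g: i for i, g in enumerate(expr.gene_ids)}
    for module in assignment.modules:
        idx = [gi[g] for g in assignment.members(module)]
        eg = module_eigengene(expr.values[idx])
        assignment.eigengenes[module] = eg
        assignment.mtr[module] = _pearson_with_p(eg, trait)
    return assignment


def gene_statistics(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    trait: np.ndarray,
) -> pd.DataFrame:
    """Per-gene GS (gene-trait correlation) and MM (gene-eigengene
    correlation within the gene's own module), with p-values."""
    trait = np.asarray(trait, dtype=float)
    rows = []
    for i, g in enumerate(expr.gene_ids):
        module = assignment.labels.get(g, UNASSIGNED)
        gs_r, gs_p = _pearson_with_p(expr.values[i], trait)
        if module != UNASSIGNED and module in assignment.eigengenes:
            mm_r, mm_p = _pearson_with_p(expr.values[i], assignment.eigengenes[module])
        else:
            mm_r, mm_p = np.nan, np.nan
        rows.append(
            {"gene_id": g, "module": module, "gs_r": gs_r, "gs_p": gs_p, "mm_r": mm_r, "mm_p": mm_p}
        )
    return pd.DataFrame(rows)


def critical_genes(
    assignment: ModuleAssignment,
    stats_table: pd.DataFrame,
    mtr_p_max: float = 0.01,
    gs_p_max: float = 0.01,
    mm_p_max: float = 0.01,
    critical_modules: list[str] | None = None,
) -> list[str]:
    """Genes with GS p and MM p below threshold inside critical modules.

    ``critical_modules`` defaults to all modules with MTR p below
    ``mtr_p_max`` (enrichment-based triage of modules is outside this
    package's scope and can be supplied explicitly instead).
    """
    if critical_modules is None:
        critical_modules = [
            m for m, (_, p) in assignment.mtr.items() if p < mtr_p_max
        ]
    sel = stats_table[
        stats_table["module"].isin(critical_modules)
        & (stats_table["gs_p"] < gs_p_max)
        & (stats_table["mm_p"] < mm_p_max)
    ]
    return sel["gene_id"].tolist()


def coexpression_analysis(
    expr: ExpressionMatrix,
    trait: np.ndarray,
    outlier_cut_height: float | None = None,
    soft_power: int | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.98,
    merge_height: float = 0.25,
    mtr_p_max: float = 0.01,
    gs_mm_p_max: float = 0.01,
) -> tuple[ModuleAssignment, pd.DataFrame, list[str], dict]:
    """Full co-expression stage: outliers -> power -> TOM -> modules ->
    MTR -> GS/MM -> critical genes.

    Returns (assignment, gene statistics table, critical gene ids, info
    dict with retained samples, chosen power and heights).
    """
    retained, height = detect_outlier_samples(expr, outlier_cut_height)
    sub = expr.subset_samples(retained)
    sub = _drop_constant_genes(sub)
    trait = np.asarray(trait, dtype=float)
    trait_sub = trait[[expr.sample_ids.index(s) for s in retained]]
    if soft_power is None:
        soft_power = pick_soft_power(sub)
    tom = tom_similarity(adjacency_matrix(sub, soft_power))
    assignment = cut_modules(
        tom, sub.gene_ids, min_module_size=min_module_size,
        cut_height=cut_height, merge_height=merge_height, expr=sub,
    )
    assignment = module_trait_relationships(sub, assignment, trait_sub)
    stats_table = gene_statistics(sub, assignment, trait_sub)
    crit = critical_genes(
        assignment, stats_table, mtr_p_max=mtr_p_max,
        gs_p_max=gs_mm_p_max, mm_p_max=gs_mm_p_max,
    )
    info = {
        "retained_samples": retained,
        "outlier_cut_height": height,
        "soft_power": int(soft_power),
        "n_modules": len(assignment.modules),
    }
    return assignment, stats_table, crit, info
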