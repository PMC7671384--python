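"""Co-expression module detection with gap-statistic model selection.

The gene set is anchored on eGenes and grown by strong Spearman co-expression
(|rho| >= 0.90 by default, non-transitive: partners must correlate with an
eGene, not merely with another partner).  The set is hierarchically clustered
on the correlation distance d = 1 - rho with average linkage, the number of
modules K is chosen by the globalSEmax rule on the gap statistic, and modules
that contain no eQTL gene are discarded (the pathway-enrichment half of the
omission rule is applied by the enrichment stage).

The gap statistic uses the pairwise-distance form of the within-cluster
dispersion, W_k = sum_r D_r / (2 n_r), which remains valid for the
non-Euclidean 1 - rho distance.  The reference distribution permutes each
gene's values across samples (destroying gene-gene correlation while
preserving marginals); the uniform-box reference of the original formulation
is available via ``reference="uniform"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import CorrelationMatrix, ExpressionMatrix, GapCurve, ModulePartition

DEFAULT_RHO_THRESHOLD = 0.90
DEFAULT_GAP_B = 50


class Dendrogram:
    """An average-linkage tree over an ordered gene list."""

    def __init__(self, genes: list[str], merge: np.ndarray):
        self.genes = list(genes)
        self.merge = merge  # scipy linkage matrix

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k modules; labels are contiguous 1..K in first-gene order."""
        raw = fcluster(self.merge, t=k, criterion="maxclust")
        relabel: dict[int, int] = {}
        out: dict[str, int] = {}
        for gene, lab in zip(self.genes, raw):
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
            out[gene] = relabel[lab]
        return out


def spearman_matrix(
    expr: ExpressionMatrix, genes: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman correlation (average ranks for ties) over genes.

    Constant genes get NaN correlations and are listed in
    ``undefined_genes`` rather than silently dropped.
    """
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    genes = list(values.index)
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    if np.isnan(x).any():
        raise ValueError("expression contains missing values; impute first")
    ranks = stats.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    # enforce exact symmetry against floating noise
    defined = ~np.isnan(rho)
    rho = np.where(defined & defined.T, (rho + rho.T) / 2.0, rho)
    return CorrelationMatrix(
        genes=genes,
        rho=rho,
        undefined_genes=[g for g, c in zip(genes, constant) if c],
    )


def assemble_geneset(
    egenes: set[str],
    expr: ExpressionMatrix,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> list[str]:
    """eGenes plus genes with |rho| >= threshold to at least one eGene.

    Order follows the expression matrix.  The threshold is inclusive.
    """
    if not egenes:
        raise ValueError("no eGenes to anchor modules")
    missing = egenes - set(expr.genes)
    if missing:
        raise ValueError(f"eGenes absent from expression matrix: {sorted(missing)}")
    corr = spearman_matrix(expr)
    idx = {g: i for i, g in enumerate(corr.genes)}
    e_idx = [idx[g] for g in sorted(egenes)]
    keep = set(egenes)
    rho_to_egenes = np.abs(corr.rho[:, e_idx])
    with np.errstate(invalid="ignore"):
        max_rho = np.nanmax(
            np.where(np.isnan(rho_to_egenes), -np.inf, rho_to_egenes), axis=1
        )
    # inclusive boundary with a float-noise guard: a partner at exactly the
    # printed threshold (e.g. rho = 0.90) must not drop out by 1 ulp
    for g, m in zip(corr.genes, max_rho):
        if m >= rho_threshold - 1e-12:
            keep.add(g)
    return [g for g in expr.genes if g in keep]


def cluster_tree(corr: CorrelationMatrix) -> Dendrogram:
    """Average-linkage agglomeration on the distance d = 1 - rho."""
    if len(corr.genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if corr.undefined_genes:
        raise ValueError(
            f"undefined correlations for genes: {corr.undefined_genes}"
        )
    d = 1.0 - corr.rho
    np.fill_diagonal(d, 0.0)
    merge = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(genes=corr.genes, merge=merge)


def _within_dispersion(d: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (full pairwise distance sum) / (2 n_r)."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        w += sub.sum() / (2.0 * idx.size)
    return w


def _log_wk_curve(values: np.ndarray, k_values: list[int]) -> np.ndarray:
    """log W_k for each k from Spearman distance + average-linkage cuts."""
    ranks = stats.rankdata(values, axis=1)
    rho = np.corrcoef(ranks)
    rho = (rho + rho.T) / 2.0
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    merge = linkage(squareform(d, checks=False), method="average")
    out = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        labels = fcluster(merge, t=k, criterion="maxclust")
        w = _within_dispersion(d, labels)
        out[i] = np.log(max(w, np.finfo(float).tiny))
    return out


def gap_statistic(
    expr_subset: ExpressionMatrix | pd.DataFrame,
    k_max: int | None = None,
    B: int = DEFAULT_GAP_B,
    seed: int | np.random.Generator | None = 0,
    reference: str = "permute",
) -> GapCurve:
    """Gap(k) = mean_b log W*_kb - log W_k for k = 1..k_max.

    ``s_k = sd_b(log W*_kb) * sqrt(1 + 1/B)``; with B = 1 the sd term is
    zero and the curve is still defined.  Reference datasets either permute
    each gene's values across samples (default) or draw uniformly from each
    gene's observed range (``reference="uniform"``).
    """
    values = (
        expr_subset.values.to_numpy(dtype=float)
        if isinstance(expr_subset, ExpressionMatrix)
        else np.asarray(expr_subset, dtype=float)
    )
    n_genes = values.shape[0]
    if k_max is None:
        k_max = min(10, n_genes - 1)
    if k_max >= n_genes:
        raise ValueError(f"k_max ({k_max}) must be below the gene count ({n_genes})")
    if B < 1:
        raise ValueError("B must be >= 1")
    if reference not in ("permute", "uniform"):
        raise ValueError(f"unknown reference {reference!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k_values = list(range(1, k_max + 1))
    log_wk = _log_wk_curve(values, k_values)
    ref = np.empty((B, len(k_values)))
    for b in range(B):
        if reference == "permute":
            sim = np.array([rng.permutation(row) for row in values])
        else:
            lo = values.min(axis=1, keepdims=True)
            hi = values.max(axis=1, keepdims=True)
            sim = lo + (hi - lo) * rng.random(values.shape)
        ref[b] = _log_wk_curve(sim, k_values)
    gap = ref.mean(axis=0) - log_wk
    sd = ref.std(axis=0, ddof=1) if B > 1 else np.zeros(len(k_values))
    se = sd * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(k_values=k_values, gap=gap, se=se, b_reference=B, log_wk=log_wk)


def choose_k_globalsemax(curve: GapCurve) -> int:
    """Smallest k with Gap(k) >= Gap(k*) - s_{k*}, k* the global maximum."""
    gap = np.asarray(curve.gap)
    if gap.size == 0:
        raise ValueError("empty gap curve")
    k_star = int(np.argmax(gap))  # argmax returns the smallest index on ties
    threshold = gap[k_star] - curve.se[k_star]
    for k, g in zip(curve.k_values, gap):
        if g >= threshold:
            return int(k)
    return int(curve.k_values[k_star])


def cut_and_filter(
    tree: Dendrogram,
    k: int,
    egene_map: dict[str, bool],
    gap_curve: GapCurve | None = None,
) -> ModulePartition:
    """Cut the tree into K modules and retain those containing an eQTL gene."""
    if k < 1:
        raise ValueError("K must be >= 1")
    assignments = tree.cut(k)
    labels = sorted(set(assignments.values()))
    retained = [
        lab
        for lab in labels
        if any(egene_map.get(g, False) for g, m in assignments.items() if m == lab)
    ]
    return ModulePartition(
        assignments=assignments,
        k=len(labels),
        gap_curve=gap_curve,
        retained=retained,
    )


def detect_modules(
    expr: ExpressionMatrix,
    egenes: set[str],
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    k_max: int | None = None,
    B: int = DEFAULT_GAP_B,
    seed: int | np.random.Generator | None = 0,
    reference: str = "permute",
) -> ModulePartition:
    """Full per-tissue module detection: assemble, cluster, choose K, filter."""
    geneset = assemble_geneset(egenes, expr, rho_threshold)
    sub = ExpressionMatrix(tissue=expr.tissue, values=expr.values.loc[geneset])
    corr = spearman_matrix(sub)
    tree = cluster_tree(corr)
    curve = gap_statistic(sub, k_max=k_max, B=B, seed=seed, reference=reference)
    k = choose_k_globalsemax(curve)
    return cut_and_filter(tree, k, {g: g in egenes for g in geneset}, gap_curve=curve)
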