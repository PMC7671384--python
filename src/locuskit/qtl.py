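"""Expression imputation, eQTL testing, eGene selection and QTL lookup.

The association model is deliberately the simplest defensible one: ordinary
least squares of expression on allelic dosage, one SNP and one gene at a
time, with no covariates.  eGenes are selected at a nominal per-tissue
P <= 0.05 without multiple-testing correction; downstream enrichment reports
adjusted values separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    EqtlResult,
    ExpressionMatrix,
    GenotypeVector,
    QtlRecord,
    StaticQtlHit,
)

_P_FLOOR = np.nextafter(0.0, 1.0)  # smallest representable positive double


def knn_impute(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing expression cells from the k nearest gene profiles.

    For each gene with missing values, neighbour distance is the root mean
    squared difference over mutually observed samples (distance scaled by the
    number of shared coordinates), and each missing cell is replaced by the
    mean of the k nearest genes' values in that sample, considering only
    neighbours observed there.  Ties in distance break by gene order.  When
    fewer than ``k`` genes are complete, the whole matrix falls back to
    per-gene row means and ``meta['row_mean_fallback']`` is set.

    Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = expr.values.to_numpy(dtype=float).copy()
    genes = expr.genes
    missing = np.isnan(values)
    all_missing = missing.all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"gene {genes[int(np.argmax(all_missing))]!r} has no observed values"
        )
    if not missing.any():
        return ExpressionMatrix(
            tissue=expr.tissue, values=expr.values.copy(), meta=dict(expr.meta)
        )

    n_complete = int((~missing).all(axis=1).sum())
    meta = dict(expr.meta)
    out = values.copy()
    if k >= n_complete:
        warnings.warn(
            "fewer complete genes than k; falling back to row-mean imputation",
            stacklevel=2,
        )
        meta["row_mean_fallback"] = True
        row_means = np.nanmean(values, axis=1)
        for i in range(values.shape[0]):
            out[i, missing[i]] = row_means[i]
    else:
        meta["row_mean_fallback"] = False
        for i in np.flatnonzero(missing.any(axis=1)):
            dist = _gene_distances(values, missing, i)
            for j in np.flatnonzero(missing[i]):
                # neighbours must be observed in the target sample
                candidates = np.flatnonzero(~missing[:, j] & np.isfinite(dist))
                order = candidates[np.argsort(dist[candidates], kind="stable")]
                neigh = order[:k]
                if neigh.size == 0:
                    out[i, j] = np.nanmean(values[i])
                else:
                    out[i, j] = values[neigh, j].mean()
    return ExpressionMatrix(
        tissue=expr.tissue,
        values=pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        meta=meta,
    )


def _gene_distances(values: np.ndarray, missing: np.ndarray, i: int) -> np.ndarray:
    """RMS difference of gene i to every gene over mutually observed samples."""
    shared = (~missing[i]) & (~missing)  # (n_genes, n_samples)
    diff = values - values[i]
    diff = np.where(shared, diff, 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt((diff**2).sum(axis=1) / n_shared)
    d[n_shared == 0] = np.inf
    d[i] = np.inf  # a gene is not its own neighbour
    return d


def test_eqtl(
    genotype: GenotypeVector,
    expr_row: pd.Series,
    tissue: str,
    gene_id: str | None = None,
) -> EqtlResult:
    """Simple OLS of expression on dosage over the shared samples.

    beta = cov(g, y) / var(g); the standard error uses the residual variance
    with n - 2 degrees of freedom and the p-value is two-sided from the t
    distribution, floored at the smallest positive double.
    """
    shared = [s for s in genotype.samples if s in expr_row.index]
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 shared samples ({len(shared)})")
    g = np.asarray(
        [genotype.dosages[genotype.samples.index(s)] for s in shared], dtype=float
    )
    y = expr_row.loc[shared].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValueError(f"{genotype.rsid}: monomorphic in tissue {tissue!r}")
    n = len(shared)
    gc = g - g.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ (y - y.mean())) / sxx
    resid = y - y.mean() - beta * gc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(max(sigma2, 0.0) / sxx))
    if se == 0.0:
        se = np.nextafter(0.0, 1.0)
        p = _P_FLOOR
    else:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(max(p, _P_FLOOR), 1.0)
    return EqtlResult(
        rsid=genotype.rsid,
        gene_id=gene_id if gene_id is not None else str(expr_row.name),
        tissue=tissue,
        beta=beta,
        se=se,
        p_value=p,
        n=n,
    )


def select_egenes(
    results: list[EqtlResult], alpha: float = 0.05
) -> dict[str, dict[str, EqtlResult]]:
    """Genes with at least one association at p <= alpha (inclusive).

    Returns gene_id -> {tissue -> minimal-p supporting record}; only tissues
    where the best record passes the screen are kept.
    """
    if not results:
        raise ValueError("no eQTL results to select from")
    best: dict[str, dict[str, EqtlResult]] = {}
    for r in results:
        per_tissue = best.setdefault(r.gene_id, {})
        cur = per_tissue.get(r.tissue)
        if cur is None or r.p_value < cur.p_value:
            per_tissue[r.tissue] = r
    selected: dict[str, dict[str, EqtlResult]] = {}
    for gene, per_tissue in best.items():
        passing = {t: r for t, r in per_tissue.items() if r.p_value <= alpha}
        if passing:
            selected[gene] = passing
    return selected


def lookup_static_qtls(
    lead_rsid: str,
    proxy_rsids: list[str],
    tables: list[QtlRecord],
) -> list[StaticQtlHit]:
    """Exact-rsid matches across the static QTL compendia.

    Each hit is annotated with whether it is on the lead or on a proxy.
    """
    proxies = set(proxy_rsids)
    hits = []
    for rec in tables:
        if rec.rsid == lead_rsid:
            hits.append(StaticQtlHit(record=rec, on_lead=True))
        elif rec.rsid in proxies:
            hits.append(StaticQtlHit(record=rec, on_lead=False))
    return hits
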