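"""Fisher-exact pathway enrichment of co-expression modules.

Each retained module is tested against every pathway restricted to the gene
universe (all genes in the tissue's expression matrix after filtering — not
the whole genome, which would inflate enrichment).  The test is one-sided
(greater): depletion does not make a module "enriched".  Raw p-values gate
the module-omission rule; Benjamini-Hochberg adjusted values are always
reported alongside, computed across all (module, pathway) pairs within a
tissue.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    ContingencyTable2x2,
    EnrichmentResult,
    ModulePartition,
    PathwayCollection,
)

DEFAULT_ALPHA_ENRICH = 0.05


def fisher_exact_greater(
    t: ContingencyTable2x2, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (odds_ratio, p_value).

    The odds ratio is the sample OR (a*d)/(b*c), +inf when b*c = 0 with
    a*d > 0 and NaN when both products vanish.  The one-sided p sums the
    hypergeometric tail P(X >= a) at the table's margins.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    n = t.total
    if alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, n, a + c, a + b))
    elif alternative == "two-sided":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return odds, min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def enrich_module(
    module_genes: set[str],
    pathways: PathwayCollection,
    universe: set[str],
    tissue: str = "",
    module_label: int = 1,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Enrichment of one module for every pathway with >= 1 universe member.

    Pathways are intersected with the universe before counting; p-values are
    raw (adjust with :func:`adjust_bh` across a tissue's full result family).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    results = []
    for pid in sorted(pathways.pathways):
        members = pathways.members(pid) & universe
        if not members:
            continue
        a = len(module_genes & members)
        b = len(module_genes) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
        odds, p = fisher_exact_greater(table, alternative=alternative)
        results.append(
            EnrichmentResult(
                tissue=tissue,
                module=module_label,
                pathway_id=pid,
                pathway_name=pathways.name(pid),
                table=table,
                odds_ratio=odds,
                p_value=p,
            )
        )
    return results


def adjust_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg adjustment over one family of enrichment results."""
    if not results:
        return []
    raw = [r.p_value for r in results]
    _, p_adj, _, _ = multipletests(raw, method="fdr_bh")
    return [replace(r, p_adjusted=float(q)) for r, q in zip(results, p_adj)]


def enrich_partition(
    partition: ModulePartition,
    pathways: PathwayCollection,
    universe: set[str],
    tissue: str = "",
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Enrichment for every retained module, BH-adjusted within the tissue."""
    results: list[EnrichmentResult] = []
    for label in partition.retained:
        results.extend(
            enrich_module(
                set(partition.module_genes(label)),
                pathways,
                universe,
                tissue=tissue,
                module_label=label,
                alternative=alternative,
            )
        )
    return adjust_bh(results)


def omit_unenriched(
    results: list[EnrichmentResult],
    partition: ModulePartition,
    alpha_enrich: float = DEFAULT_ALPHA_ENRICH,
) -> ModulePartition:
    """Drop retained modules lacking any pathway with raw p <= alpha."""
    passing = {
        r.module for r in results if r.p_value <= alpha_enrich
    }
    return ModulePartition(
        assignments=partition.assignments,
        k=partition.k,
        gap_curve=partition.gap_curve,
        retained=[m for m in partition.retained if m in passing],
    )


def aggregate_across_tissues(
    results_per_tissue: dict[str, list[EnrichmentResult]],
) -> pd.DataFrame:
    """Best module-level (p, OR) per (pathway, tissue), ties to the smaller
    module label; rows ordered by pathway id then tissue name."""
    rows = []
    for tissue in sorted(results_per_tissue):
        best: dict[str, EnrichmentResult] = {}
        for r in sorted(results_per_tissue[tissue], key=lambda r: r.module):
            cur = best.get(r.pathway_id)
            if cur is None or r.p_value < cur.p_value:
                best[r.pathway_id] = r
        for pid, r in best.items():
            rows.append(
                {
                    "pathway_id": pid,
                    "pathway_name": r.pathway_name,
                    "tissue": tissue,
                    "module": r.module,
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "pathway_name", "tissue", "module",
            "odds_ratio", "p_value", "p_adjusted",
        ],
    )
    return df.sort_values(["pathway_id", "tissue"], kind="stable").reset_index(
        drop=True
    )


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat TSV-ready table of enrichment results."""
    return pd.DataFrame(
        [
            {
                "tissue": r.tissue,
                "module": r.module,
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ],
        columns=[
            "tissue", "module", "pathway_id", "pathway_name",
            "a", "b", "c", "d", "odds_ratio", "p_value", "p_adjusted",
        ],
    )
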