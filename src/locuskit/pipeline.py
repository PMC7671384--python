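"""Pipeline orchestration: summarize, analyze and colocalize.

``summarize`` builds one JSON bundle per lead SNP (LD region, expanded
candidate genes, eQTL tests, static QTL lookups, segmentation states,
interactions).  ``analyze`` pools the bundles' eGenes per tissue, detects
co-expression modules, applies the eQTL and enrichment omission rules and
emits module/enrichment tables.  ``run_coloc`` wraps the two-trait ABF
colocalization on summary-statistic files.

Per-SNP failures never abort a batch: a SNP absent from the local data is
skipped with a logged reason, and the run status distinguishes clean,
partial and failed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .coloc import DEFAULT_PRIORS, DEFAULT_W, coloc_abf
from .enrich import (
    DEFAULT_ALPHA_ENRICH,
    aggregate_across_tissues,
    enrich_partition,
    omit_unenriched,
    results_table,
)
from .modules import DEFAULT_GAP_B, DEFAULT_RHO_THRESHOLD, detect_modules
from .qtl import knn_impute, lookup_static_qtls, select_egenes, test_eqtl
from .regions import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    build_ld_region,
    candidate_genes,
    overlaps,
    query_segmentations,
)
from .types import (
    ExpressionMatrix,
    GenotypeVector,
    SnpRecord,
    SummaryBundle,
)

logger = logging.getLogger("locuskit")

EXIT_CLEAN, EXIT_PARTIAL, EXIT_FAILED = 0, 1, 2


@dataclass
class RunConfig:
    """Validated run configuration for the CLI pipeline."""

    snp_list: Path
    data_dir: Path
    out_dir: Path
    tissues: list[str] = field(default_factory=list)
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    window_bp: int = DEFAULT_WINDOW_BP
    rho_threshold: float = DEFAULT_RHO_THRESHOLD
    alpha_egene: float = 0.05
    alpha_enrich: float = DEFAULT_ALPHA_ENRICH
    coloc_priors: tuple[float, float, float] = DEFAULT_PRIORS
    coloc_w: float = DEFAULT_W
    gap_b: int = DEFAULT_GAP_B
    gap_k_max: int | None = None
    gap_reference: str = "permute"
    knn_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.snp_list = Path(self.snp_list)
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        if not self.data_dir.is_dir():
            raise FileNotFoundError(f"data directory {self.data_dir} not found")
        if not self.snp_list.is_file():
            raise FileNotFoundError(f"SNP list {self.snp_list} not found")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if not (0.0 < self.rho_threshold <= 1.0):
            raise ValueError("rho_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "coloc_priors" in raw:
            raw["coloc_priors"] = tuple(raw["coloc_priors"])
        return cls(**raw)


@dataclass
class LocusData:
    """All local tables a summarize run needs, loaded once."""

    snp_info: dict[str, SnpRecord]
    proxies_by_lead: dict[str, list]
    genes: list
    interactions: list
    segmentations: list
    qtl_rows: list
    genotypes: dict[str, GenotypeVector]
    expression: dict[str, ExpressionMatrix]


def load_locus_data(cfg: RunConfig) -> LocusData:
    d = cfg.data_dir
    info = pd.read_csv(d / "snp_info.tsv", sep="\t")
    snp_info = {
        str(r.rsid): SnpRecord(rsid=str(r.rsid), chrom=str(r.chrom), pos=int(r.pos))
        for r in info.itertuples(index=False)
    }
    proxies = lio.read_table(d / "proxies.tsv", "proxies")
    by_lead: dict[str, list] = {}
    for p in proxies:
        by_lead.setdefault(p.lead_rsid, []).append(p)
    genotypes = {}
    geno_path = d / "genotypes.tsv"
    if geno_path.is_file():
        genotypes = {v.rsid: v for v in lio.read_genotypes(geno_path)}
    expression: dict[str, ExpressionMatrix] = {}
    for path in sorted(d.glob("expression_*.tsv")):
        mat = lio.read_expression(path)
        if cfg.tissues and mat.tissue not in cfg.tissues:
            continue
        if mat.n_missing:
            mat = knn_impute(mat, k=cfg.knn_k)
        expression[mat.tissue] = mat
    for tissue in cfg.tissues:
        if tissue not in expression:
            logger.warning("stage=summarize tissue=%s message=no expression file; skipped", tissue)
    qtl_path = d / "qtls.tsv"
    return LocusData(
        snp_info=snp_info,
        proxies_by_lead=by_lead,
        genes=lio.read_table(d / "genes.tsv", "genes"),
        interactions=lio.read_table(d / "interactions.tsv", "interactions"),
        segmentations=lio.read_table(d / "segmentations.bed", "segmentation"),
        qtl_rows=lio.read_table(qtl_path, "qtl") if qtl_path.is_file() else [],
        genotypes=genotypes,
        expression=expression,
    )


def summarize_snp(rsid: str, data: LocusData, cfg: RunConfig) -> SummaryBundle:
    """Build the per-SNP summary bundle from local data."""
    if rsid not in data.snp_info:
        raise KeyError(f"{rsid}: not present in snp_info")
    lead = data.snp_info[rsid]
    region = build_ld_region(
        lead, data.proxies_by_lead.get(rsid, []), cfg.r2_threshold
    )
    cands = candidate_genes(region, data.genes, data.interactions, cfg.window_bp)
    eqtls = []
    geno = data.genotypes.get(rsid)
    if geno is not None:
        for tissue, expr in data.expression.items():
            for cand in cands.all:
                gid = cand.gene.gene_id
                if gid not in expr.values.index:
                    continue
                try:
                    eqtls.append(
                        test_eqtl(geno, expr.values.loc[gid], tissue, gene_id=gid)
                    )
                except ValueError as exc:
                    logger.info(
                        "stage=summarize snp=%s message=eqtl skipped (%s)", rsid, exc
                    )
    hits = lookup_static_qtls(
        rsid, [p.proxy_rsid for p in region.proxies], data.qtl_rows
    )
    seg = query_segmentations(region, data.segmentations)
    inter = [
        i
        for i in data.interactions
        if overlaps(i.anchor_a, region.span) or overlaps(i.anchor_b, region.span)
    ]
    return SummaryBundle(
        snp=lead,
        region=region,
        candidate_genes=cands,
        eqtls=eqtls,
        static_qtl_hits=hits,
        segment_states=seg,
        interactions=inter,
    )


def run_summarize(cfg: RunConfig) -> tuple[list[Path], int]:
    """Summarize every SNP in the list; returns (bundle paths, exit status)."""
    rsids = lio.read_snp_list(cfg.snp_list)
    data = load_locus_data(cfg)
    bundle_dir = cfg.out_dir / "bundles"
    bundle_dir.mkdir(parents=True, exist_ok=True)
    written, skipped = [], 0
    for rsid in rsids:
        try:
            bundle = summarize_snp(rsid, data, cfg)
        except KeyError as exc:
            logger.warning("stage=summarize snp=%s message=skipped (%s)", rsid, exc)
            skipped += 1
            continue
        written.append(lio.write_bundle(bundle, bundle_dir))
        logger.info("stage=summarize snp=%s message=bundle written", rsid)
    status = EXIT_CLEAN if skipped == 0 else (EXIT_PARTIAL if written else EXIT_FAILED)
    return written, status


def run_analyze(cfg: RunConfig, bundle_paths: list[Path] | None = None) -> dict:
    """Module detection + enrichment per tissue from summarize bundles.

    Returns a dict with per-tissue partitions, enrichment tables and the
    cross-tissue aggregate; also writes TSV/JSON outputs under ``out_dir``.
    """
    if bundle_paths is None:
        bundle_paths = sorted((cfg.out_dir / "bundles").glob("*.json"))
    bundles = [lio.read_bundle(p) for p in bundle_paths]
    if not bundles:
        raise ValueError("no bundles to analyze")
    if len(bundles) < 20:
        warnings.warn(
            f"only {len(bundles)} SNPs analyzed; twenty or more are advisable "
            "for stable co-expression modules",
            stacklevel=2,
        )
    data = load_locus_data(cfg)
    all_eqtls = [e for b in bundles for e in b.eqtls]
    if not all_eqtls:
        raise ValueError("nothing to modularize: no eQTL results in bundles")
    out: dict = {"tissues": {}}
    results_by_tissue = {}
    for tissue, expr in data.expression.items():
        tissue_eqtls = [e for e in all_eqtls if e.tissue == tissue]
        if not tissue_eqtls:
            logger.warning("stage=analyze tissue=%s message=no eQTLs; skipped", tissue)
            continue
        try:
            egenes = set(select_egenes(tissue_eqtls, cfg.alpha_egene))
        except ValueError:
            egenes = set()
        if not egenes:
            logger.warning("stage=analyze tissue=%s message=no eGenes; skipped", tissue)
            continue
        partition = detect_modules(
            expr,
            egenes,
            rho_threshold=cfg.rho_threshold,
            k_max=cfg.gap_k_max,
            B=cfg.gap_b,
            seed=cfg.seed,
            reference=cfg.gap_reference,
        )
        universe = set(expr.genes)
        enr = enrich_partition(partition, _load_pathways(cfg), universe, tissue=tissue)
        filtered = omit_unenriched(enr, partition, cfg.alpha_enrich)
        results_by_tissue[tissue] = [r for r in enr if r.module in filtered.retained]
        out["tissues"][tissue] = {
            "egenes": sorted(egenes),
            "partition": filtered,
            "enrichment": enr,
        }
    if not out["tissues"]:
        raise ValueError("nothing to modularize: no tissue produced eGenes")
    out["aggregate"] = aggregate_across_tissues(results_by_tissue)
    _write_analyze_outputs(cfg, out)
    return out


def _load_pathways(cfg: RunConfig):
    return lio.read_gmt(cfg.data_dir / "pathways.gmt")


def _write_analyze_outputs(cfg: RunConfig, out: dict) -> None:
    adir = cfg.out_dir / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"tissues": {}}
    for tissue, res in out["tissues"].items():
        part = res["partition"]
        enr_df = results_table(res["enrichment"])
        enr_df.to_csv(adir / f"enrichment_{tissue}.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(part.assignments.items()),
            columns=["gene_id", "module"],
        ).to_csv(adir / f"modules_{tissue}.tsv", sep="\t", index=False)
        payload["tissues"][tissue] = {
            "egenes": res["egenes"],
            "k": part.k,
            "retained_modules": part.retained,
            "assignments": part.assignments,
            "gap_curve": {
                "k_values": part.gap_curve.k_values,
                "gap": [float(g) for g in part.gap_curve.gap],
                "se": [float(s) for s in part.gap_curve.se],
            }
            if part.gap_curve is not None
            else None,
            "enrichment": enr_df.to_dict(orient="records"),
        }
    out["aggregate"].to_csv(adir / "pathway_by_tissue.tsv", sep="\t", index=False)
    payload["aggregate"] = out["aggregate"].to_dict(orient="records")
    (adir / "analysis.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_coloc(
    trait1_path: str | Path,
    trait2_path: str | Path,
    out_dir: str | Path,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    W1: float = DEFAULT_W,
    W2: float = DEFAULT_W,
):
    """Colocalize two summary-statistic files; write pp table + SNP track."""
    t1 = lio.read_table(trait1_path, "summary_stats")
    t2 = lio.read_table(trait2_path, "summary_stats")
    result = coloc_abf(t1, t2, p1=p1, p2=p2, p12=p12, W1=W1, W2=W2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = f"coloc_{t1.trait_id}_{t2.trait_id}"
    payload = {
        "trait1": t1.trait_id,
        "trait2": t2.trait_id,
        "pp": {
            f"PP{i}": float(v) for i, v in enumerate(result.pp)
        },
        "priors": {"p1": result.priors[0], "p2": result.priors[1], "p12": result.priors[2]},
        "prior_variance": {"W1": result.prior_variance[0], "W2": result.prior_variance[1]},
        "n_snps": len(result.snps),
        "n_dropped": result.n_dropped,
    }
    (out_dir / f"{name}.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    pd.DataFrame(
        {
            "rsid": result.snps,
            "pos": result.positions,
            "h4_posterior": result.per_snp_h4,
        }
    ).to_csv(out_dir / f"{name}_track.tsv", sep="\t", index=False)
    return result
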