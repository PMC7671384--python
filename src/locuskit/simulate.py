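"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: LD-block genotypes
(Gaussian copula thresholded to dosages under Hardy-Weinberg proportions),
block-correlated expression with planted eQTL effects, per-trait association
summary statistics with configurable shared or distinct causal variants,
gene annotations with a >1 Mb distal gene wired to the LD region through a
chromosomal interaction, 15-state segmentation tilings, static QTL
compendium rows and GMT pathway sets with one pathway planted on the first
co-expression module.

Generators return their ground truth alongside the data, and the same seed
produces byte-identical outputs.  Each generator draws from an independent
seed stream derived from ``cfg.seed``, so outputs do not depend on call
order.

The TPM-likeness of the expression values is a monotone shift only; all
Spearman-based downstream stages are invariant to it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AssocStats,
    CHROMATIN_STATES_15,
    ExpressionMatrix,
    GeneRecord,
    GenomicInterval,
    GenotypeVector,
    InteractionRecord,
    PathwayCollection,
    ProxyRecord,
    QtlRecord,
    SegmentationRecord,
    SnpRecord,
)

# seed-stream ids, one per generator
_STREAM_GENO, _STREAM_EXPR, _STREAM_STATS, _STREAM_ANNOT = 1, 2, 3, 4


@dataclass(frozen=True)
class LdBlockSpec:
    """Equicorrelated latent blocks thresholded to dosages at a given MAF."""

    block_size: int = 10
    rho: float = 0.8
    maf: float = 0.3


@dataclass(frozen=True)
class ModuleSpec:
    """Planted co-expression structure: K factor blocks of genes."""

    k: int = 4
    genes_per_module: int = 20
    within_rho: float = 0.9
    between_rho: float = 0.1


@dataclass(frozen=True)
class EqtlSpec:
    """A planted cis effect: dosage of one SNP added to one gene."""

    gene_index: int = 0
    snp_index: int = 0
    beta: float = 1.0
    residual_sd: float = 0.5


@dataclass(frozen=True)
class ColocSpec:
    """Causal-variant placement for the two simulated traits."""

    causal_index_t1: int = 5
    causal_index_t2: int = 5  # equal => shared causal variant
    var_explained: float = 0.05
    n_per_trait: int = 1000


@dataclass(frozen=True)
class PathwaySpec:
    """One pathway planted on module 1 plus random background pathways."""

    n_pathways: int = 10
    pathway_size: int = 25
    planted_overlap: int = 15


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 100
    n_snps: int = 200
    ld: LdBlockSpec = field(default_factory=LdBlockSpec)
    modules: ModuleSpec = field(default_factory=ModuleSpec)
    # one effect, a list of effects (multi-locus study), or None
    eqtl: EqtlSpec | tuple[EqtlSpec, ...] | None = field(default_factory=EqtlSpec)
    coloc: ColocSpec = field(default_factory=ColocSpec)
    missing_rate: float = 0.0
    pathways: PathwaySpec = field(default_factory=PathwaySpec)
    chrom: str = "chr1"
    tissue: str = "simulated"

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if not (0.0 <= self.coloc.var_explained < 1.0):
            raise ValueError("var_explained must be in [0, 1)")
        if isinstance(self.eqtl, list):
            object.__setattr__(self, "eqtl", tuple(self.eqtl))

    @property
    def eqtl_effects(self) -> tuple[EqtlSpec, ...]:
        if self.eqtl is None:
            return ()
        if isinstance(self.eqtl, EqtlSpec):
            return (self.eqtl,)
        return tuple(self.eqtl)


@dataclass
class SimulatedGenotypes:
    vectors: list[GenotypeVector]
    rsids: list[str]
    positions: np.ndarray
    chrom: str
    dosages: np.ndarray  # (n_snps, n_samples)
    target_r2: np.ndarray
    realized_r2: np.ndarray
    sample_ids: list[str]


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _block_latent(
    rng: np.random.Generator, n_samples: int, n_snps: int, spec: LdBlockSpec
) -> np.ndarray:
    """Latent standard-normal draws with equicorrelated LD blocks."""
    m = spec.block_size
    rho = spec.rho
    if not (0.0 <= rho <= 1.0):
        raise ValueError("within-block rho must be in [0, 1]")
    if m > 1 and rho < -1.0 / (m - 1):
        raise ValueError("block correlation matrix not positive semi-definite")
    z = np.empty((n_snps, n_samples))
    for start in range(0, n_snps, m):
        size = min(m, n_snps - start)
        if rho == 1.0:
            shared = rng.standard_normal(n_samples)
            z[start : start + size] = shared
        else:
            # z_j = sqrt(rho) * f + sqrt(1 - rho) * e_j gives equicorrelation
            f = rng.standard_normal(n_samples)
            e = rng.standard_normal((size, n_samples))
            z[start : start + size] = np.sqrt(rho) * f + np.sqrt(1 - rho) * e
    return z


def _threshold_dosage(z: np.ndarray, maf: float) -> np.ndarray:
    """Threshold latent normals at Hardy-Weinberg genotype frequencies."""
    q0 = (1 - maf) ** 2
    q1 = q0 + 2 * maf * (1 - maf)
    t0 = stats.norm.ppf(q0)
    t1 = stats.norm.ppf(q1)
    return ((z > t0).astype(int) + (z > t1).astype(int)).astype(int)


def simulate_genotypes(cfg: SimulationConfig) -> SimulatedGenotypes:
    """Dosage matrix with LD-block structure plus target and realized r^2."""
    rng = _rng(cfg, _STREAM_GENO)
    z = _block_latent(rng, cfg.n_samples, cfg.n_snps, cfg.ld)
    dosages = _threshold_dosage(z, cfg.ld.maf)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    rsids = [f"rs{100001 + i}" for i in range(cfg.n_snps)]
    positions = 1_500_000 + 500 * np.arange(cfg.n_snps)

    m = cfg.ld.block_size
    target = np.zeros((cfg.n_snps, cfg.n_snps))
    for start in range(0, cfg.n_snps, m):
        stop = min(start + m, cfg.n_snps)
        target[start:stop, start:stop] = cfg.ld.rho**2
    np.fill_diagonal(target, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dosages)
    realized = corr**2

    vectors = [
        GenotypeVector(rsid=r, samples=samples, dosages=dosages[i])
        for i, r in enumerate(rsids)
    ]
    return SimulatedGenotypes(
        vectors=vectors,
        rsids=rsids,
        positions=positions,
        chrom=cfg.chrom,
        dosages=dosages,
        target_r2=target,
        realized_r2=realized,
        sample_ids=samples,
    )


def simulate_expression(
    cfg: SimulationConfig, genotypes: SimulatedGenotypes | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Block-correlated expression with an optional planted eQTL.

    Genes load on one latent factor each (within-block correlation
    ``within_rho``); factors are cross-correlated so that between-block gene
    correlation equals ``between_rho``.  The configured eQTL gene
    additionally receives ``beta * dosage`` of the configured SNP, with its
    idiosyncratic noise scaled to ``residual_sd``.  Values are shifted to be
    non-negative (TPM-like) and missing cells are masked at
    ``missing_rate``.
    """
    rng = _rng(cfg, _STREAM_EXPR)
    spec = cfg.modules
    n_genes = spec.k * spec.genes_per_module
    w = spec.within_rho
    if not (0.0 < w <= 1.0):
        raise ValueError("within_rho must be in (0, 1]")
    cross = spec.between_rho / w
    if not (0.0 <= cross < 1.0):
        raise ValueError("between_rho must be below within_rho")

    # factor draw with equicorrelation `cross` across the K factors
    shared = rng.standard_normal(cfg.n_samples)
    eigen = rng.standard_normal((spec.k, cfg.n_samples))
    factors = np.sqrt(cross) * shared + np.sqrt(1 - cross) * eigen

    labels = np.repeat(np.arange(1, spec.k + 1), spec.genes_per_module)
    noise = rng.standard_normal((n_genes, cfg.n_samples))
    x = np.sqrt(w) * factors[labels - 1] + np.sqrt(1 - w) * noise

    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    truth = {
        "module_labels": {g: int(lab) for g, lab in zip(genes, labels)},
        "eqtl_genes": [],
        "eqtl_pairs": [],
    }
    effects = cfg.eqtl_effects
    if effects:
        if genotypes is None:
            genotypes = simulate_genotypes(cfg)
        for eff in effects:
            gi, si = eff.gene_index, eff.snp_index
            dos = genotypes.dosages[si][: cfg.n_samples].astype(float)
            x[gi] = (
                np.sqrt(w) * factors[labels[gi] - 1]
                + eff.residual_sd * noise[gi]
                + eff.beta * dos
            )
            truth["eqtl_genes"].append(genes[gi])
            truth["eqtl_pairs"].append([genotypes.rsids[si], genes[gi]])

    x = x - x.min()  # monotone shift to a non-negative TPM-like scale
    if cfg.missing_rate > 0:
        mask = rng.random(x.shape) < cfg.missing_rate
        for i in range(x.shape[0]):  # keep >= 1 observed value per gene
            if mask[i].all():
                mask[i, 0] = False
        x = np.where(mask, np.nan, x)

    samples = (
        genotypes.sample_ids[: cfg.n_samples]
        if genotypes is not None
        else [f"S{i:04d}" for i in range(cfg.n_samples)]
    )
    expr = ExpressionMatrix(
        tissue=cfg.tissue,
        values=pd.DataFrame(x, index=genes, columns=samples),
    )
    return expr, truth


def _marginal_ols(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression beta and varbeta, vectorized."""
    n = y.shape[0]
    gc = dosages - dosages.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=1)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = gc @ yc / sxx
    rss = (yc @ yc) - beta**2 * sxx
    varbeta = np.clip(rss, 0, None) / (n - 2) / sxx
    beta = np.nan_to_num(beta, nan=0.0)
    varbeta = np.where(np.isfinite(varbeta) & (varbeta > 0), varbeta, 1e6)
    return beta, varbeta


def simulate_summary_stats(
    cfg: SimulationConfig, genotypes: SimulatedGenotypes | None = None
) -> tuple[AssocStats, AssocStats, dict]:
    """Marginal association statistics for two traits with planted causals.

    Each trait is measured in its own cohort of ``n_per_trait`` individuals
    drawn from the same LD structure; the phenotype is the standardized
    causal dosage scaled to the configured variance explained plus Gaussian
    noise.  Returns the two traits' stats and the causal truth.
    """
    rng = _rng(cfg, _STREAM_STATS)
    if genotypes is None:
        genotypes = simulate_genotypes(cfg)
    spec = cfg.coloc
    out = []
    for trait_id, causal in (
        ("trait1", spec.causal_index_t1),
        ("trait2", spec.causal_index_t2),
    ):
        z = _block_latent(rng, spec.n_per_trait, cfg.n_snps, cfg.ld)
        dosages = _threshold_dosage(z, cfg.ld.maf)
        g = dosages[causal].astype(float)
        if g.std() == 0:
            raise ValueError("causal variant monomorphic in simulated cohort")
        g_std = (g - g.mean()) / g.std()
        ve = spec.var_explained
        y = np.sqrt(ve) * g_std + np.sqrt(1 - ve) * rng.standard_normal(
            spec.n_per_trait
        )
        beta, varbeta = _marginal_ols(dosages, y)
        out.append(
            AssocStats(
                trait_id=trait_id,
                snps=list(genotypes.rsids),
                positions=genotypes.positions.copy(),
                beta=beta,
                varbeta=varbeta,
            )
        )
    truth = {
        "causal_t1": genotypes.rsids[spec.causal_index_t1],
        "causal_t2": genotypes.rsids[spec.causal_index_t2],
        "shared": spec.causal_index_t1 == spec.causal_index_t2,
    }
    return out[0], out[1], truth


@dataclass
class AnnotationSet:
    lead: SnpRecord  # first lead; anchors the interaction and segmentation
    leads: list[SnpRecord]
    genes: list[GeneRecord]
    interactions: list[InteractionRecord]
    segmentations: list[SegmentationRecord]
    pathways: PathwayCollection
    proxies: list[ProxyRecord]
    qtl_rows: list[QtlRecord]
    distal_gene_id: str


def simulate_annotation(
    cfg: SimulationConfig,
    genotypes: SimulatedGenotypes | None = None,
    n_epigenomes: int = 3,
) -> AnnotationSet:
    """Genes, interactions, segmentations, pathways and proxies for a locus.

    All but the last module gene are tiled with TSSs inside the 1 Mb window
    of the lead SNP; the last gene is placed 2 Mb downstream and linked to
    the LD region by a single chromosomal interaction, so it is recoverable
    only through interaction expansion.  The segmentation tiles the LD
    region gap-free for each epigenome, cycling through the 15 states.  One
    pathway is planted on module 1 with the configured overlap; the rest are
    random draws.
    """
    rng = _rng(cfg, _STREAM_ANNOT)
    if genotypes is None:
        genotypes = simulate_genotypes(cfg)
    spec = cfg.modules
    n_genes = spec.k * spec.genes_per_module
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    lead_indices = list(
        dict.fromkeys(e.snp_index for e in cfg.eqtl_effects)
    ) or [0]
    leads = [
        SnpRecord(
            rsid=genotypes.rsids[i], chrom=cfg.chrom,
            pos=int(genotypes.positions[i]),
        )
        for i in lead_indices
    ]
    lead = leads[0]
    lead_idx, lead_pos = lead_indices[0], leads[0].pos

    genes: list[GeneRecord] = []
    gene_len, spacing = 10_000, 15_000
    base = 1_000_000
    for i, gid in enumerate(gene_ids[:-1]):
        start = base + i * spacing
        genes.append(
            GeneRecord(
                gene_id=gid,
                symbol=gid,
                interval=GenomicInterval(cfg.chrom, start, start + gene_len),
                tss=start + 1,
                strand="+",
            )
        )
    distal_start = lead_pos + 2_000_000
    distal = GeneRecord(
        gene_id=gene_ids[-1],
        symbol=gene_ids[-1],
        interval=GenomicInterval(cfg.chrom, distal_start, distal_start + gene_len),
        tss=distal_start + 1,
        strand="+",
    )
    genes.append(distal)

    proxies = [
        ProxyRecord(
            lead_rsid=ld.rsid,
            proxy_rsid=genotypes.rsids[j],
            chrom=cfg.chrom,
            pos=int(genotypes.positions[j]),
            r2=float(np.nan_to_num(genotypes.realized_r2[li, j])),
        )
        for li, ld in zip(lead_indices, leads)
        for j in range(cfg.n_snps)
        if j != li
    ]
    span_positions = [lead_pos] + [
        p.pos for p in proxies if p.lead_rsid == lead.rsid and p.r2 >= 0.80
    ]
    span = GenomicInterval(
        cfg.chrom, min(span_positions) - 1, max(span_positions)
    )

    interactions = [
        InteractionRecord(
            anchor_a=GenomicInterval(cfg.chrom, span.start, span.end + 1),
            anchor_b=distal.interval,
            tissue=cfg.tissue,
            score=1.0,
        )
    ]

    segmentations: list[SegmentationRecord] = []
    bounds = np.linspace(span.start, span.end, 16).round().astype(int)
    bounds = np.unique(bounds)
    for e in range(n_epigenomes):
        epi = f"E{e + 1:03d}"
        for i in range(len(bounds) - 1):
            segmentations.append(
                SegmentationRecord(
                    epigenome_id=epi,
                    interval=GenomicInterval(
                        cfg.chrom, int(bounds[i]), int(bounds[i + 1])
                    ),
                    state=CHROMATIN_STATES_15[i % 15],
                )
            )

    pw = cfg.pathways
    module1 = gene_ids[: spec.genes_per_module]
    planted = list(
        rng.choice(module1, size=min(pw.planted_overlap, len(module1)), replace=False)
    )
    filler = [
        f"BG{j + 1:04d}" for j in range(max(pw.pathway_size - len(planted), 0))
    ]
    pathways = {"PW0001": ("planted_pathway", frozenset(planted + filler))}
    for j in range(1, pw.n_pathways):
        members = rng.choice(gene_ids, size=min(pw.pathway_size, n_genes), replace=False)
        pathways[f"PW{j + 1:04d}"] = (f"background_{j}", frozenset(members))

    qtl_rows = [
        QtlRecord(
            qtl_class="pQTL",
            rsid=lead.rsid,
            target="PROT1",
            p_value=1e-6,
            tissue_or_source="plasma",
        ),
        QtlRecord(
            qtl_class="mQTL",
            rsid=proxies[0].proxy_rsid,
            target="MET1",
            p_value=1e-4,
            tissue_or_source="serum",
        ),
        QtlRecord(
            qtl_class="meQTL",
            rsid="rs999999999",
            target="cg000001",
            p_value=1e-3,
            tissue_or_source="blood",
        ),
    ]
    return AnnotationSet(
        lead=lead,
        leads=leads,
        genes=genes,
        interactions=interactions,
        segmentations=segmentations,
        pathways=PathwayCollection(pathways=pathways),
        proxies=proxies,
        qtl_rows=qtl_rows,
        distal_gene_id=distal.gene_id,
    )


def write_fixture_dir(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete fixture directory (all input files + truth.json)."""
    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(cfg)
    expr, expr_truth = simulate_expression(cfg, geno)
    t1, t2, coloc_truth = simulate_summary_stats(cfg, geno)
    annot = simulate_annotation(cfg, geno)

    (outdir / "snps.txt").write_text(
        "".join(ld.rsid + "\n" for ld in annot.leads)
    )
    pd.DataFrame(
        [
            {"rsid": ld.rsid, "chrom": ld.chrom, "pos": ld.pos}
            for ld in annot.leads
        ]
    ).to_csv(outdir / "snp_info.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "lead_rsid": p.lead_rsid,
                "proxy_rsid": p.proxy_rsid,
                "chrom": p.chrom,
                "pos": p.pos,
                "r2": p.r2,
            }
            for p in annot.proxies
        ]
    ).to_csv(outdir / "proxies.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.strand,
                "tss": g.tss,
            }
            for g in annot.genes
        ]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom_a": i.anchor_a.chrom,
                "start_a": i.anchor_a.start,
                "end_a": i.anchor_a.end,
                "chrom_b": i.anchor_b.chrom,
                "start_b": i.anchor_b.start,
                "end_b": i.anchor_b.end,
                "tissue": i.tissue,
                "score": i.score,
            }
            for i in annot.interactions
        ]
    ).to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    with open(outdir / "segmentations.bed", "w") as fh:
        for s in annot.segmentations:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.state}\t{s.epigenome_id}\n"
            )
    pd.DataFrame(
        [
            {
                "qtl_class": q.qtl_class,
                "rsid": q.rsid,
                "target": q.target,
                "p_value": q.p_value,
                "tissue_or_source": q.tissue_or_source,
            }
            for q in annot.qtl_rows
        ]
    ).to_csv(outdir / "qtls.tsv", sep="\t", index=False)
    pd.DataFrame(
        geno.dosages, index=pd.Index(geno.rsids, name="rsid"), columns=geno.sample_ids
    ).to_csv(outdir / "genotypes.tsv", sep="\t")
    expr.values.rename_axis("gene_id").to_csv(
        outdir / f"expression_{cfg.tissue}.tsv", sep="\t", na_rep="NA"
    )
    with open(outdir / "pathways.gmt", "w") as fh:
        for pid in sorted(annot.pathways.pathways):
            name = annot.pathways.name(pid)
            members = sorted(annot.pathways.members(pid))
            fh.write("\t".join([pid, name] + members) + "\n")
    lio.write_assoc_stats(t1, outdir / "trait1.tsv", chrom=cfg.chrom)
    lio.write_assoc_stats(t2, outdir / "trait2.tsv", chrom=cfg.chrom)
    truth = {
        "config": asdict(cfg),
        "lead": annot.lead.rsid,
        "leads": [ld.rsid for ld in annot.leads],
        "distal_gene": annot.distal_gene_id,
        "expression": expr_truth,
        "coloc": coloc_truth,
        "planted_pathway": "PW0001",
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return outdir
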