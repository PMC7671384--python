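"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
All intervals are stored 0-based half-open (BED convention) regardless of the
source dialect.  SNP positions and transcription start sites are 1-based, as
they appear in the input files; they are converted at the interval boundary
(e.g. a SNP at 1-based position ``p`` occupies the interval ``[p-1, p)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CHROMATIN_STATES_15 = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

QTL_CLASSES = ("pQTL", "lQTL", "sQTL", "meQTL", "miQTL", "mQTL", "eQTL")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SnpRecord:
    """A queried variant identified by rsID; ``pos`` is 1-based."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class ProxyRecord:
    """A proxy variant with its squared correlation to a lead SNP."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    pos: int
    chrom: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must be within [0, 1], got {self.r2}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with its 1-based transcription start site."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        # tss is 1-based; the gene body covers 1-based positions
        # interval.start+1 .. interval.end
        if not (self.interval.start + 1 <= self.tss <= self.interval.end):
            raise ValueError(
                f"tss {self.tss} outside gene body "
                f"[{self.interval.start + 1}, {self.interval.end}] (1-based)"
            )


@dataclass(frozen=True)
class SegmentationRecord:
    """One chromatin-state block of an epigenome's 15-state segmentation."""

    epigenome_id: str
    interval: GenomicInterval
    state: str


@dataclass(frozen=True)
class InteractionRecord:
    """A pairwise chromosomal interaction between two anchor intervals."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    tissue: str = ""
    score: Optional[float] = None


@dataclass
class ExpressionMatrix:
    """A tissue's TPM expression matrix (genes x samples).

    Missing values are NaN in ``values``; observed entries are non-negative.
    ``meta`` carries processing flags (e.g. the kNN-imputation fallback).
    """

    tissue: str
    values: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        observed = self.values.to_numpy(dtype=float)
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValueError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass(frozen=True)
class QtlRecord:
    """A static-compendium QTL association (pQTL, lQTL, sQTL, ...)."""

    qtl_class: str
    rsid: str
    target: str
    p_value: float
    tissue_or_source: str = ""
    effect: Optional[float] = None

    def __post_init__(self) -> None:
        if self.qtl_class not in QTL_CLASSES:
            raise ValueError(
                f"qtl_class {self.qtl_class!r} not in {QTL_CLASSES}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass
class PathwayCollection:
    """Named gene sets, e.g. KEGG pathways read from a GMT file."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.pathways[pathway_id][0]


@dataclass(frozen=True)
class LdRegion:
    """A lead SNP, its qualifying proxies and the interval they span."""

    lead: SnpRecord
    proxies: tuple[ProxyRecord, ...]
    span: GenomicInterval
    r2_threshold: float = 0.80


@dataclass(frozen=True)
class CandidateGene:
    """A candidate gene with the provenance of its recruitment."""

    gene: GeneRecord
    provenance: str  # "window" | "interaction" | "both"


@dataclass
class CandidateGeneSet:
    """The expanded eQTL search space around one lead SNP."""

    window_genes: list[GeneRecord]
    interaction_genes: list[GeneRecord]
    all: list[CandidateGene]


@dataclass(frozen=True)
class EqtlResult:
    """A single SNP-gene-tissue association from simple OLS."""

    rsid: str
    gene_id: str
    tissue: str
    beta: float
    se: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass
class GenotypeVector:
    """Dosages in {0, 1, 2} for one variant across samples."""

    rsid: str
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("sample ids must be unique")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("samples and dosages length mismatch")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")


@dataclass(frozen=True)
class StaticQtlHit:
    """A compendium QTL match annotated with where it hit (lead or proxy)."""

    record: QtlRecord
    on_lead: bool


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations over an ordered gene list.

    Genes whose expression is constant have undefined correlations; they are
    reported in ``undefined_genes`` and carry NaN rows/columns rather than
    being silently dropped.
    """

    genes: list[str]
    rho: np.ndarray
    undefined_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.rho.shape != (n, n):
            raise ValueError("rho shape inconsistent with gene list")
        defined = ~np.isnan(self.rho)
        if not np.allclose(
            self.rho[defined], self.rho.T[defined], atol=1e-12
        ):
            raise ValueError("rho must be symmetric")


@dataclass
class GapCurve:
    """Gap(k) values with standard errors from B reference datasets."""

    k_values: list[int]
    gap: np.ndarray
    se: np.ndarray
    b_reference: int
    log_wk: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.gap) == len(self.se)):
            raise ValueError("gap-curve arrays must have equal length")
        if self.b_reference < 1:
            raise ValueError("b_reference must be >= 1")


@dataclass
class ModulePartition:
    """A cut of the co-expression tree plus the eQTL/enrichment filter state."""

    assignments: dict[str, int]
    k: int
    gap_curve: Optional[GapCurve]
    retained: list[int]

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels and labels != set(range(1, len(labels) + 1)):
            raise ValueError("module labels must be contiguous from 1")
        if not set(self.retained) <= labels:
            raise ValueError("retained labels must be assigned labels")

    def module_genes(self, label: int) -> list[str]:
        return [g for g, m in self.assignments.items() if m == label]

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignments.values()))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a module-vs-pathway 2x2 table within a gene universe."""

    a: int  # module & pathway
    b: int  # module only
    c: int  # pathway only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    """Fisher-exact enrichment of one module for one pathway."""

    tissue: str
    module: int
    pathway_id: str
    pathway_name: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    p_adjusted: Optional[float] = None


@dataclass
class AssocStats:
    """Per-SNP marginal association summary statistics for one trait."""

    trait_id: str
    snps: list[str]
    positions: np.ndarray
    beta: np.ndarray
    varbeta: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.beta = np.asarray(self.beta, dtype=float)
        self.varbeta = np.asarray(self.varbeta, dtype=float)
        if len(self.snps) != len(set(self.snps)):
            raise ValueError("snp ids must be unique")
        if not (
            len(self.snps)
            == len(self.positions)
            == len(self.beta)
            == len(self.varbeta)
        ):
            raise ValueError("stat arrays must have equal length")
        if (self.varbeta <= 0).any():
            raise ValueError("varbeta must be positive for every snp")


@dataclass
class ColocResult:
    """Posteriors of the five colocalization hypotheses plus per-SNP H4."""

    pp: np.ndarray  # [PP0, PP1, PP2, PP3, PP4]
    snps: list[str]
    positions: np.ndarray
    per_snp_h4: np.ndarray
    priors: tuple[float, float, float]  # (p1, p2, p12)
    prior_variance: tuple[float, float]  # (W1, W2)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if abs(float(self.pp.sum()) - 1.0) > 1e-12:
            raise ValueError("hypothesis posteriors must sum to 1")
        if abs(float(self.per_snp_h4.sum()) - 1.0) > 1e-12:
            raise ValueError("per-snp posteriors must sum to 1")
        if (self.pp < 0).any() or (self.per_snp_h4 < 0).any():
            raise ValueError("posteriors must be non-negative")


@dataclass
class SummaryBundle:
    """The per-lead-SNP aggregate consumed by the report stage."""

    snp: SnpRecord
    region: LdRegion
    candidate_genes: CandidateGeneSet
    eqtls: list[EqtlResult]
    static_qtl_hits: list[StaticQtlHit]
    segment_states: dict[str, list[SegmentationRecord]]
    interactions: list[InteractionRecord]
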