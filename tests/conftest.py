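"""Shared fixtures: small deterministic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from locuskit.types import (
    CandidateGene,
    CandidateGeneSet,
    EqtlResult,
    ExpressionMatrix,
    GeneRecord,
    GenomicInterval,
    InteractionRecord,
    LdRegion,
    ProxyRecord,
    QtlRecord,
    SegmentationRecord,
    SnpRecord,
    StaticQtlHit,
    SummaryBundle,
)


def make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str = "+",
              tss: int | None = None) -> GeneRecord:
    if tss is None:
        tss = start + 1 if strand == "+" else end
    return GeneRecord(gene_id=gene_id, symbol=gene_id, strand=strand,
                      interval=GenomicInterval(chrom, start, end), tss=tss)


def make_expr(values: np.ndarray, genes=None, samples=None,
              tissue: str = "testis") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        tissue=tissue, values=pd.DataFrame(values, index=genes, columns=samples)
    )


@pytest.fixture
def lead_snp() -> SnpRecord:
    return SnpRecord(rsid="rs1363907", chrom="chr5", pos=96_875_939)


@pytest.fixture
def small_bundle(lead_snp) -> SummaryBundle:
    proxy = ProxyRecord(
        lead_rsid=lead_snp.rsid, proxy_rsid="rs2927608",
        chrom="chr5", pos=96_900_000, r2=0.92,
    )
    region = LdRegion(
        lead=lead_snp, proxies=(proxy,),
        span=GenomicInterval("chr5", lead_snp.pos - 1, 96_900_000),
    )
    gene = make_gene("ENSG1", "chr5", 96_800_000, 96_850_000)
    cands = CandidateGeneSet(
        window_genes=[gene], interaction_genes=[],
        all=[CandidateGene(gene=gene, provenance="window")],
    )
    return SummaryBundle(
        snp=lead_snp,
        region=region,
        candidate_genes=cands,
        eqtls=[EqtlResult(rsid=lead_snp.rsid, gene_id="ENSG1", tissue="blood",
                          beta=0.8, se=0.1, p_value=1e-8, n=100)],
        static_qtl_hits=[StaticQtlHit(
            record=QtlRecord(qtl_class="pQTL", rsid=lead_snp.rsid,
                             target="ERAP2", p_value=1.31e-6,
                             tissue_or_source="plasma"),
            on_lead=True,
        )],
        segment_states={"E001": [SegmentationRecord(
            epigenome_id="E001",
            interval=GenomicInterval("chr5", 96_875_000, 96_880_000),
            state="1_TssA",
        )]},
        interactions=[InteractionRecord(
            anchor_a=GenomicInterval("chr5", 96_870_000, 96_880_000),
            anchor_b=GenomicInterval("chr5", 98_000_000, 98_010_000),
            tissue="blood", score=2.0,
        )],
    )
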