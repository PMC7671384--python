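"""LD-region construction and candidate-gene search-space expansion.

The locus around a lead GWAS SNP is defined by its proxies at r^2 >= 0.80
(inclusive).  The candidate-gene set combines a 1 Mb TSS window around the
lead (the standard cis-eQTL mapping window) with genes recruited through
chromosomal interactions whose distal anchor lies under a gene body on the
same chromosome — the search-space expansion that lets the pipeline test
genes far outside the cis window.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .types import (
    CandidateGene,
    CandidateGeneSet,
    GeneRecord,
    GenomicInterval,
    InteractionRecord,
    LdRegion,
    ProxyRecord,
    SegmentationRecord,
    SnpRecord,
)

DEFAULT_R2_THRESHOLD = 0.80
DEFAULT_WINDOW_BP = 1_000_000


def compute_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation between two dosage vectors.

    This is composite LD computed directly from unphased dosages; it is
    symmetric and invariant to allele flipping (d -> 2 - d).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"dosage length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples to compute r2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic variant: constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def build_ld_region(
    lead: SnpRecord,
    proxies: list[ProxyRecord],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> LdRegion:
    """Filter proxies at r^2 >= threshold and span lead plus qualifiers.

    The span is returned 0-based half-open; a lead with no qualifying proxy
    yields the degenerate 1-bp interval at the lead position.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    for p in proxies:
        if p.chrom != lead.chrom:
            raise ValueError(
                f"proxy {p.proxy_rsid} on {p.chrom}, lead on {lead.chrom}"
            )
    kept = tuple(p for p in proxies if p.r2 >= r2_threshold)
    positions = [lead.pos] + [p.pos for p in kept]
    span = GenomicInterval(lead.chrom, min(positions) - 1, max(positions))
    return LdRegion(lead=lead, proxies=kept, span=span, r2_threshold=r2_threshold)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open interval overlap on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def window_genes(
    lead: SnpRecord,
    genes: list[GeneRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[GeneRecord]:
    """Genes whose TSS lies within ``window_bp`` of the lead (inclusive)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    return [
        g
        for g in genes
        if g.interval.chrom == lead.chrom and abs(g.tss - lead.pos) <= window_bp
    ]


def interaction_genes(
    region: LdRegion,
    interactions: list[InteractionRecord],
    genes: list[GeneRecord],
) -> list[GeneRecord]:
    """Genes recruited through interactions anchored in the LD region.

    For an interaction with exactly one anchor overlapping the region span,
    genes under the other anchor are recruited; when both anchors overlap the
    region, genes under either qualify.  Recruitment is restricted to the
    region's chromosome and de-duplicated preserving gene-list order.
    """
    recruited: OrderedDict[str, GeneRecord] = OrderedDict()
    for inter in interactions:
        hit_a = overlaps(inter.anchor_a, region.span)
        hit_b = overlaps(inter.anchor_b, region.span)
        if not (hit_a or hit_b):
            continue
        distal_anchors = []
        if hit_a and hit_b:
            distal_anchors = [inter.anchor_a, inter.anchor_b]
        elif hit_a:
            distal_anchors = [inter.anchor_b]
        else:
            distal_anchors = [inter.anchor_a]
        for anchor in distal_anchors:
            if anchor.chrom != region.span.chrom:
                continue
            for g in genes:
                if overlaps(g.interval, anchor):
                    recruited.setdefault(g.gene_id, g)
    return list(recruited.values())


def candidate_genes(
    region: LdRegion,
    genes: list[GeneRecord],
    interactions: list[InteractionRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> CandidateGeneSet:
    """Union of window and interaction recruitment with provenance tags.

    Output order is deterministic: gene interval start, then gene id.
    """
    wgenes = window_genes(region.lead, genes, window_bp)
    igenes = interaction_genes(region, interactions, genes)
    w_ids = {g.gene_id for g in wgenes}
    i_ids = {g.gene_id for g in igenes}
    union = {g.gene_id: g for g in wgenes}
    union.update({g.gene_id: g for g in igenes})
    ordered = sorted(union.values(), key=lambda g: (g.interval.start, g.gene_id))
    tagged = []
    for g in ordered:
        if g.gene_id in w_ids and g.gene_id in i_ids:
            tag = "both"
        elif g.gene_id in w_ids:
            tag = "window"
        else:
            tag = "interaction"
        tagged.append(CandidateGene(gene=g, provenance=tag))
    return CandidateGeneSet(window_genes=wgenes, interaction_genes=igenes, all=tagged)


def query_segmentations(
    region: LdRegion, segs: list[SegmentationRecord]
) -> dict[str, list[SegmentationRecord]]:
    """Chromatin-state blocks overlapping the region, grouped by epigenome.

    Within each epigenome the original record order is preserved.
    """
    grouped: dict[str, list[SegmentationRecord]] = {}
    for s in segs:
        if overlaps(s.interval, region.span):
            grouped.setdefault(s.epigenome_id, []).append(s)
    return grouped
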