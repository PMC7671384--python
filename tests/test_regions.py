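"""LD regions, interval overlap and candidate-gene expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locuskit import regions
from locuskit.types import (
    GenomicInterval,
    InteractionRecord,
    ProxyRecord,
    SegmentationRecord,
    SnpRecord,
)

from conftest import make_gene


def proxy(lead="rs1", rsid="rs2", r2=0.9, pos=200, chrom="chr1"):
    return ProxyRecord(lead_rsid=lead, proxy_rsid=rsid, r2=r2, pos=pos, chrom=chrom)


class TestComputeR2:
    def test_self_correlation_is_one(self):
        v = [0, 1, 2, 1, 0]
        assert regions.compute_r2(v, v) == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        assert regions.compute_r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        b = np.array([0, 1, 1, 0, 2, 2], dtype=float)
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        expected = cov**2 / (a.var() * b.var())
        assert regions.compute_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_vector_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            regions.compute_r2([1, 1, 1], [0, 1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            regions.compute_r2([0, 1, 2], [0, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 2), min_size=4, max_size=30),
        st.data(),
    )
    def test_symmetric_flip_invariant_and_bounded(self, a, data):
        b = data.draw(st.lists(st.integers(0, 2), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        r2 = regions.compute_r2(a, b)
        assert 0.0 <= r2 <= 1.0
        assert regions.compute_r2(b, a) == pytest.approx(r2, abs=1e-12)
        assert regions.compute_r2(2 - a, b) == pytest.approx(r2, abs=1e-12)


class TestBuildLdRegion:
    def test_threshold_inclusive_at_080(self):
        lead = SnpRecord("rs1", "chr1", 100)
        proxies = [
            proxy(rsid="rs2", r2=0.85, pos=150),
            proxy(rsid="rs3", r2=0.80, pos=160),
            proxy(rsid="rs4", r2=0.79, pos=170),
        ]
        region = regions.build_ld_region(lead, proxies)
        assert [p.proxy_rsid for p in region.proxies] == ["rs2", "rs3"]

    def test_no_proxies_yields_one_bp_span(self):
        lead = SnpRecord("rs1", "chr1", 100)
        region = regions.build_ld_region(lead, [])
        assert (region.span.start, region.span.end) == (99, 100)

    def test_span_covers_lead_and_qualifying_proxies(self):
        lead = SnpRecord("rs1", "chr1", 100)
        proxies = [proxy(rsid="rs2", r2=0.9, pos=50), proxy(rsid="rs3", r2=0.9, pos=200)]
        region = regions.build_ld_region(lead, proxies)
        assert (region.span.start, region.span.end) == (49, 200)

    def test_proxy_on_other_chromosome_rejected(self):
        lead = SnpRecord("rs1", "chr1", 100)
        with pytest.raises(ValueError, match="chr2"):
            regions.build_ld_region(lead, [proxy(chrom="chr2")])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=0, max_size=20), st.data())
    def test_lowering_threshold_never_shrinks_region(self, r2s, data):
        lead = SnpRecord("rs1", "chr1", 1000)
        proxies = [
            proxy(rsid=f"rs{i + 2}", r2=r2, pos=500 + 100 * i)
            for i, r2 in enumerate(r2s)
        ]
        hi = data.draw(st.floats(0.1, 1.0))
        lo = data.draw(st.floats(0.01, hi))
        strict = regions.build_ld_region(lead, proxies, r2_threshold=hi)
        loose = regions.build_ld_region(lead, proxies, r2_threshold=lo)
        assert set(p.proxy_rsid for p in strict.proxies) <= set(
            p.proxy_rsid for p in loose.proxies
        )
        assert loose.span.start <= strict.span.start
        assert loose.span.end >= strict.span.end


class TestOverlaps:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 10), ("chr1", 10, 20), False),  # half-open abutment
            (("chr1", 0, 10), ("chr1", 9, 20), True),
            (("chr1", 0, 10), ("chr2", 0, 10), False),
        ],
    )
    def test_half_open_semantics(self, a, b, expected):
        assert regions.overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected


class TestWindowGenes:
    def test_one_mb_boundary_inclusive(self):
        lead = SnpRecord("rs1", "chr1", 5_000_000)
        inside = make_gene("gin", "chr1", 5_999_999, 6_100_000, tss=6_000_000)
        outside = make_gene("gout", "chr1", 6_000_000, 6_100_000, tss=6_000_001)
        other = make_gene("gother", "chr2", 4_999_999, 5_100_000, tss=5_000_000)
        result = regions.window_genes(lead, [inside, outside, other])
        assert [g.gene_id for g in result] == ["gin"]


class TestInteractionGenes:
    def region(self):
        lead = SnpRecord("rs1", "chr1", 1000)
        return regions.build_ld_region(
            lead, [proxy(rsid="rs2", r2=0.9, pos=2000)]
        )

    def test_gene_under_distal_anchor_recruited(self):
        gene = make_gene("gfar", "chr1", 5_000_000, 5_010_000)
        inter = InteractionRecord(
            anchor_a=GenomicInterval("chr1", 500, 1500),
            anchor_b=GenomicInterval("chr1", 5_000_000, 5_005_000),
        )
        out = regions.interaction_genes(self.region(), [inter], [gene])
        assert [g.gene_id for g in out] == ["gfar"]

    def test_distal_anchor_on_other_chromosome_not_recruited(self):
        gene = make_gene("gother", "chr2", 5_000_000, 5_010_000)
        inter = InteractionRecord(
            anchor_a=GenomicInterval("chr1", 500, 1500),
            anchor_b=GenomicInterval("chr2", 5_000_000, 5_005_000),
        )
        assert regions.interaction_genes(self.region(), [inter], [gene]) == []

    def test_no_anchor_overlap_recruits_nothing(self):
        gene = make_gene("g", "chr1", 5_000_000, 5_010_000)
        inter = InteractionRecord(
            anchor_a=GenomicInterval("chr1", 100_000, 200_000),
            anchor_b=GenomicInterval("chr1", 5_000_000, 5_005_000),
        )
        assert regions.interaction_genes(self.region(), [inter], [gene]) == []


class TestCandidateGenes:
    def setup_method(self):
        lead = SnpRecord("rs1", "chr1", 2_000_000)
        self.region = regions.build_ld_region(
            lead, [proxy(rsid="rs2", r2=0.9, pos=2_001_000)]
        )
        self.near = make_gene("gnear", "chr1", 2_100_000, 2_110_000)
        self.far = make_gene("gfar", "chr1", 7_000_000, 7_010_000)  # 5 Mb away
        self.inter = InteractionRecord(
            anchor_a=GenomicInterval("chr1", 1_999_000, 2_000_500),
            anchor_b=GenomicInterval("chr1", 7_000_000, 7_005_000),
        )

    def test_window_only_gene_tagged_window(self):
        out = regions.candidate_genes(self.region, [self.near], [])
        assert [(c.gene.gene_id, c.provenance) for c in out.all] == [
            ("gnear", "window")
        ]

    def test_distal_gene_recruited_by_interaction_only(self):
        out = regions.candidate_genes(
            self.region, [self.near, self.far], [self.inter]
        )
        tags = {c.gene.gene_id: c.provenance for c in out.all}
        assert tags == {"gnear": "window", "gfar": "interaction"}

    def test_gene_qualifying_both_ways_tagged_both_once(self):
        inter = InteractionRecord(
            anchor_a=GenomicInterval("chr1", 1_999_000, 2_000_500),
            anchor_b=GenomicInterval("chr1", 2_100_000, 2_105_000),
        )
        out = regions.candidate_genes(self.region, [self.near], [inter])
        assert [(c.gene.gene_id, c.provenance) for c in out.all] == [
            ("gnear", "both")
        ]

    def test_order_is_by_gene_start_then_id(self):
        out = regions.candidate_genes(
            self.region, [self.far, self.near], [self.inter]
        )
        assert [c.gene.gene_id for c in out.all] == ["gnear", "gfar"]


class TestQuerySegmentations:
    def region(self):
        lead = SnpRecord("rs1", "chr1", 1001)
        return regions.build_ld_region(
            lead, [proxy(rsid="rs2", r2=0.9, pos=2000)]
        )  # span [1000, 2000)

    def seg(self, epi, start, end):
        return SegmentationRecord(
            epigenome_id=epi, interval=GenomicInterval("chr1", start, end),
            state="1_TssA",
        )

    def test_one_bp_overlap_included_abutting_excluded(self):
        region = self.region()
        inside = self.seg("E001", 1000, 1001)
        abutting = self.seg("E001", 900, 1000)
        out = regions.query_segmentations(region, [inside, abutting])
        assert out == {"E001": [inside]}

    def test_grouping_matches_brute_force_scan(self):
        region = self.region()
        rng = np.random.default_rng(0)
        segs = []
        for e in range(3):
            for _ in range(10):
                start = int(rng.integers(0, 3000))
                segs.append(self.seg(f"E{e:03d}", start, start + 150))
        out = regions.query_segmentations(region, segs)
        # oracle: O(n) scan with explicit half-open arithmetic
        expected: dict[str, list] = {}
        for s in segs:
            if s.interval.start < region.span.end and region.span.start < s.interval.end:
                expected.setdefault(s.epigenome_id, []).append(s)
        assert out == expected
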