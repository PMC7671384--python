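"""Spearman matrices, hierarchical clustering and gap-statistic K selection."""

import numpy as np
import pytest
from scipy import stats

from locuskit.modules import (
    assemble_geneset,
    choose_k_globalsemax,
    cluster_tree,
    cut_and_filter,
    gap_statistic,
    spearman_matrix,
)
from locuskit.types import CorrelationMatrix, GapCurve

from conftest import make_expr


def naive_spearman(x: np.ndarray) -> np.ndarray:
    """Rank (average ties) then explicit Pearson formula."""
    ranks = np.array([stats.rankdata(row) for row in x])
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a, b = ranks[i] - ranks[i].mean(), ranks[j] - ranks[j].mean()
            out[i, j] = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return out


def naive_average_linkage(d: np.ndarray) -> list[float]:
    """O(n^3) agglomeration; returns the sorted merge heights."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if dij < best[0]:
                    best = (dij, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_rho_one(self):
        y1 = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        expr = make_expr(np.vstack([y1, np.exp(y1)]))
        corr = spearman_matrix(expr)
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_negation_gives_rho_minus_one(self):
        y1 = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        expr = make_expr(np.vstack([y1, y1.max() - y1]))
        assert spearman_matrix(expr).rho[0, 1] == pytest.approx(-1.0)

    def test_tie_handling_matches_naive_oracle(self):
        x = np.array([[1.0, 1.0, 2.0, 3.0],
                      [4.0, 4.0, 4.0, 5.0],
                      [2.0, 1.0, 1.0, 2.0]])
        corr = spearman_matrix(make_expr(x))
        np.testing.assert_allclose(corr.rho, naive_spearman(x), atol=1e-12)

    def test_random_fixtures_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 5, size=(6, 8)).astype(float)  # many ties
            if (np.ptp(x, axis=1) == 0).any():
                continue
            corr = spearman_matrix(make_expr(x))
            np.testing.assert_allclose(corr.rho, naive_spearman(x), atol=1e-12)

    def test_constant_gene_flagged_not_dropped(self):
        x = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        corr = spearman_matrix(make_expr(x))
        assert corr.undefined_genes == ["g2"]
        assert np.isnan(corr.rho[0, 1])
        assert len(corr.genes) == 2


class TestAssembleGeneset:
    def base_matrix(self):
        # Spearman against the anchor is exact by construction:
        # one adjacent swap of ranks on n=5 gives rho = 1 - 6*2/120 = 0.9
        anchor = [1.0, 2.0, 3.0, 4.0, 5.0]
        at_09 = [2.0, 1.0, 3.0, 4.0, 5.0]        # rho = +0.90
        at_neg09 = [5.0, 6.0, 4.0, 3.0, 2.0]      # negation of at_09: rho = -0.90
        at_08 = [1.0, 3.0, 2.0, 5.0, 4.0]        # rho = +0.80
        return make_expr(
            np.array([anchor, at_09, at_neg09, at_08]),
            genes=["ge", "gpos", "gneg", "gweak"],
        )

    def test_inclusive_positive_threshold(self):
        out = assemble_geneset({"ge"}, self.base_matrix())
        assert "gpos" in out

    def test_absolute_value_semantics(self):
        out = assemble_geneset({"ge"}, self.base_matrix())
        assert "gneg" in out

    def test_below_threshold_excluded(self):
        out = assemble_geneset({"ge"}, self.base_matrix())
        assert "gweak" not in out
        assert set(out) == {"ge", "gpos", "gneg"}

    def test_empty_egenes_rejected(self):
        with pytest.raises(ValueError, match="no eGenes"):
            assemble_geneset(set(), self.base_matrix())


class TestClusterTree:
    def corr(self, rho: np.ndarray) -> CorrelationMatrix:
        genes = [f"g{i + 1}" for i in range(rho.shape[0])]
        return CorrelationMatrix(genes=genes, rho=rho)

    def test_perfectly_correlated_pair_merges_at_zero(self):
        rho = np.array([[1.0, 1.0, 0.0],
                        [1.0, 1.0, 0.0],
                        [0.0, 0.0, 1.0]])
        tree = cluster_tree(self.corr(rho))
        assert tree.merge[0, 2] == pytest.approx(0.0)

    def test_anticorrelated_gene_joins_last_near_two(self):
        rho = np.array([[1.0, 0.95, -0.99],
                        [0.95, 1.0, -0.99],
                        [-0.99, -0.99, 1.0]])
        tree = cluster_tree(self.corr(rho))
        assert tree.merge[-1, 2] == pytest.approx(1.99, abs=1e-9)

    def test_merge_heights_match_naive_agglomerator(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 7
            a = rng.random((n, n))
            rho = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(rho, 1.0)
            tree = cluster_tree(self.corr(rho))
            d = 1.0 - rho
            np.fill_diagonal(d, 0.0)
            np.testing.assert_allclose(
                sorted(tree.merge[:, 2]), naive_average_linkage(d), atol=1e-10
            )

    def test_undefined_correlations_rejected_listing_genes(self):
        rho = np.array([[1.0, np.nan], [np.nan, np.nan]])
        corr = CorrelationMatrix(genes=["g1", "g2"], rho=rho,
                                 undefined_genes=["g2"])
        with pytest.raises(ValueError, match="g2"):
            cluster_tree(corr)


def block_expression(seed, k=2, genes_per_block=20, n_samples=100,
                     within=0.9, between=0.0):
    rng = np.random.default_rng(seed)
    cross = between / within
    shared = rng.standard_normal(n_samples)
    eig = rng.standard_normal((k, n_samples))
    f = np.sqrt(cross) * shared + np.sqrt(1 - cross) * eig
    labels = np.repeat(np.arange(k), genes_per_block)
    x = np.sqrt(within) * f[labels] + np.sqrt(1 - within) * rng.standard_normal(
        (k * genes_per_block, n_samples)
    )
    return make_expr(x - x.min()), labels


class TestGapStatistic:
    def test_single_tight_block_maximizes_gap_at_one(self):
        for seed in (0, 1, 2):
            expr, _ = block_expression(seed, k=1, genes_per_block=30,
                                       n_samples=200, within=0.95)
            curve = gap_statistic(expr, k_max=4, B=20, seed=seed)
            assert int(np.argmax(curve.gap)) + 1 == 1

    def test_two_separated_blocks_select_k_two(self):
        chosen = []
        for seed in range(10):
            expr, _ = block_expression(seed, k=2)
            curve = gap_statistic(expr, k_max=5, B=25, seed=seed)
            chosen.append(choose_k_globalsemax(curve))
        assert np.mean([k == 2 for k in chosen]) >= 0.9

    def test_single_reference_keeps_curve_defined(self):
        expr, _ = block_expression(3, k=2, genes_per_block=5, n_samples=30,
                                   within=0.95)
        curve = gap_statistic(expr, k_max=3, B=1, seed=0)
        assert np.isfinite(curve.gap).all()
        assert (curve.se == 0).all()

    def test_k_max_must_be_below_gene_count(self):
        expr, _ = block_expression(0, k=1, genes_per_block=4, n_samples=20)
        with pytest.raises(ValueError, match="k_max"):
            gap_statistic(expr, k_max=4, B=2, seed=0)

    def test_reproducible_given_seed(self):
        expr, _ = block_expression(5, k=2, genes_per_block=6, n_samples=40)
        c1 = gap_statistic(expr, k_max=4, B=10, seed=42)
        c2 = gap_statistic(expr, k_max=4, B=10, seed=42)
        np.testing.assert_array_equal(c1.gap, c2.gap)


class TestChooseKGlobalSEMax:
    def curve(self, gap, se):
        return GapCurve(
            k_values=list(range(1, len(gap) + 1)),
            gap=np.array(gap, dtype=float),
            se=np.array(se, dtype=float),
            b_reference=10,
        )

    def test_zero_se_forces_global_max(self):
        assert choose_k_globalsemax(self.curve([1.0, 1.4, 1.5], [0, 0, 0])) == 3

    def test_one_se_rule_arithmetic(self):
        # 1.4 >= 1.5 - 0.2, so the smaller k = 2 qualifies
        assert choose_k_globalsemax(self.curve([1.0, 1.4, 1.5], [0.1, 0.1, 0.2])) == 2

    def test_flat_curve_chooses_one(self):
        assert choose_k_globalsemax(self.curve([1.0, 1.0, 1.0], [0, 0, 0])) == 1


class TestCutAndFilter:
    def tree(self):
        x = np.array([[1.0, 2, 3, 4, 5],
                      [1.1, 2, 3, 4, 5.2],
                      [5, 4, 3, 2, 1],
                      [5.1, 4, 3, 2, 0.9]])
        corr = spearman_matrix(make_expr(x, genes=["a1", "a2", "b1", "b2"]))
        return cluster_tree(corr)

    def test_single_module_with_egene_retained(self):
        part = cut_and_filter(self.tree(), 1, {"a1": True})
        assert part.k == 1 and part.retained == [1]

    def test_module_without_egene_dropped(self):
        part = cut_and_filter(self.tree(), 2, {"a1": True, "b1": False})
        a_label = part.assignments["a1"]
        assert part.retained == [a_label]

    def test_all_modules_with_egenes_retained(self):
        part = cut_and_filter(self.tree(), 2, {"a1": True, "b1": True})
        assert part.retained == sorted(set(part.assignments.values()))

    def test_partition_is_exact_cover(self):
        part = cut_and_filter(self.tree(), 2, {})
        assert sorted(part.assignments) == ["a1", "a2", "b1", "b2"]
        sizes = sum(len(part.module_genes(m)) for m in part.labels)
        assert sizes == 4

    def test_adding_eqtl_flag_never_removes_retained_module(self):
        base = cut_and_filter(self.tree(), 2, {"a1": True})
        more = cut_and_filter(self.tree(), 2, {"a1": True, "b1": True})
        assert set(base.retained) <= set(more.retained)


class TestPipelineRecovery:
    def test_planted_two_block_structure_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = block_expression(7, k=2, genes_per_block=10)
        corr = spearman_matrix(expr)
        tree = cluster_tree(corr)
        curve = gap_statistic(expr, k_max=5, B=25, seed=7)
        k = choose_k_globalsemax(curve)
        part = cut_and_filter(tree, k, {g: True for g in corr.genes})
        pred = [part.assignments[g] for g in corr.genes]
        assert adjusted_rand_score(labels.tolist(), pred) >= 0.9
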