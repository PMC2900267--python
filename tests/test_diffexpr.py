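"""Moderated statistics, FDR conversions and the conglomerate ranking."""

import numpy as np
import pytest
from scipy import stats

from chronomics import ExpressionMatrix, ValidationError, simulate_expression
from chronomics.diffexpr import (allison_fdr, anova_decomposition, classical_f,
                                 conglomerate_rank, cybert_f, limma_moderated_f,
                                 sam_multiclass)
from chronomics.simulate import ProfileSpec


def _em_from_groups(rows, group_sizes):
    """rows: genes x arrays values; groups laid out contiguously."""
    values = np.asarray(rows, float)
    array_ids, design = [], {}
    i = 0
    for g, size in enumerate(group_sizes):
        for r in range(size):
            aid = f"a{i}"
            array_ids.append(aid)
            design[aid] = f"G{g}"
            i += 1
    return ExpressionMatrix([f"g{k}" for k in range(values.shape[0])],
                            array_ids, values, design)


class TestAnova:
    def test_matches_textbook_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 12))
        em = _em_from_groups(X, (3, 4, 5))
        comp = anova_decomposition(em)
        for g in range(6):
            groups = [X[g, :3], X[g, 3:7], X[g, 7:]]
            grand = X[g].mean()
            ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
            ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
            assert comp.ss_between[g] == pytest.approx(ssb)
            assert comp.ss_within[g] == pytest.approx(ssw)
            # scipy's F as a second, independent route
            F = comp.ms_between[g] / (comp.ss_within[g] / comp.df_within)
            assert F == pytest.approx(stats.f_oneway(*groups).statistic)

    def test_equal_group_means_zero_between_ss(self):
        row = np.concatenate([np.full(3, 1.0), np.full(3, 1.0)])
        em = _em_from_groups([row, row + 1], (3, 3))
        comp = anova_decomposition(em)
        np.testing.assert_allclose(comp.ss_between, 0.0, atol=1e-12)

    def test_zero_within_variance_yields_finite_f(self):
        em = _em_from_groups([[1.0, 1.0, 3.0, 3.0]], (2, 2))
        comp = anova_decomposition(em)
        F, p = classical_f(comp)
        assert np.isfinite(F[0]) and F[0] > 1e10 and p[0] < 1e-6

    def test_single_array_group_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="fewer than two"):
            _em_from_groups([[1.0, 2.0, 3.0]], (2, 1))


class TestModeratedF:
    @pytest.fixture
    def comp(self):
        em, _ = simulate_expression(
            [ProfileSpec(1, (1, 0, -1, 0, 1), 30, 1.0, 0.5)], 170, seed=11)
        return anova_decomposition(em)

    def test_no_shrinkage_limit_equals_classical_f(self, comp):
        F0, _ = classical_f(comp)
        F, p, d0, _ = limma_moderated_f(comp, prior_df=0.0)
        np.testing.assert_allclose(F, F0, rtol=1e-12)

    def test_identical_variances_make_shrinkage_a_noop(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        # rows with identical within-group scatter -> identical s2
        rows = [base + shift for shift in np.linspace(0, 3, 20)]
        em = _em_from_groups(rows, (6, 6))
        comp = anova_decomposition(em)
        F, _, d0, s02 = limma_moderated_f(comp)
        F0, _ = classical_f(comp)
        assert np.isinf(d0)
        assert s02 == pytest.approx(comp.s2[0], rel=1e-6)
        np.testing.assert_allclose(F, F0, rtol=1e-6)

    def test_null_pvalues_are_uniform(self):
        """KS statistic of moderated-F p-values on 5,000 null genes stays
        below the 1% critical value in >= 19/20 replicates."""
        crit = stats.ksone.ppf(1 - 0.005, 5000)  # two-sided 1% approx
        ok = 0
        for s in range(20):
            em, _ = simulate_expression([], 5000, seed=200 + s)
            comp = anova_decomposition(em)
            _, p, _, _ = limma_moderated_f(comp)
            ks = stats.kstest(p, "uniform").statistic
            ok += ks < crit
        assert ok >= 19

    def test_too_few_genes_rejected(self):
        em = _em_from_groups(np.random.default_rng(0).normal(size=(5, 8)), (4, 4))
        with pytest.raises(ValidationError, match="at least 10"):
            limma_moderated_f(anova_decomposition(em))


class TestCybertF:
    def test_n0_zero_equals_classical(self):
        em, _ = simulate_expression([], 50, seed=2)
        comp = anova_decomposition(em)
        F, _, reg = cybert_f(comp, window_size=11, n0=0.0)
        F0, _ = classical_f(comp)
        np.testing.assert_allclose(F, F0, rtol=1e-12)
        np.testing.assert_allclose(reg, comp.s2)

    def test_window_means_match_direct_enumeration(self):
        em, _ = simulate_expression([], 5, seed=3)
        comp = anova_decomposition(em)
        n0, w = 4.0, 3
        _, _, reg = cybert_f(comp, window_size=w, n0=n0)
        order = np.argsort(comp.mean_expr, kind="stable")
        s2s = comp.s2[order]
        for pos in range(5):
            lo, hi = max(0, pos - 1), min(5, pos + 2)
            bg = s2s[lo:hi].mean()
            expect = (n0 * bg + comp.df_within * s2s[pos]) / (n0 + comp.df_within)
            assert reg[order[pos]] == pytest.approx(expect)

    def test_low_variance_outlier_is_pulled_up(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(0, 2.0, size=(21, 10))
        rows[10] = rows[10].mean() + rng.normal(0, 1e-3, 10)  # tiny variance
        # equal means so window ordering keeps the outlier centered
        em = _em_from_groups(rows - rows.mean(axis=1, keepdims=True), (5, 5))
        comp = anova_decomposition(em)
        _, _, reg = cybert_f(comp, window_size=5, n0=10.0)
        assert reg[10] > comp.s2[10]

    def test_window_larger_than_gene_count_rejected(self):
        em, _ = simulate_expression([], 5, seed=5)
        with pytest.raises(ValidationError, match="window"):
            cybert_f(anova_decomposition(em), window_size=7)


class TestSam:
    def test_two_group_d_reduces_to_t_statistic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 10))
        em = _em_from_groups(X, (4, 6))
        res = sam_multiclass(em, n_perm=100, seed=0, s0=0.0)
        for g in range(0, 200, 17):
            t = stats.ttest_ind(X[g, 4:], X[g, :4], equal_var=True).statistic
            assert abs(res.d[g]) == pytest.approx(abs(t), rel=1e-9)

    def test_fixed_seed_reproducible(self):
        em, _ = simulate_expression([], 100, seed=7)
        r1 = sam_multiclass(em, n_perm=100, seed=9)
        r2 = sam_multiclass(em, n_perm=100, seed=9)
        np.testing.assert_array_equal(r1.fdr, r2.fdr)
        assert r1.s0 == r2.s0

    def test_complete_null_fdr_near_one(self):
        meds = []
        for s in range(5):
            em, _ = simulate_expression([], 300, seed=400 + s)
            res = sam_multiclass(em, n_perm=100, seed=s)
            meds.append(np.median(res.fdr))
        assert np.mean(meds) > 0.8

    def test_single_group_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="two groups"):
            _em_from_groups(np.random.default_rng(0).normal(size=(20, 4)), (4,))

    def test_low_n_perm_rejected(self):
        em = _em_from_groups(np.random.default_rng(0).normal(size=(20, 8)), (4, 4))
        with pytest.raises(ValidationError, match="n_perm"):
            sam_multiclass(em, n_perm=50)


class TestAllisonFdr:
    def test_null_pvalues_fit_lambda_near_one(self):
        hits = 0
        for s in range(10):
            p = np.random.default_rng(500 + s).uniform(size=2000)
            _, fit = allison_fdr(p, return_fit=True)
            if fit["method"] == "bum" and 0.9 < fit["lambda"] <= 1.0:
                hits += 1
        assert hits >= 9

    def test_strong_signal_gives_small_fdr_at_top(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 1e-8, 200), rng.uniform(size=800)])
        fdr = allison_fdr(p)
        assert fdr[:200].max() < 0.01

    def test_bh_values_on_fixed_vector(self):
        fdr = allison_fdr(np.array([0.01, 0.02, 0.5, 1.0]), method="bh")
        np.testing.assert_allclose(fdr, [0.04, 0.04, 2.0 / 3.0, 1.0], rtol=1e-9)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            allison_fdr(np.array([0.1, 1.5]))


class TestConglomerate:
    def test_mean_rank_toy_matches_hand_enumeration(self):
        ranks = np.array([[1, 2, 3, 4, 5],
                          [2, 1, 3, 5, 4],
                          [3, 4, 1, 2, 5]], float)
        fdrs = np.tile(np.array([0.001, 0.01, 0.02, 0.5, 0.9]), (3, 1))
        genes = [f"g{i}" for i in range(5)]
        score, cong_rank, cong_fdr, de = conglomerate_rank(genes, ranks, fdrs,
                                                           alpha=0.02)
        np.testing.assert_allclose(score, [2.0, 7 / 3, 7 / 3, 11 / 3, 14 / 3])
        # ties at 7/3 broken by gene id: g1 before g2
        assert cong_rank.tolist() == [1, 2, 3, 4, 5]
        assert de.tolist() == [True, True, True, False, False]

    def test_unanimous_ordering_is_preserved(self):
        ranks = np.tile(np.arange(1, 7, dtype=float), (3, 1))
        fdrs = np.tile(np.linspace(0.001, 0.6, 6), (3, 1))
        genes = [f"g{i}" for i in range(6)]
        _, cong_rank, cong_fdr, _ = conglomerate_rank(genes, ranks, fdrs)
        assert cong_rank.tolist() == [1, 2, 3, 4, 5, 6]
        # median of identical FDRs with running max leaves them unchanged
        np.testing.assert_allclose(cong_fdr, fdrs[0])

    def test_fdr_monotone_along_ordering(self):
        rng = np.random.default_rng(10)
        ranks = np.vstack([rng.permutation(20) + 1.0 for _ in range(3)])
        fdrs = rng.uniform(size=(3, 20))
        genes = [f"g{i}" for i in range(20)]
        _, cong_rank, cong_fdr, _ = conglomerate_rank(genes, ranks, fdrs)
        order = np.argsort(cong_rank)
        assert np.all(np.diff(cong_fdr[order]) >= -1e-12)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValidationError):
            conglomerate_rank(["g1"], np.ones((2, 1)), np.ones((2, 1)))
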