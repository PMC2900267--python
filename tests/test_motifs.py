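"""PWM scanning, over-representation Z scores and Z-matrix analytics."""

from itertools import product

import numpy as np
import pytest

from chronomics import PWM, PromoterSet, ValidationError
from chronomics.motifs import (MotifOverrepresentationModel, ZScoreMatrix,
                               background_composition, build_scorer,
                               count_sites, count_windows, zmatrix_cluster,
                               zmatrix_pca, zscore_overrep)
from chronomics.simulate import SimTruth, reverse_complement, simulate_promoters

UNIFORM = (0.25, 0.25, 0.25, 0.25)
BASES = "ACGT"


def _consensus_pwm(word, weight=100.0):
    """Near-deterministic PWM whose consensus is `word`."""
    m = np.ones((4, len(word)))
    for j, b in enumerate(word):
        m[BASES.index(b), j] = weight
    return PWM("M_" + word, m)


def _brute_count(seq, scorer):
    """Score every window on both strands with explicit loops."""
    L = scorer.length
    total = 0
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - L + 1):
            window = s[i:i + L]
            if "N" in window:
                continue
            score = sum(scorer.log_odds[BASES.index(b), j]
                        for j, b in enumerate(window))
            if score >= scorer.threshold:
                total += 1
    return total


class TestScorer:
    def test_uniform_pwm_is_degenerate_and_hitless(self):
        pwm = PWM("U", np.ones((4, 6)))
        scorer = build_scorer(pwm, UNIFORM)
        np.testing.assert_allclose(scorer.log_odds, 0.0, atol=1e-12)
        assert scorer.degenerate
        assert count_sites("ACGT" * 100, scorer) == 0

    def test_consensus_only_pwm_hits_enumerated_words(self):
        """For L=4, hits among all 4^4 words match explicit enumeration."""
        scorer = build_scorer(_consensus_pwm("ACGT"), UNIFORM,
                              threshold_fraction=0.9)
        n_hits = 0
        for word in map("".join, product(BASES, repeat=4)):
            expected = _brute_count(word, scorer)
            got = count_sites(word, scorer)
            assert got == expected
            n_hits += got
        # with a 0.9 threshold only the consensus itself (fwd) and its
        # reverse complement source word score
        assert n_hits == 2

    def test_threshold_one_keeps_only_maximal_word(self):
        scorer = build_scorer(_consensus_pwm("AACC"), UNIFORM,
                              threshold_fraction=1.0)
        assert count_sites("AACC", scorer) == 1
        assert count_sites("AACT", scorer) == 0

    def test_zero_background_rejected(self):
        with pytest.raises(ValidationError):
            build_scorer(_consensus_pwm("ACGT"), (0.5, 0.5, 0.0, 0.0))


class TestCountSites:
    def test_sequence_shorter_than_motif_counts_zero(self):
        scorer = build_scorer(_consensus_pwm("ACGTAC"), UNIFORM)
        assert count_sites("ACG", scorer) == 0
        assert count_windows("ACG", 6) == 0

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(BASES), 300))
        scorer = build_scorer(_consensus_pwm("ACGGT"), UNIFORM, 0.7)
        assert count_sites(seq, scorer) == count_sites(reverse_complement(seq), scorer)

    def test_planted_sites_found_and_match_brute_force(self):
        rng = np.random.default_rng(1)
        word = "ACGGTACG"
        seq = list(rng.choice(list("AT"), 1200))  # AT background: no false hits
        seq[10:18] = word
        seq[500:508] = word
        seq = "".join(seq)
        scorer = build_scorer(_consensus_pwm(word), UNIFORM, 0.9)
        assert count_sites(seq, scorer) == _brute_count(seq, scorer) == 2

    def test_shift_invariance_of_counts(self):
        word = "ACGGTACG"
        base = ["T"] * 400
        for offset in (0, 37):
            seq = list(base)
            seq[50 + offset:58 + offset] = word
            seq[200 + offset:208 + offset] = word
            scorer = build_scorer(_consensus_pwm(word), UNIFORM, 0.9)
            assert count_sites("".join(seq), scorer) == 2

    def test_n_windows_are_skipped(self):
        word = "ACGGTACG"
        scorer = build_scorer(_consensus_pwm(word), UNIFORM, 0.9)
        seq = "TTTT" + word + "TTTT"
        assert count_sites(seq, scorer) == 1
        broken = seq.replace("ACGGTACG", "ACGGNACG")
        assert count_sites(broken, scorer) == _brute_count(broken, scorer) == 0
        assert count_windows("NN" + "A" * 10, 4) < count_windows("A" * 12, 4)


def _promoset(seqs):
    return PromoterSet({f"g{i}": s for i, s in enumerate(seqs)}, 0, 0)


class TestZScore:
    def test_background_against_itself_is_zero(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list(BASES), 200)) for _ in range(20)]
        ps = _promoset(seqs)
        scorer = build_scorer(_consensus_pwm("ACGT", 5), UNIFORM, 0.5)
        z, obs, exp, sd = zscore_overrep(ps, ps, scorer)
        assert sd > 0
        assert z == pytest.approx(0.0, abs=1e-12)
        assert obs == pytest.approx(exp)

    def test_depleted_foreground_scores_negative(self):
        rng = np.random.default_rng(3)
        word = "ACGGTACG"
        rich = ["".join(rng.choice(list(BASES), 200)) + word for _ in range(20)]
        poor = ["T" * 208 for _ in range(20)]
        background = PromoterSet({f"r{i}": s for i, s in enumerate(rich)} |
                                 {f"p{i}": s for i, s in enumerate(poor)}, 0, 0)
        fore = PromoterSet({f"p{i}": poor[i] for i in range(20)}, 0, 0)
        scorer = build_scorer(_consensus_pwm(word), UNIFORM, 0.9)
        z, *_ = zscore_overrep(fore, background, scorer)
        assert z < 0

    def test_foreground_must_be_subset(self):
        scorer = build_scorer(_consensus_pwm("ACGT"), UNIFORM)
        with pytest.raises(ValidationError):
            zscore_overrep(_promoset(["ACGTACGT"]),
                           PromoterSet({"x": "ACGTACGT"}, 0, 0), scorer)

    def test_analytic_z_agrees_with_resampling_oracle(self):
        """The binomial Z tracks a Z from same-size random foreground
        resamplings of the background (sign agreement, |difference| <= 0.5)."""
        for s in (200, 201, 202):
            rng = np.random.default_rng(100 + s)
            truth = SimTruth(gene_cluster={f"g{i}": (1 if i < 15 else None)
                                           for i in range(60)})
            pwm = _consensus_pwm("ACGGTACG")
            ps = simulate_promoters(truth, [pwm], 300,
                                    {1: {pwm.motif_id: 1.0}}, 0.3, seed=s)
            scorer = build_scorer(pwm, background_composition(ps), 0.85)
            fore_ids = [f"g{i}" for i in range(15)]
            fore = ps.subset(fore_ids)
            z, obs, _, _ = zscore_overrep(fore, ps, scorer)
            hits = {g: count_sites(sq, scorer) for g, sq in ps.sequences.items()}
            ids = list(ps.sequences)
            resampled = [sum(hits[g] for g in rng.choice(ids, len(fore_ids),
                                                         replace=False))
                         for _ in range(4000)]
            z_perm = (obs - np.mean(resampled)) / np.std(resampled, ddof=1)
            assert np.sign(z) == np.sign(z_perm)
            assert abs(z - z_perm) <= 0.5

    def test_uniform_foreground_z_centered_at_zero(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list(BASES), 200)) for _ in range(40)]
        ps = _promoset(seqs)
        scorer = build_scorer(_consensus_pwm("ACGT", 8), UNIFORM, 0.5)
        zs = []
        for _ in range(200):
            ids = rng.choice(ps.gene_ids, 10, replace=False)
            z, *_ = zscore_overrep(ps.subset(ids), ps, scorer)
            zs.append(z)
        assert abs(np.mean(zs)) < 0.1


def _toy_zmatrix():
    # two motif blocks x two cluster blocks
    z = np.array([[5.0, 4.8, -4.9, -5.2],
                  [4.6, 5.1, -5.0, -4.7],
                  [-5.1, -4.9, 5.2, 5.0],
                  [-4.8, -5.2, 4.9, 5.1]])
    return ZScoreMatrix([1, 2, 3, 4], ["m1", "m2", "m3", "m4"], z.T,
                        np.zeros_like(z), np.zeros_like(z), np.ones_like(z))


class TestZMatrixAnalytics:
    def test_two_way_ordering_unit_variance_and_block_split(self):
        res = zmatrix_cluster(_toy_zmatrix())
        np.testing.assert_allclose(res["matrix"].std(axis=0, ddof=1), 1.0)
        col_order = [res["cluster_ids"][j] for j in res["col_order"]]
        assert {tuple(col_order[:2]), tuple(col_order[2:])} in (
            {(1, 2), (3, 4)}, {(2, 1), (3, 4)}, {(1, 2), (4, 3)},
            {(2, 1), (4, 3)}, {(3, 4), (1, 2)}, {(4, 3), (1, 2)},
            {(3, 4), (2, 1)}, {(4, 3), (2, 1)})

    def test_duplicated_cluster_columns_end_up_adjacent(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(5, 6))
        z[3] = z[1]  # clusters 4 and 2 identical
        zm = ZScoreMatrix(list(range(1, 6)), [f"m{i}" for i in range(6)], z,
                          np.zeros_like(z), np.zeros_like(z), np.ones_like(z))
        res = zmatrix_cluster(zm)
        order = [res["cluster_ids"][j] for j in res["col_order"]]
        assert abs(order.index(2) - order.index(4)) == 1

    def test_undefined_column_excluded_with_warning(self):
        zm = _toy_zmatrix()
        zm.z[0, :] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            res = zmatrix_cluster(zm)
        assert 1 not in res["cluster_ids"]

    def test_pca_matches_independent_eigen_route(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(8)
        z = rng.normal(size=(6, 4))
        zm = ZScoreMatrix(list(range(1, 7)), ["a", "b", "c", "d"], z,
                          np.zeros_like(z), np.zeros_like(z), np.ones_like(z))
        ours = zmatrix_pca(zm)
        theirs = PCA(n_components=2).fit_transform(z)
        for k, col in enumerate(["pc1", "pc2"]):
            a, b = ours[col].to_numpy(), theirs[:, k]
            assert (np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8))
        assert ours["var_pc1"].iloc[0] >= ours["var_pc2"].iloc[0]

    def test_identical_clusters_project_identically(self):
        z = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [4.0, 0.0, 1.0],
                      [0.0, 5.0, 2.0]])
        zm = ZScoreMatrix([1, 2, 3, 4], ["a", "b", "c"], z,
                          np.zeros_like(z), np.zeros_like(z), np.ones_like(z))
        res = zmatrix_pca(zm)
        np.testing.assert_allclose(res.iloc[0][["pc1", "pc2"]].astype(float),
                                   res.iloc[1][["pc1", "pc2"]].astype(float))

    def test_rank_deficient_pca_rejected(self):
        z = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0])
        zm = ZScoreMatrix([1, 2, 3], list("abcd"), z, np.zeros_like(z),
                          np.zeros_like(z), np.ones_like(z))
        with pytest.raises(ValidationError, match="rank"):
            zmatrix_pca(zm)


class TestModel:
    def test_no_hit_motif_column_flagged_undefined(self):
        rng = np.random.default_rng(9)
        seqs = {f"g{i}": "".join(rng.choice(list("AT"), 100)) for i in range(12)}
        ps = PromoterSet(seqs, 0, 0)
        pwm = _consensus_pwm("GGGGCCCC")  # cannot occur in an A/T background
        res = MotifOverrepresentationModel({1: list(seqs)[:6], 2: list(seqs)[6:]},
                                           ps, [pwm]).fit()
        assert np.isnan(res.zmatrix.z).all()
        assert (res.calls()["call"] == "undefined").all()

    def test_calls_follow_reporting_rule(self):
        z = np.array([[4.0, -4.0, 1.0]])
        zm = ZScoreMatrix([1], ["a", "b", "c"], z, np.zeros_like(z),
                          np.zeros_like(z), np.ones_like(z))
        calls = zm.calls()
        assert calls["call"].tolist() == ["over", "under", "none"]

    def test_genes_without_promoters_are_excluded(self, caplog):
        rng = np.random.default_rng(10)
        seqs = {f"g{i}": "".join(rng.choice(list(BASES), 100)) for i in range(6)}
        ps = PromoterSet(seqs, 0, 0)
        model = MotifOverrepresentationModel(
            {1: ["g0", "g1", "missing"], 2: ["g2", "g3"]}, ps,
            [_consensus_pwm("ACGT", 5)])
        assert model.cluster_genes[1] == ["g0", "g1"]
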