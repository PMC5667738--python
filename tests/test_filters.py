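"""Filter scores against independent oracles, and fold-rank aggregation."""

import numpy as np
import pytest
from scipy import stats as sps

from swarmselect import (
    GeneList,
    SyntheticSpec,
    aggregate_fold_ranks,
    cor_scores,
    filter_stage,
    generate,
    overlap_percent,
    recovery_score,
    welch_scores,
    wrs_scores,
)
from swarmselect.filters import rank_genes

from conftest import two_class_matrix


def _col(class0, class1):
    return two_class_matrix(np.asarray(class0, float).reshape(-1, 1),
                            np.asarray(class1, float).reshape(-1, 1))


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        fs = welch_scores(_col([1, 2, 3], [1, 2, 3]))
        assert fs.t[0] == 0.0
        assert fs.p[0] == 1.0

    def test_hand_evaluated_statistic(self):
        # c1=2.5, c2=5, s1²=5/3, s2²=20/3 -> t = -2.5/sqrt(25/12)
        fs = welch_scores(_col([1, 2, 3, 4], [2, 4, 6, 8]))
        assert fs.t[0] == pytest.approx(-2.5 / np.sqrt(25 / 12), abs=1e-12)

    def test_matches_scipy_reference_to_1e10(self):
        rng = np.random.default_rng(12)
        m = two_class_matrix(rng.normal(5, 2, (9, 40)), rng.normal(5, 3, (13, 40)))
        fs = welch_scores(m)
        ref_t, ref_p = sps.ttest_ind(m.values[:9], m.values[9:], equal_var=False)
        np.testing.assert_allclose(fs.t, ref_t, rtol=1e-10)
        np.testing.assert_allclose(fs.p, ref_p, rtol=1e-10)

    def test_zero_variance_unequal_means_ranks_first(self):
        m = two_class_matrix([[1.0, 5.0], [1.0, 6.0]], [[2.0, 5.5], [2.0, 4.5]])
        fs = welch_scores(m)
        assert fs.p[0] == np.finfo(float).tiny
        assert "zero_variance_separated" in fs.flags
        assert rank_genes(fs, "tt").ids[0] == "g0"


class TestCor:
    def test_equal_class_means_score_zero(self):
        fs = cor_scores(_col([1.0, 3.0], [0.0, 4.0]))
        assert fs.cor[0] == 0.0

    def test_hand_evaluated_score(self):
        # c=1, c0=0, c1=2, P=1/2; numerator 1; sigma²=8/3; denom weight 1/2
        fs = cor_scores(_col([-1.0, 1.0], [1.0, 3.0]))
        assert fs.cor[0] == pytest.approx(0.75, abs=1e-12)

    def test_doubling_mean_gap_quadruples_score(self):
        # doubling the class-mean gap at unchanged within-class spread
        # quadruples the numerator; normalize out the induced σ²(f) change
        a = cor_scores(_col([-1.0, 1.0], [1.0, 3.0])).cor[0]
        v = _col([-1.0, 1.0], [1.0, 3.0]).values
        widened = v + np.array([[0.0], [0.0], [2.0], [2.0]])  # gap 2 -> 4
        fs_wide = cor_scores(two_class_matrix(widened[:2], widened[2:]))
        ratio_var = widened.var(ddof=1) / v.var(ddof=1)
        assert fs_wide.cor[0] * ratio_var == pytest.approx(4 * a, rel=1e-9)

    def test_shift_invariance_and_scale_behavior(self):
        rng = np.random.default_rng(5)
        m = two_class_matrix(rng.normal(10, 2, (6, 8)), rng.normal(12, 2, (6, 8)))
        shifted = two_class_matrix(m.values[:6] + 37.0, m.values[6:] + 37.0)
        scaled = two_class_matrix(m.values[:6] * 3.0, m.values[6:] * 3.0)
        np.testing.assert_allclose(cor_scores(shifted).cor, cor_scores(m).cor, rtol=1e-9)
        np.testing.assert_allclose(cor_scores(scaled).cor, cor_scores(m).cor, rtol=1e-9)

    def test_zero_variance_gene_flagged_zero(self):
        fs = cor_scores(_col([2.0, 2.0], [2.0, 2.0]))
        assert fs.cor[0] == 0.0
        assert fs.flags["zero_variance"] == ["g0"]


def _wrs_bruteforce(x0, x1):
    s = 0
    for xi in x0:
        for xj in x1:
            if xj - xi <= 0:
                s += 1
    return s


class TestWrs:
    @pytest.mark.parametrize(
        "class0,class1,s,q",
        [
            ([1, 2], [3, 4], 0, 4),
            ([1, 3], [2, 4], 1, 3),
        ],
    )
    def test_pair_count_examples(self, class0, class1, s, q):
        fs = wrs_scores(_col(class0, class1))
        assert fs.wrs_s[0] == s
        assert fs.wrs_q[0] == q

    def test_identical_multisets_minimally_discriminative(self):
        fs = wrs_scores(_col([1, 2], [1, 2]))
        n2 = 4
        assert abs(fs.wrs_q[0] - n2 / 2) <= 1

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n0, n1 = rng.integers(2, 12, 2)
            vals = rng.integers(0, 6, (n0 + n1, 7)).astype(float)  # many ties
            m = two_class_matrix(vals[:n0], vals[n0:])
            fs = wrs_scores(m)
            for j in range(7):
                expected = _wrs_bruteforce(vals[:n0, j], vals[n0:, j])
                assert fs.wrs_s[j] == expected
                assert fs.wrs_q[j] == max(expected, n0 * n1 - expected)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(3)
        m = two_class_matrix(rng.normal(size=(8, 30)), rng.normal(size=(11, 30)))
        fs = wrs_scores(m)
        assert np.all(fs.wrs_s >= 0) and np.all(fs.wrs_s <= 88)
        assert np.all(fs.wrs_q >= np.ceil(88 / 2)) and np.all(fs.wrs_q <= 88)


class TestAggregateFoldRanks:
    def test_best_position_in_all_folds(self):
        lists = [["star"] + [f"f{i}_{j}" for j in range(199)] for i in range(10)]
        fused = aggregate_fold_ranks(lists)
        assert fused.ids[0] == "star"
        assert fused.scores[0] == 10 * 200

    def test_absent_gene_excluded(self):
        fused = aggregate_fold_ranks([["a", "b"], ["b", "a"]])
        assert "z" not in fused

    def test_single_fold_is_identity(self):
        fused = aggregate_fold_ranks([["x", "y", "z"]])
        assert fused.ids == ["x", "y", "z"]

    def test_fold_order_irrelevant(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        lists = [list(rng.permutation(genes)[:10]) for _ in range(5)]
        a = aggregate_fold_ranks(lists)
        b = aggregate_fold_ranks(lists[::-1])
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            aggregate_fold_ranks([["a", "b"], ["a"]])

    def test_duplicates_within_fold_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_fold_ranks([["a", "a"]])


class TestFilterStage:
    def test_planted_gene_tops_every_filter(self):
        m, planted = generate(SyntheticSpec(n_class0=30, n_class1=30, n_genes=300,
                                            n_discriminative=1, effect_size=5.0,
                                            outlier_rate=0.0, seed=21))
        for method in ("tt", "cor", "wrs"):
            ranked = filter_stage(m, method, R=20, K=10, seed=1)
            assert ranked.ids[0] == planted.ids[0]

    def test_single_fold_wrs_equals_direct_ranking(self, toy_matrix):
        staged = filter_stage(toy_matrix, "wrs", R=5, K=1, seed=0)
        direct = rank_genes(wrs_scores(toy_matrix), "wrs")
        assert staged.ids == direct.ids[:5]

    def test_deterministic_given_seed(self, toy_matrix):
        a = filter_stage(toy_matrix, "tt", R=6, K=4, seed=3)
        b = filter_stage(toy_matrix, "tt", R=6, K=4, seed=3)
        assert a.ids == b.ids

    def test_r_exceeding_gene_count_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            filter_stage(toy_matrix, "tt", R=100, K=2, seed=0)

    def test_filter_recovery_on_planted_panel(self):
        """Top-50 fused list of each filter recovers >=90% of 20 planted genes."""
        m, planted = generate(SyntheticSpec(n_class0=40, n_class1=40, n_genes=1000,
                                            n_discriminative=20, effect_size=2.0,
                                            seed=13))
        for method in ("tt", "cor", "wrs"):
            top50 = GeneList(filter_stage(m, method, R=50, K=10, seed=2).ids)
            assert recovery_score(top50, planted) >= 0.9, method


class TestOverlapPercent:
    def test_identical_disjoint_partial(self):
        a = GeneList(["a", "b", "c", "d"])
        assert overlap_percent(a, a) == 100.0
        assert overlap_percent(a, GeneList(["w", "x", "y", "z"])) == 0.0
        assert overlap_percent(a, GeneList(["a", "b", "x", "y"])) == 50.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_percent(GeneList(["a"]), GeneList(["a", "b"]))
        with pytest.raises(ValueError):
            overlap_percent(GeneList([]), GeneList([]))
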