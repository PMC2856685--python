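"""Repeated 10-fold protocol, source scoring and the comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netkern import (
    ExpressionMatrix,
    RepeatConfig,
    SyntheticSpec,
    aggregate_scores,
    binarize_predictions,
    decision_values,
    generate_complementary_expression,
    gmatrix_for_source,
    identity_gmatrix,
    mutual_information_binary,
    mutual_information_from_joint,
    paired_t_one_sided,
    run_protocol,
    score_sources,
    stratified_folds,
    train_weighted_lssvm,
    wilcoxon_signed_rank,
)
from netkern.protocol import BASE_FOLDS, COMBINER_FOLDS, TEST_FOLDS


class TestStratifiedFolds:
    def test_exactly_proportional_when_divisible(self):
        y = np.array([1] * 20 + [-1] * 80)
        scheme = stratified_folds(y, k=10, seed=0)
        for f in range(1, 11):
            sel = scheme.fold_assignment == f
            assert (y[sel] == 1).sum() == 2
            assert (y[sel] == -1).sum() == 8

    def test_deterministic_given_seed(self):
        y = np.array([1, -1] * 25)
        a = stratified_folds(y, seed=5).fold_assignment
        b = stratified_folds(y, seed=5).fold_assignment
        c = stratified_folds(y, seed=6).fold_assignment
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_remainders_spread_within_one(self):
        y = np.array([1] * 7 + [-1] * 23)
        scheme = stratified_folds(y, k=5, seed=2)
        counts = [(y[scheme.fold_assignment == f] == 1).sum() for f in range(1, 6)]
        assert max(counts) - min(counts) <= 1

    def test_role_partition_is_5_3_2(self):
        y = np.array([1, -1] * 30)
        scheme = stratified_folds(y, seed=1)
        assert BASE_FOLDS == (1, 2, 3, 4, 5)
        assert COMBINER_FOLDS == (6, 7, 8)
        assert TEST_FOLDS == (9, 10)
        n = y.size
        assert scheme.base_train.size == n // 2
        assert scheme.combiner_train.size == int(0.8 * n)
        assert scheme.test.size == n // 5
        all_idx = np.concatenate([scheme.base_train,
                                  scheme.indices(COMBINER_FOLDS), scheme.test])
        assert np.array_equal(np.sort(all_idx), np.arange(n))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([1, -1]), k=10, seed=0)


def small_dataset(seed=3):
    spec = SyntheticSpec(n_genes=60, n_samples=60, pathway_size=10,
                         n_pathways=2, n_informative_pathways=1, seed=seed)
    X = generate_complementary_expression(spec)
    return spec, X


class TestRunProtocol:
    def test_no_sources_gives_baseline_only(self):
        _, X = small_dataset()
        rep = run_protocol(X, {}, RepeatConfig(n_repeats=3, master_seed=1))
        assert rep.model_names == ["baseline"]
        assert rep.auc_matrix.shape == (3, 1)
        assert np.all((rep.auc_matrix >= 0) & (rep.auc_matrix <= 1))

    def test_identity_source_reproduces_baseline_bit_for_bit(self):
        _, X = small_dataset()
        rep = run_protocol(X, {"ident": identity_gmatrix(X.gene_ids)},
                           RepeatConfig(n_repeats=4, master_seed=2, rules=()))
        assert np.array_equal(rep.auc_vector("ident"), rep.auc_vector("baseline"))

    def test_informative_source_beats_baseline(self):
        spec, X = small_dataset(seed=9)
        from netkern import generate_pathway_source
        g = gmatrix_for_source(generate_pathway_source(spec), X.gene_ids)
        rep = run_protocol(X, {"true": g},
                           RepeatConfig(n_repeats=10, master_seed=3, rules=("mean",)))
        assert rep.mean_auc("true") > rep.mean_auc("baseline")

    def test_report_vectors_have_repeat_length(self):
        _, X = small_dataset()
        cfg = RepeatConfig(n_repeats=5, master_seed=0, rules=("mean", "median"))
        rep = run_protocol(X, {"ident": identity_gmatrix(X.gene_ids)}, cfg)
        for name in rep.model_names:
            assert rep.auc_vector(name).shape == (5,)

    def test_unaligned_gmatrix_rejected(self):
        _, X = small_dataset()
        with pytest.raises(ValueError, match="gene order"):
            run_protocol(X, {"bad": identity_gmatrix(list(reversed(X.gene_ids)))},
                         RepeatConfig(n_repeats=1))


class TestScoreSources:
    def test_table_pattern_two_beating_sources(self):
        scores = score_sources({"a": 0.81, "b": 0.82, "c": 0.70},
                               baseline_mean_auc=0.80, M=15)
        assert scores == {"b": 15, "a": 14, "c": 0}

    def test_no_source_beats_baseline(self):
        assert score_sources({"a": 0.5, "b": 0.6}, 0.7) == {"a": 0, "b": 0}

    def test_three_beating_sources_rank_arithmetic(self):
        scores = score_sources({"a": 0.9, "b": 0.85, "c": 0.8, "d": 0.1},
                               baseline_mean_auc=0.5, M=15)
        assert (scores["a"], scores["b"], scores["c"], scores["d"]) == (15, 14, 13, 0)

    def test_monotone_in_own_auc(self):
        before = score_sources({"a": 0.75, "b": 0.85}, 0.7, M=5)
        after = score_sources({"a": 0.9, "b": 0.85}, 0.7, M=5)
        assert after["a"] >= before["a"]

    def test_aggregate_is_column_sums(self):
        table = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
        sums = aggregate_scores(table)
        assert sums["a"] == 6 and sums["b"] == 0


class TestPairedT:
    def test_identical_vectors_give_half(self):
        a = np.array([0.7, 0.8, 0.9, 0.6])
        assert paired_t_one_sided(a, a) == pytest.approx(0.5)

    def test_consistent_positive_differences(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=30)
        a = b + 1.0 + 0.01 * rng.normal(size=30)
        assert paired_t_one_sided(a, b) < 1e-10

    def test_matches_scipy_on_mixed_vector(self):
        d = np.array([1.0, -1, 1, 1, 1, -1, 1, 1, 1, 1])
        b = np.zeros(10)
        expect = stats.ttest_rel(d, b, alternative="greater").pvalue
        assert paired_t_one_sided(d, b) == pytest.approx(expect)


def brute_force_signed_rank_p(d, sided):
    """2^n enumeration over all sign vectors (midranks for tied |d|)."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if sided == "greater":
        return ge / 2 ** n
    return min(1.0, 2 * min(ge, le) / 2 ** n)


class TestWilcoxon:
    def test_six_concordant_pairs(self):
        a = np.arange(6) + 1.0
        b = np.arange(6).astype(float)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.03125)

    def test_equal_vectors_give_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(a, a) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("sided", ["two-sided", "greater"])
    def test_exact_matches_enumeration_oracle(self, seed, sided):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = np.round(rng.normal(size=n), 1)  # rounding forces some ties
        a = d
        b = np.zeros(n)
        mine = wilcoxon_signed_rank(a, b, sided=sided, method="exact")
        assert mine == pytest.approx(brute_force_signed_rank_p(d, sided))

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(size=9)
        while len(np.unique(np.abs(d))) < 9:
            d = rng.normal(size=9)
        mine = wilcoxon_signed_rank(d, np.zeros(9), method="exact")
        ref = stats.wilcoxon(d, mode="exact").pvalue
        assert mine == pytest.approx(ref)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30) + 0.8
        b = np.zeros(30)
        p = wilcoxon_signed_rank(a, b, sided="greater")  # auto -> approx
        ref = stats.wilcoxon(a, b, alternative="greater", mode="approx",
                             correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestBinarize:
    def test_signs(self):
        assert list(binarize_predictions([0.5, -0.5])) == [1, 0]

    def test_zero_is_negative(self):
        assert binarize_predictions([0.0])[0] == 0

    def test_composition_with_lssvm_toy(self):
        m = train_weighted_lssvm(np.eye(2), np.array([1.0, -1.0]), gamma=1.0)
        f = decision_values(m, np.eye(2))
        assert list(binarize_predictions(f)) == [1, 0]


class TestMutualInformation:
    def test_independent_fair_coins(self):
        mi = mutual_information_from_joint(np.full((2, 2), 0.25))
        assert mi.value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_dependence_one_bit(self):
        mi = mutual_information_from_joint([[0.5, 0.0], [0.0, 0.5]])
        assert mi.value == pytest.approx(1.0)

    def test_worked_joint_table(self):
        mi = mutual_information_from_joint([[0.4, 0.1], [0.1, 0.4]])
        assert round(mi.value, 3) == 0.278

    def test_symmetric_nonnegative_bounded(self, rng):
        for _ in range(10):
            x = rng.integers(0, 2, size=40)
            y = rng.integers(0, 2, size=40)
            mxy = mutual_information_binary(x, y).value
            myx = mutual_information_binary(y, x).value
            assert mxy == pytest.approx(myx)
            assert 0.0 <= mxy <= 1.0

    def test_zero_under_empirical_independence(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information_binary(x, y).value == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_binary([], [])
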