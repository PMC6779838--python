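import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tkdseq import (
    TKDOT,
    TransitionTable,
    adjusted_residuals,
    analyze,
    expected_frequencies,
    g_test,
    pearson_chi_square,
    significance_masks,
    standardized_residuals,
    transition_counts,
    planted_pattern_spec,
    simulate_corpus,
)

from conftest import make_corpus


def table_ab(cells, lag=1):
    return TransitionTable(np.array(cells), ("A", "B"), lag)


class TestTransitionCounts:
    def test_within_sequence_pairs(self, ab_alphabet):
        corpus = make_corpus([["A", "B", "A", "B"]], alphabet=ab_alphabet)
        table = transition_counts(corpus, lag=1)
        assert table.observed[0, 1] == 2  # A->B
        assert table.observed[1, 0] == 1  # B->A
        assert table.n_pairs == 3

    def test_no_cross_boundary_pairs(self, ab_alphabet):
        corpus = make_corpus([["A", "B"], ["B", "A"]], alphabet=ab_alphabet)
        table = transition_counts(corpus, lag=1)
        assert table.observed[0, 1] == 1 and table.observed[1, 0] == 1
        assert table.n_pairs == 2

    def test_lag_two(self, ab_alphabet):
        corpus = make_corpus([["A", "B", "A", "B"]], alphabet=ab_alphabet)
        table = transition_counts(corpus, lag=2)
        assert table.observed[0, 0] == 1 and table.observed[1, 1] == 1
        assert table.n_pairs == 2

    def test_lag_beyond_length_warns_empty(self, ab_alphabet):
        corpus = make_corpus([["A", "B"]], alphabet=ab_alphabet)
        with pytest.warns(UserWarning, match="no lag-5 pairs"):
            table = transition_counts(corpus, lag=5)
        assert table.n_pairs == 0

    def test_pair_count_identity(self, ab_alphabet):
        corpus = make_corpus(
            [["A"], ["A", "B", "A"], ["B", "B"]], alphabet=ab_alphabet
        )
        table = transition_counts(corpus, lag=1)
        assert table.n_pairs == sum(max(len(s) - 1, 0) for s in corpus)


_seq_lists = st.lists(
    st.lists(st.sampled_from(["A", "B"]), min_size=1, max_size=12),
    min_size=1,
    max_size=5,
)


@settings(derandomize=True, max_examples=40)
@given(_seq_lists, _seq_lists, st.integers(1, 3))
def test_concatenation_adds_counts(seqs1, seqs2, lag):
    """Merging corpora never creates pairs that span their sequences."""
    import warnings as w

    from tkdseq import ActionCode, Alphabet, Corpus

    ab = Alphabet([ActionCode("A", "a", "attack"), ActionCode("B", "b", "defense")])
    c1, c2 = make_corpus(seqs1, alphabet=ab), make_corpus(seqs2, alphabet=ab)
    merged = Corpus(c1.sequences + c2.sequences, ab)
    with w.catch_warnings():
        w.simplefilter("ignore")
        total = transition_counts(merged, lag).observed
        parts = (
            transition_counts(c1, lag).observed
            + transition_counts(c2, lag).observed
        )
    assert (total == parts).all()


class TestExpectedFrequencies:
    def test_symmetric_marginals(self):
        e = expected_frequencies(table_ab([[10, 0], [0, 10]]))
        assert np.allclose(e, 5.0)

    def test_uniform_table_is_its_own_expectation(self):
        e = expected_frequencies(table_ab([[5, 5], [5, 5]]))
        assert np.allclose(e, 5.0)

    def test_zero_row_gives_zero_expected_row(self):
        e = expected_frequencies(table_ab([[3, 4], [0, 0]]))
        assert np.allclose(e[1], 0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expected_frequencies(table_ab([[0, 0], [0, 0]]))

    def test_conservation(self):
        table = table_ab([[3, 9], [1, 7]])
        assert expected_frequencies(table).sum() == pytest.approx(table.n_pairs)


class TestOmnibusTests:
    def test_chi_square_hand_value(self):
        table = table_ab([[10, 0], [0, 10]])
        stat, df, p = pearson_chi_square(table, expected_frequencies(table))
        assert stat == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_chi_square_zero_at_independence(self):
        table = table_ab([[5, 5], [5, 5]])
        stat, _, p = pearson_chi_square(table, expected_frequencies(table))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_nine_code_df_is_64(self):
        table = TransitionTable(np.ones((9, 9), dtype=int), TKDOT.codes, 1)
        assert pearson_chi_square(table, expected_frequencies(table)).df == 64
        assert g_test(table, expected_frequencies(table)).df == 64

    def test_g_hand_value(self):
        table = table_ab([[10, 0], [0, 10]])
        stat, df, _ = g_test(table, expected_frequencies(table))
        assert stat == pytest.approx(40.0 * math.log(2.0))
        assert df == 1

    def test_g_zero_at_independence(self):
        table = table_ab([[5, 5], [5, 5]])
        assert g_test(table, expected_frequencies(table)).statistic == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    def test_g_nonnegative(self, cells):
        table = table_ab(np.array(cells).reshape(2, 2))
        if table.n_pairs == 0:
            return
        assert g_test(table, expected_frequencies(table)).statistic >= -1e-12


class TestAdjustedResiduals:
    def test_hand_value(self):
        table = table_ab([[10, 0], [0, 10]])
        z = adjusted_residuals(table, expected_frequencies(table))
        expected = 5.0 / math.sqrt(5.0 * 0.5 * 0.5)
        assert z[0, 0] == pytest.approx(expected)      # ~4.4721
        assert z[0, 1] == pytest.approx(-expected)

    def test_uniform_table_all_zero(self):
        table = table_ab([[5, 5], [5, 5]])
        assert np.allclose(adjusted_residuals(table, expected_frequencies(table)), 0)

    def test_degenerate_cells_zero(self):
        table = table_ab([[3, 4], [0, 0]])
        z = adjusted_residuals(table, expected_frequencies(table))
        assert np.all(np.isfinite(z))
        assert np.allclose(z[1], 0.0)

    def test_standardized_variant(self):
        table = table_ab([[10, 0], [0, 10]])
        z = standardized_residuals(table, expected_frequencies(table))
        assert z[0, 0] == pytest.approx(5.0 / math.sqrt(5.0))


class TestSignificanceMasks:
    def test_strict_threshold_and_disjoint(self):
        z = np.array([[4.47, 1.96], [-2.5, 0.0]])
        exc, inh = significance_masks(z, 1.96)
        assert exc[0, 0] and not exc[0, 1]   # exactly 1.96 is not significant
        assert inh[1, 0]
        assert not (exc & inh).any()

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            significance_masks(np.zeros((2, 2)), 0.0)


class TestOracleEquivalence:
    """chi2, G2 and adjusted residuals vs direct loop evaluation (and scipy)."""

    @staticmethod
    def brute_force(observed):
        o = observed.astype(float)
        n = o.sum()
        rows, cols = o.sum(axis=1), o.sum(axis=0)
        k = o.shape[0]
        e = np.zeros_like(o)
        chi2 = g2 = 0.0
        z = np.zeros_like(o)
        for i in range(k):
            for j in range(k):
                e[i, j] = rows[i] * cols[j] / n
                if e[i, j] > 0:
                    chi2 += (o[i, j] - e[i, j]) ** 2 / e[i, j]
                if o[i, j] > 0:
                    g2 += 2.0 * o[i, j] * math.log(o[i, j] / e[i, j])
                var = e[i, j] * (1 - rows[i] / n) * (1 - cols[j] / n)
                if var > 0:
                    z[i, j] = (o[i, j] - e[i, j]) / math.sqrt(var)
        return e, chi2, g2, z

    @pytest.mark.parametrize("k", [2, 3])
    def test_random_small_tables(self, k):
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 200:
            observed = rng.integers(0, 6, size=(k, k))
            if observed.sum() == 0:
                continue
            checked += 1
            table = TransitionTable(observed, tuple("ABC"[:k]), 1)
            e_ref, chi2_ref, g2_ref, z_ref = self.brute_force(observed)
            e = expected_frequencies(table)
            np.testing.assert_allclose(e, e_ref, rtol=1e-9, atol=1e-12)
            assert pearson_chi_square(table, e).statistic == pytest.approx(
                chi2_ref, rel=1e-9, abs=1e-12
            )
            assert g_test(table, e).statistic == pytest.approx(
                g2_ref, rel=1e-9, abs=1e-12
            )
            np.testing.assert_allclose(
                adjusted_residuals(table, e), z_ref, rtol=1e-9, atol=1e-12
            )

    def test_chi_square_agrees_with_scipy_contingency(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            observed = rng.integers(1, 30, size=(3, 3))
            table = TransitionTable(observed, ("A", "B", "C"), 1)
            e = expected_frequencies(table)
            ours = pearson_chi_square(table, e)
            ref = stats.chi2_contingency(observed, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.df == (3 - 1) ** 2 == ref.dof
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_g_agrees_with_scipy_lambda_llr(self):
        rng = np.random.default_rng(8)
        observed = rng.integers(1, 30, size=(3, 3))
        table = TransitionTable(observed, ("A", "B", "C"), 1)
        e = expected_frequencies(table)
        ref = stats.chi2_contingency(
            observed, correction=False, lambda_="log-likelihood"
        )
        assert g_test(table, e).statistic == pytest.approx(ref.statistic, rel=1e-12)


class TestAnalyze:
    def test_composition_identity(self, ab_alphabet):
        corpus = make_corpus([["A", "B", "A", "B"]], alphabet=ab_alphabet)
        result = analyze(corpus)
        assert (result.table.observed == transition_counts(corpus, 1).observed).all()
        assert result.z_threshold == pytest.approx(stats.norm.ppf(0.975))

    def test_planted_transition_detected(self):
        spec = planted_pattern_spec(
            [("DIA", "SCA", 0.8)], n_sequences=200, length=50, seed=42
        )
        result = analyze(simulate_corpus(spec))
        i, j = TKDOT.index("DIA"), TKDOT.index("SCA")
        assert result.excitatory[i, j]
        assert result.p_chi2 < 0.01 and result.p_g2 < 0.01

    def test_empty_corpus_rejected(self):
        from tkdseq import Corpus

        with pytest.raises(ValueError, match="empty"):
            analyze(Corpus((), TKDOT))

    def test_deterministic_for_fixed_input(self, tiny_corpus):
        r1, r2 = analyze(tiny_corpus), analyze(tiny_corpus)
        assert np.array_equal(r1.z, r2.z)
        assert r1.chi2 == r2.chi2 and r1.g2 == r2.g2
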