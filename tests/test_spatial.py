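"""Fixed-margin randomization test: sampler, statistics, P-values, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from haplospatial import (ContingencyMatrix, build_null_ensemble,
                          cell_p_values, chi_squared_obs, fdr_calls,
                          pool_locations, sample_random_table, spatial_test,
                          ts_diff, whole_table_test)


def _random_matrix(rng, shape=(4, 3), lam=4.0):
    while True:
        counts = rng.poisson(lam, size=shape)
        m = ContingencyMatrix(counts, (), ())
        if (m.row_totals > 0).all() and (m.col_totals > 0).all():
            return m


class TestSampler:
    def test_forced_single_cell(self):
        t = sample_random_table([3], [3], np.random.default_rng(0))
        assert t.tolist() == [[3]]

    def test_forced_by_zero_column(self):
        t = sample_random_table([1, 1], [2, 0], np.random.default_rng(0))
        assert t.tolist() == [[1, 0], [1, 0]]

    def test_margin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sample_random_table([2, 2], [3, 2], np.random.default_rng(0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 8), min_size=1, max_size=5),
           st.integers(0, 2 ** 31 - 1), st.data())
    def test_margins_always_preserved(self, rows, seed, data):
        n = sum(rows)
        # split n into column totals
        k = data.draw(st.integers(1, 4))
        cuts = sorted(data.draw(st.lists(st.integers(0, n), min_size=k - 1,
                                         max_size=k - 1)))
        cols = np.diff([0, *cuts, n])
        t = sample_random_table(rows, cols, np.random.default_rng(seed))
        assert t.sum(axis=1).tolist() == list(rows)
        assert t.sum(axis=0).tolist() == list(cols)
        assert (t >= 0).all()

    def test_2x2_matches_exhaustive_enumeration(self):
        """Margins [2,2]/[2,2] admit top-left counts 0,1,2 with conditional
        (hypergeometric) probabilities 1/6, 4/6, 1/6."""
        rng = np.random.default_rng(7)
        draws = sample_random_table([2, 2], [2, 2], rng, size=60_000)
        k = draws[:, 0, 0]
        probs = np.array([1, 4, 1]) / 6.0
        for value, p in zip((0, 1, 2), probs):
            freq = (k == value).mean()
            se = np.sqrt(p * (1 - p) / k.size)
            assert abs(freq - p) <= 3 * se


class TestChiSquared:
    def test_zero_when_observed_equals_expectation(self):
        m = ContingencyMatrix([[1, 1], [1, 1]], (), ())
        ens = build_null_ensemble(m, mode="analytic")
        assert chi_squared_obs(m, ens) == 0.0

    def test_hand_example(self, small_matrix):
        ens = build_null_ensemble(small_matrix, mode="analytic")
        assert chi_squared_obs(small_matrix, ens) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_analytic_mode_equals_pearson_statistic(self, seed):
        m = _random_matrix(np.random.default_rng(seed))
        ens = build_null_ensemble(m, mode="analytic")
        ours = chi_squared_obs(m, ens)
        pearson = stats.chi2_contingency(m.counts, correction=False).statistic
        assert ours == pytest.approx(pearson, abs=1e-9)

    def test_monte_carlo_mean_converges_to_analytic(self, small_matrix):
        analytic = build_null_ensemble(small_matrix, mode="analytic").mean
        ens = build_null_ensemble(small_matrix, m=10_000, seed=3)
        # per-cell SE of the Monte-Carlo mean, bounded by the count range
        se = np.sqrt(ens.mean * (1 - ens.mean / small_matrix.n) / ens.m) + 1e-9
        assert (np.abs(ens.mean - analytic) <= 4 * se).all()

    def test_single_row_mean_equals_column_totals(self):
        m = ContingencyMatrix([[2, 5, 3]], (), ())
        ens = build_null_ensemble(m, m=100, seed=0)
        np.testing.assert_allclose(ens.mean, [[2, 5, 3]])


class TestTsDiff:
    def test_cell_at_null_mean_is_zero(self):
        m = ContingencyMatrix([[1, 1], [1, 1]], (), ())
        ens = build_null_ensemble(m, mode="analytic")
        assert (ts_diff(m, ens) == 0).all()

    def test_hand_example(self, small_matrix):
        ens = build_null_ensemble(small_matrix, mode="analytic")
        np.testing.assert_allclose(ts_diff(small_matrix, ens),
                                   [[1, -1], [-1, 1]])

    @pytest.mark.parametrize("seed", range(5))
    def test_row_and_column_sums_vanish_in_analytic_mode(self, seed):
        m = _random_matrix(np.random.default_rng(seed), shape=(5, 4))
        ens = build_null_ensemble(m, mode="analytic")
        d = ts_diff(m, ens)
        np.testing.assert_allclose(d.sum(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(d.sum(axis=1), 0, atol=1e-9)


class TestPermutationPValues:
    def test_degenerate_distribution_reports_one(self):
        """When the statistic is constant, raw P = 2.0 rounds down to 1.0."""
        m = ContingencyMatrix([[4]], (), ())
        _, p = whole_table_test(m, m=100, seed=0)
        assert p == 1.0

    def test_forced_cell_p_is_one(self):
        m = ContingencyMatrix([[4]], (), ())
        p = cell_p_values(m, m=50, seed=0)
        assert p[0, 0] == 1.0

    def test_p_values_never_exceed_one(self):
        rng = np.random.default_rng(5)
        for seed in range(4):
            m = _random_matrix(rng)
            chi2, p = whole_table_test(m, m=500, seed=seed)
            cells = cell_p_values(m, m=500, seed=seed)
            assert 0.0 <= p <= 1.0
            assert (cells > 0).all() and (cells <= 1.0).all()

    def test_cell_p_matches_hypergeometric_enumeration(self):
        """2x2 with margins [2,2]/[2,2], observed diagonal table: the top-left
        count is 2; P(K >= 2) = 1/6 and P(K <= 2) = 1, so the two-tailed
        P-value is 1/3."""
        m = ContingencyMatrix([[2, 0], [0, 2]], (), ())
        big = 20_000
        p = cell_p_values(m, m=big, seed=9)
        se = np.sqrt((1 / 6) * (5 / 6) / big)
        assert abs(p[0, 0] - 2 / 6) <= 2 * 3 * se

    def test_whole_table_p_within_enumeration_bounds(self):
        """Same toy table: the chi-squared values of the three allowable
        tables tie pairwise around the null mean, so the two-tailed P lies
        between 2*P(K=2) = 1/3 and 2*P(K in {0,2}) = 2/3 depending on how
        Monte-Carlo noise breaks the tie."""
        m = ContingencyMatrix([[2, 0], [0, 2]], (), ())
        _, p = whole_table_test(m, m=20_000, seed=11)
        assert 1 / 3 - 0.02 <= p <= 2 / 3 + 0.02

    def test_structured_matrix_strongly_rejected(self):
        block = np.array([[30, 0, 0], [0, 30, 0], [0, 0, 30],
                          [5, 5, 5]])
        m = ContingencyMatrix(block, (), ())
        chi2, p = whole_table_test(m, m=2000, seed=1)
        assert p == 0.0 and chi2 > 50


class TestFdr:
    def _bh_oracle(self, p, q):
        """Literal Benjamini-Hochberg step-up definition."""
        p = np.asarray(p, float)
        order = np.argsort(p)
        m = p.size
        thresh = q * (np.arange(1, m + 1)) / m
        passing = np.nonzero(p[order] <= thresh)[0]
        reject = np.zeros(m, bool)
        if passing.size:
            reject[order[: passing.max() + 1]] = True
        return reject

    def test_all_ones_give_no_flags(self):
        assert not fdr_calls(np.ones((3, 4)), q=0.10).any()

    def test_matches_stepup_oracle_on_fixed_set(self):
        p = np.array([0.001, 0.02, 0.03, 0.04, 0.5, 0.7, 0.9, 1.0])
        got = fdr_calls(p.reshape(2, 4), q=0.05).ravel()
        np.testing.assert_array_equal(got, self._bh_oracle(p, 0.05))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_stepup_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        p = np.clip(rng.uniform(size=24) ** 2, 1e-6, 1.0)
        for q in (0.05, 0.10):
            np.testing.assert_array_equal(
                fdr_calls(p.reshape(4, 6), q=q), self._bh_oracle(p, q).reshape(4, 6))


class TestPooling:
    def test_identity_grouping(self, small_matrix):
        grouping = {c: c for c in small_matrix.col_labels}
        pooled = pool_locations(small_matrix, grouping)
        np.testing.assert_array_equal(pooled.counts, small_matrix.counts)

    def test_grand_total_preserved(self, paper_scale_template):
        grouping = {c: ("BRA" if j < 8 else "nonBRA")
                    for j, c in enumerate(paper_scale_template.col_labels)}
        pooled = pool_locations(paper_scale_template, grouping)
        assert pooled.n == paper_scale_template.n
        assert pooled.shape == (25, 2)
        np.testing.assert_array_equal(pooled.row_totals,
                                      paper_scale_template.row_totals)

    def test_unassigned_column_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="without a group"):
            pool_locations(small_matrix, {small_matrix.col_labels[0]: "g"})


class TestInvariances:
    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_results_invariant_under_permutation(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_matrix(rng, shape=(5, 4))
        rp = rng.permutation(5)
        cp = rng.permutation(4)
        mp = ContingencyMatrix(m.counts[np.ix_(rp, cp)],
                               tuple(np.array(m.row_labels)[rp]),
                               tuple(np.array(m.col_labels)[cp]))
        e1 = build_null_ensemble(m, mode="analytic")
        e2 = build_null_ensemble(mp, mode="analytic")
        assert chi_squared_obs(m, e1) == pytest.approx(
            chi_squared_obs(mp, e2), abs=1e-9)
        np.testing.assert_allclose(ts_diff(m, e1)[np.ix_(rp, cp)],
                                   ts_diff(mp, e2), atol=1e-9)

    def test_empty_margins_dropped_with_warning(self):
        m = ContingencyMatrix([[2, 0, 3], [0, 0, 0], [1, 0, 4]], (), ())
        with pytest.warns(UserWarning, match="dropping"):
            reduced = m.drop_empty()
        assert reduced.shape == (2, 2)
        assert reduced.n == m.n


def test_full_test_result_contract(small_matrix):
    res = spatial_test(small_matrix, m=500, seed=4, fdr_q=0.10)
    assert res.ts_diff.shape == small_matrix.shape
    assert ((res.p_cell > 0) & (res.p_cell <= 1)).all()
    np.testing.assert_array_equal(res.direction, np.sign(res.ts_diff))
    assert set(np.unique(res.heat_table().to_numpy())) <= {
        "sig_over", "sig_under", "ns_over", "ns_under"}
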