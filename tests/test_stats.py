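"""Statistical primitives vs independent enumeration/permutation oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from embryodyn.stats import (bh_fdr, fisher_exact, mann_whitney_u,
                             pearson_test, two_sample_log_test)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d, alternative="two-sided"):
    """Direct hypergeometric enumeration with exact rational-ish arithmetic."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    denom = math.comb(n, col1)
    probs = {k: math.comb(row1, k) * math.comb(n - row1, col1 - k) / denom
             for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in probs.items() if k <= a)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))

def mwu_oracle_two_sided(x, y):
    """Enumerate every assignment of the pooled ranks to sample x."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled)); ranks[order] = np.arange(1, len(pooled) + 1)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    tail = min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, 2 * tail)

def bh_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

class TestFisher:
    def test_small_table_matches_enumeration(self):
        res = fisher_exact(3, 1, 1, 3)
        assert res.p_value == pytest.approx(fisher_oracle(3, 1, 1, 3),
                                            abs=1e-12)

    def test_minimal_observed_gives_p_one_greater(self):
        assert fisher_exact(0, 5, 5, 0, alternative="greater").p_value == \
            pytest.approx(1.0)

    def test_sweep_small_tables_against_oracle(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            for alt in ("two-sided", "greater", "less"):
                assert fisher_exact(a, b, c, d, alt).p_value == pytest.approx(
                    fisher_oracle(a, b, c, d, alt), abs=1e-10), (a, b, c, d, alt)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)

    def test_symmetric_under_row_and_column_swap(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, 4)
            if a + b + c + d == 0:
                continue
            p1 = fisher_exact(int(a), int(b), int(c), int(d)).p_value
            p2 = fisher_exact(int(d), int(c), int(b), int(a)).p_value
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_infinite_odds_ratio_flag(self):
        res = fisher_exact(5, 0, 0, 5)
        assert res.effect == np.inf


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_near_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (5, 6), (6, 6)])
    def test_exact_mode_matches_assignment_enumeration(self, n1, n2, rng):
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert mann_whitney_u(x, y).p_value == pytest.approx(
                mwu_oracle_two_sided(x, y), abs=1e-12)

    def test_normal_approximation_close_to_permutation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.3, 1, size=30)
        p = mann_whitney_u(x, y).p_value
        pooled = np.concatenate([x, y])
        stats = []
        for _ in range(20_000):
            perm = rng.permutation(pooled)
            stats.append(mann_whitney_u_stat(perm[:30], perm[30:]))
        obs = mann_whitney_u_stat(x, y)
        stats = np.array(stats)
        mu = 30 * 30 / 2
        p_perm = min(1.0, 2 * min((stats <= obs).mean(), (stats >= obs).mean()))
        assert abs(p - p_perm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def mann_whitney_u_stat(x, y):
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    r = rankdata(pooled)
    return r[:len(x)].sum() - len(x) * (len(x) + 1) / 2


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

class TestPearson:
    def test_identity_gives_r_one_p_zero(self):
        x = np.arange(8.0)
        res = pearson_test(x, x)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_orthogonal_gives_p_one(self):
        x = np.array([1., -1, 1, -1, 1, -1])
        y = np.array([1., 1, -1, -1, 1, 1]) * np.sqrt(2)
        y = y - y.mean()
        res = pearson_test(x, y)
        assert abs(res.statistic) < 1e-12
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        res = pearson_test(np.ones(5), np.arange(5.0))
        assert res.undefined and res.p_value == 1.0

    def test_p_close_to_permutation_oracle(self, rng):
        x = rng.normal(size=8)
        y = 0.6 * x + rng.normal(size=8)
        p = pearson_test(x, y).p_value
        robs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        n_perm = 50_000
        for _ in range(n_perm):
            count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= robs
        assert abs(p - count / n_perm) < 0.03


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_oracle_case(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_matches_independent_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(size=1000)
            assert np.allclose(bh_fdr(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_reapplication_never_decreases(self, pvals):
        q = bh_fdr(pvals)
        q2 = bh_fdr(q)
        assert (q2 >= q - 1e-12).all()


# ---------------------------------------------------------------------------
# two-sample log test
# ---------------------------------------------------------------------------

class TestTwoSampleLog:
    def test_identical_groups_null(self):
        res = two_sample_log_test([10, 20, 30], [10, 20, 30])
        assert res.effect == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_fourfold_change_log2fc_two(self):
        a = np.array([1000., 2000, 1500])
        res = two_sample_log_test(a, 4 * a)
        assert res.effect == pytest.approx(2.0, abs=0.01)

    def test_replicate_deficit_rejected(self):
        with pytest.raises(ValueError):
            two_sample_log_test([1.0], [1.0, 2.0])

    def test_null_type_one_rate_calibrated(self, rng):
        hits = 0
        n_genes = 5000
        for _ in range(n_genes):
            base = rng.gamma(2, 50)
            a = rng.poisson(base, 3)
            b = rng.poisson(base, 3)
            if two_sample_log_test(a, b).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_genes <= 0.08
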