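"""Nonparametric statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata, pearsonr

from moodrpe.stats import (
    CollinearCovariatesError,
    ConstantInputError,
    DegenerateInputError,
    apply_exclusion,
    ranksum_test,
    residualized_spearman,
    signedrank_test,
    spearman,
)


# ---------------------------------------------------------------------------
# independent oracles

def rank_then_pearson(x, y):
    return pearsonr(rankdata(x), rankdata(y))[0]


def ranksum_permutation_z(a, b):
    """Standardize group A's rank sum by the moments of its exhaustive
    permutation distribution."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = len(a)
    ws = np.array([
        ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)
    ])
    w = ranks[:n1].sum()
    sd = ws.std(ddof=0)
    return 0.0 if sd == 0 else (w - ws.mean()) / sd, ws, w


def signedrank_permutation(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    wpos = ranks[d > 0].sum()
    ws = np.array([
        np.dot(signs, ranks) for signs in itertools.product((0, 1), repeat=len(d))
    ])
    sd = ws.std(ddof=0)
    z = 0.0 if sd == 0 else (wpos - ws.mean()) / sd
    return z, ws, wpos


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3], [2, 4, 6]).estimate == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 1 - 6*6 / (3*(9-1)) = -0.5
        assert spearman([1, 2, 3], [3, 1, 2]).estimate == pytest.approx(-0.5)

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).estimate == pytest.approx(
                rank_then_pearson(x, y), abs=1e-12
            )

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(
            st.floats(-100, 100).map(lambda v: round(v, 3)),
            min_size=4, max_size=15, unique=True,
        )
    )
    def test_invariant_under_monotone_transforms(self, xs):
        rng = np.random.default_rng(42)
        y = rng.permutation(len(xs)).astype(float)
        x = np.asarray(xs)
        base = spearman(x, y).estimate
        assert spearman(np.exp(x / 100), y).estimate == pytest.approx(base, abs=1e-12)
        assert spearman(x, 2 * y + 5).estimate == pytest.approx(base, abs=1e-12)


class TestResidualizedSpearman:
    def test_orthogonal_covariates_change_little(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        raw = spearman(x, y).estimate
        adj = residualized_spearman(x, y, cov).estimate
        assert abs(adj - raw) <= 3.0 / np.sqrt(n - 1)

    def test_fully_absorbed_variable(self):
        rng = np.random.default_rng(2)
        n = 300
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        res = residualized_spearman(x, c, pd.DataFrame({"c": c}))
        assert abs(res.estimate) <= 3.0 / np.sqrt(n - 1)

    def test_deconfounding_shrinks_a_shared_driver(self):
        """When age drives both variables, removing it shrinks |rho| in
        at least 90% of seeded draws."""
        shrunk = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 200
            age = rng.normal(size=n)
            x = age + 0.5 * rng.normal(size=n)
            y = age + 0.5 * rng.normal(size=n)
            cov = pd.DataFrame({"age": age})
            raw = spearman(x, y).estimate
            adj = residualized_spearman(x, y, cov).estimate
            shrunk += abs(adj) < abs(raw)
        assert shrunk >= 90

    def test_collinear_columns_are_named(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        cov = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(CollinearCovariatesError, match="twice_a"):
            residualized_spearman(rng.normal(size=50), rng.normal(size=50), cov)

    def test_degree_indicator_covariate(self):
        rng = np.random.default_rng(4)
        n = 120
        cov = pd.DataFrame({"degree": rng.random(n) < 0.6, "age": rng.normal(34, 10, n)})
        res = residualized_spearman(rng.normal(size=n), rng.normal(size=n), cov)
        assert res.covariates == ("degree", "age")


class TestRankTests:
    def test_identical_groups(self):
        res = ranksum_test([1, 2, 3], [1, 2, 3])
        assert res.estimate == 0.0
        assert res.p == 1.0

    def test_separated_groups_match_permutation_oracle(self):
        a = np.arange(10, dtype=float)
        b = np.arange(10, dtype=float) + 100
        z, *_ = ranksum_permutation_z(a, b)  # n=10: oracle via enumeration
        res = ranksum_test(a, b)
        assert res.estimate == pytest.approx(z, abs=1e-6)
        assert res.estimate < 0  # group a has the lower mean rank

    def test_z_sign_follows_mean_rank_difference(self):
        res = ranksum_test([5, 6, 7, 8, 9, 10, 11, 12, 13, 14], [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        assert res.estimate > 0

    def test_single_positive_pair_signedrank(self):
        res = signedrank_test([0.7])
        assert res.p == 1.0

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            signedrank_test([1.0, 2.0], [1.0, 2.0])

    def test_exhaustive_oracle_equivalence_small_n(self):
        """z and exact p match the exhaustive permutation oracle for every
        random input with group sizes up to 8 (ties included)."""
        rng = np.random.default_rng(7)
        for n1, n2 in [(2, 3), (4, 4), (5, 8), (8, 8), (3, 6)]:
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            z, ws, w = ranksum_permutation_z(a, b)
            res = ranksum_test(a, b)
            assert res.estimate == pytest.approx(z, abs=1e-6)
            dev = abs(w - ws.mean())
            p_exact = np.mean(np.abs(ws - ws.mean()) >= dev - 1e-12)
            assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_signedrank_oracle_equivalence_small_n(self):
        rng = np.random.default_rng(8)
        for n in (2, 4, 6, 8):
            d = rng.integers(-4, 5, n).astype(float)
            if not np.any(d != 0):
                continue
            z, ws, wpos = signedrank_permutation(d)
            res = signedrank_test(d)
            assert res.estimate == pytest.approx(z, abs=1e-6)
            dev = abs(wpos - ws.mean())
            p_exact = np.mean(np.abs(ws - ws.mean()) >= dev - 1e-12)
            assert res.p == pytest.approx(p_exact, abs=1e-12)


class TestExclusion:
    def test_strict_inequality_boundary(self):
        kept = apply_exclusion(["a", "b", "c"], [0, 30, 31])
        assert kept == ["a", "b"]

    def test_three_failures_among_35(self):
        ids = list(range(35))
        counts = [5] * 32 + [31, 40, 60]
        assert len(apply_exclusion(ids, counts)) == 32

    def test_empty_cohort(self):
        assert apply_exclusion([], []) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_exclusion(["a"], [-1])
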