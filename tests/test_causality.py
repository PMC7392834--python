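"""CI overlap, overlap regression, Bonferroni-by-uncorrelated and LEO scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aileqtl.causality import (
    bonferroni_uncorrelated,
    ci_overlap,
    leo_multi,
    leo_single,
    overlap_regression,
)
from aileqtl.datatypes import CovariateTable
from aileqtl.sem import PathModel


def _cov(n, rng=None):
    sex = ["F" if k % 2 else "M" for k in range(n)]
    batch = [f"b{k % 3}" for k in range(n)]
    return CovariateTable(pd.DataFrame({"sex": sex, "batch": batch},
                                       index=[f"i{k}" for k in range(n)]))


class TestCiOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        (("1", 10, 30), ("1", 20, 40), (20, 30)),
        (("1", 10, 20), ("1", 30, 40), None),
        (("1", 10, 20), ("2", 10, 20), None),
        (("8", 79, 123), ("8", 42, 89), (79, 89)),   # published overlap example
        (("1", 0, 10), ("1", 10, 20), (10, 10)),     # closed endpoints touch
    ])
    def test_intersection(self, a, b, expected):
        assert ci_overlap(a, b) == expected
        # symmetric
        assert ci_overlap(b, a) == expected


class TestOverlapRegression:
    def test_perfect_relationship(self, rng):
        n = 40
        x = rng.normal(size=n)
        p, t, r2 = overlap_regression(2 * x, x, _cov(n))
        assert p < 1e-20
        assert r2 > 0.999

    def test_constant_expression_flagged(self, rng):
        n = 30
        p, t, r2 = overlap_regression(rng.normal(size=n), np.ones(n), _cov(n))
        assert p == 1.0 and t == 0.0

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        n = 40
        cov = _cov(n)
        ps = [overlap_regression(rng.normal(size=n), rng.normal(size=n), cov)[0]
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_coefficient_recovery_within_2se(self):
        rng = np.random.default_rng(6)
        import statsmodels.api as sm
        n, beta, hits = 80, 0.7, 0
        cov = _cov(n)
        for _ in range(100):
            x = rng.normal(size=n)
            y = beta * x + rng.normal(size=n)
            X = np.column_stack([cov.design(), x])
            fit = sm.OLS(y, X).fit()
            hits += abs(fit.params[-1] - beta) <= 2 * fit.bse[-1]
        assert hits >= 93  # ~95% coverage with binomial slack


class TestBonferroni:
    def test_fully_correlated_counts_once(self, rng):
        base = rng.normal(size=30)
        E = np.vstack([base, 2 * base + 1, -base])
        adj, m = bonferroni_uncorrelated(np.array([0.01, 0.02, 0.03]), E)
        assert m == 1
        np.testing.assert_allclose(adj, [0.01, 0.02, 0.03])

    def test_uncorrelated_multiply_by_k(self, rng):
        E = rng.normal(size=(4, 500))
        adj, m = bonferroni_uncorrelated(np.array([0.01] * 4), E)
        assert m == 4
        np.testing.assert_allclose(adj, 0.04)

    def test_three_blocks_recovered(self, rng):
        blocks = []
        for _ in range(3):
            b = rng.normal(size=300)
            blocks += [b + rng.normal(0, 0.1, 300) for _ in range(4)]
        adj, m = bonferroni_uncorrelated(np.full(12, 0.01), np.vstack(blocks))
        assert m == 3

    def test_never_below_raw_and_order_invariant(self, rng):
        E = rng.normal(size=(6, 100))
        p = rng.uniform(size=6)
        adj, m = bonferroni_uncorrelated(p, E)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(6)
        adj2, m2 = bonferroni_uncorrelated(p[perm], E[perm])
        assert m2 == m


class TestSemFit:
    def test_saturated_model_fits_exactly(self, rng):
        data = rng.normal(size=(100, 3))
        S = np.cov(data, rowvar=False)
        # fully connected recursive model: saturated, F_min = 0
        fit = PathModel(["M", "A", "B"], [("M", "A"), ("M", "B"), ("A", "B")]).fit(S, 100)
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value == 1.0 and fit.flagged

    def test_chi_square_null_calibration(self):
        rng = np.random.default_rng(8)
        n = 500
        ps = []
        for _ in range(300):
            M = rng.normal(size=n)
            A = 0.6 * M + rng.normal(size=n)
            B = 0.6 * A + rng.normal(size=n)
            S = np.cov(np.column_stack([M, A, B]), rowvar=False)
            ps.append(PathModel(["M", "A", "B"], [("M", "A"), ("A", "B")]).fit(S, n).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_misspecified_model_rejected(self):
        rng = np.random.default_rng(9)
        n, rejected = 500, 0
        causal = PathModel(["M", "A", "B"], [("M", "A"), ("A", "B")])
        for _ in range(100):
            M = rng.normal(size=n)
            B = 0.8 * M + rng.normal(size=n)       # true reactive
            A = 0.8 * B + rng.normal(size=n)
            S = np.cov(np.column_stack([M, A, B]), rowvar=False)
            rejected += causal.fit(S, n).p_value < 0.05
        assert rejected >= 90

    def test_fit_invariant_to_variable_rescaling(self, rng):
        n = 300
        M = rng.normal(size=n)
        A = 0.5 * M + rng.normal(size=n)
        B = 0.5 * A + rng.normal(size=n)
        X = np.column_stack([M, A, B])
        m = PathModel(["M", "A", "B"], [("M", "A"), ("A", "B")])
        f1 = m.fit(np.cov(X, rowvar=False), n)
        X2 = X * np.array([3.0, 0.2, 11.0])
        f2 = m.fit(np.cov(X2, rowvar=False), n)
        assert f1.chi_square == pytest.approx(f2.chi_square, rel=1e-8)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            PathModel(["A", "B"], [("A", "B"), ("B", "A")])


class TestLeo:
    def test_causal_reactive_sign_symmetry(self, rng):
        n = 300
        M = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
        A = 0.6 * M + rng.normal(size=n)
        B = 0.6 * A + rng.normal(size=n)
        fwd = leo_single(M, A, B)
        swapped = leo_single(M, B, A)   # roles exchanged: now truly reactive
        assert fwd.leo_nb > 0
        assert swapped.leo_nb < 0

    def test_uninformative_anchors_give_small_scores(self):
        rng = np.random.default_rng(10)
        scores = []
        for _ in range(60):
            n = 200
            MA = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
            MB = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
            A = rng.normal(size=n)
            B = rng.normal(size=n)
            scores.append(leo_multi(MA, MB, A, B, mode="oca").leo_nb_oca)
        assert abs(np.median(scores)) < 0.3

    def test_oca_recovers_direction_with_strong_anchors(self):
        rng = np.random.default_rng(11)
        called = 0
        for _ in range(50):
            n = 200
            MA = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
            MB = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
            A = 0.6 * MA + rng.normal(size=n)
            B = 0.6 * MB + 0.6 * A + rng.normal(size=n)
            r = leo_multi(MA, MB, A, B, mode="oca")
            called += r.edge_call == "probeset->trait"
        assert called >= 40   # >= 80% of replicates

    def test_p_floor_prevents_infinite_scores(self, rng):
        n = 2000
        M = rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.5, 0.25], size=n)
        A = 2.0 * M + 0.01 * rng.normal(size=n)
        B = 2.0 * A + 0.01 * rng.normal(size=n)
        r = leo_single(M, A, B)
        assert np.isfinite(r.leo_nb)
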