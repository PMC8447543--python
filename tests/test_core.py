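"""Restricted least squares, the GIC and the selection procedure Phi."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from subspaceboost import (
    CriterionSpec,
    Dataset,
    center,
    gic,
    phi_select,
    restricted_ls,
)


def _brute_force_phi(ds, candidate, crit):
    """Independent oracle: enumerate all subsets with numpy lstsq."""
    lam = crit.penalty(ds.n, ds.p)
    best = None
    for size in range(len(candidate) + 1):
        for combo in itertools.combinations(sorted(candidate), size):
            if combo:
                cols = np.array(combo) - 1
                coef, *_ = np.linalg.lstsq(ds.X[:, cols], ds.y, rcond=None)
                resid = ds.y - ds.X[:, cols] @ coef
                rss = float(resid @ resid)
            else:
                rss = float(ds.y @ ds.y)
            rss = max(rss, 1e-12 * float(ds.y @ ds.y))
            val = ds.n * math.log(rss / ds.n) + lam * size
            if best is None or val < best[0] - 1e-9:
                best = (val, combo)
    return best[1]


class TestRestrictedLS:
    def test_empty_subset_is_null_model(self, small_dataset):
        fit = restricted_ls(small_dataset, ())
        assert fit.subset == ()
        assert np.all(fit.coefficients == 0)
        assert fit.rss == pytest.approx(float(small_dataset.y @ small_dataset.y))

    def test_orthonormal_projection(self, orthonormal_dataset):
        ds = orthonormal_dataset
        for j in (1, 3, 8):
            fit = restricted_ls(ds, (j,))
            expected = float(ds.X[:, j - 1] @ ds.y) / float(
                ds.X[:, j - 1] @ ds.X[:, j - 1]
            )
            assert fit.coefficients[j - 1] == pytest.approx(expected, rel=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((8, 3))
        y = rng.standard_normal(8)
        ds = center(Dataset(X=X, y=y))
        fit = restricted_ls(ds, (1, 2, 3))
        beta = np.linalg.solve(ds.X.T @ ds.X, ds.X.T @ ds.y)
        assert np.allclose(fit.coefficients, beta, atol=1e-10)
        resid = ds.y - ds.X @ beta
        assert fit.rss == pytest.approx(float(resid @ resid), rel=1e-8)

    def test_saturated_subset_rejected(self, rng):
        ds = Dataset(X=rng.standard_normal((4, 6)), y=rng.standard_normal(4))
        with pytest.raises(ValueError, match="saturat"):
            restricted_ls(ds, (1, 2, 3, 4))

    def test_rank_deficient_uses_minimum_norm(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 2] = X[:, 0]  # exact duplicate
        ds = center(Dataset(X=X, y=X[:, 0] + 0.1 * rng.standard_normal(20)))
        fit = restricted_ls(ds, (1, 3))
        # duplicated columns: minimum-norm splits the coefficient evenly
        assert fit.coefficients[0] == pytest.approx(fit.coefficients[2], rel=1e-6)

    def test_rss_monotone_in_inclusion(self, small_dataset, rng):
        subsets = [(), (2,), (2, 5), (1, 2, 5), (1, 2, 3, 5, 6)]
        rss = [restricted_ls(small_dataset, s).rss for s in subsets]
        for a, b in zip(rss, rss[1:]):
            assert b <= a + 1e-8


class TestGic:
    def test_unit_rss_per_sample_gives_zero(self):
        ds = Dataset(X=np.ones((2, 1)), y=np.array([1.0, -1.0]), centered=True)
        # rss/n = 1 makes the log term vanish; empty subset kills the penalty
        for crit in (CriterionSpec("AIC"), CriterionSpec("BIC"), CriterionSpec("RAW", lambda_raw=37.0)):
            assert gic(ds, (), crit) == pytest.approx(0.0, abs=1e-12)

    def test_empty_model_value(self):
        y = np.array([2.0, -2.0, 1.0, -1.0])
        ds = Dataset(X=np.zeros((4, 1)) + np.arange(4)[:, None], y=y, centered=True)
        assert gic(ds, (), CriterionSpec("BIC")) == pytest.approx(4 * math.log(10 / 4))

    def test_ebic_penalty_formula(self):
        crit = CriterionSpec("EBIC", gamma=1.0)
        assert crit.penalty(100, 1000) == pytest.approx(
            math.log(100) + 2 * math.log(1000)
        )
        assert CriterionSpec("AIC").penalty(50, 9) == 2.0
        assert CriterionSpec("BIC").penalty(50, 9) == pytest.approx(math.log(50))

    def test_zero_response_rejected(self, rng):
        ds = Dataset(X=rng.standard_normal((5, 2)), y=np.zeros(5), centered=True)
        with pytest.raises(ValueError, match="degenerate"):
            gic(ds, (1,), CriterionSpec("BIC"))

    def test_empty_model_invariant_to_lambda(self, small_dataset):
        vals = {
            gic(small_dataset, (), CriterionSpec("RAW", lambda_raw=lam))
            for lam in (0.5, 2.0, 50.0)
        }
        assert len({round(v, 10) for v in vals}) == 1


class TestPhiSelect:
    def test_empty_candidate(self, small_dataset):
        assert phi_select(small_dataset, (), CriterionSpec("BIC")) == ()

    def test_matches_exhaustive_oracle(self, rng):
        crit = CriterionSpec("BIC")
        for _ in range(5):
            X = rng.standard_normal((30, 6))
            y = X[:, 0] - X[:, 3] + 0.8 * rng.standard_normal(30)
            ds = center(Dataset(X=X, y=y))
            sel = phi_select(ds, range(1, 7), crit)
            assert sel == _brute_force_phi(ds, range(1, 7), crit)

    def test_null_response_mostly_empty(self):
        # EBIC(1) with n=100, p=1000: lambda ~ 18.4 dominates chance RSS
        # reductions, so a size-10 candidate set should almost always yield
        # the empty model under a pure-noise response
        crit = CriterionSpec("EBIC", gamma=1.0)
        rng = np.random.default_rng(7)
        empty = 0
        reps = 100
        for _ in range(reps):
            X = rng.standard_normal((100, 1000))
            y = rng.standard_normal(100)
            ds = Dataset(X=X, y=y, centered=True)  # means ~0 suffice under the null
            if phi_select(ds, range(1, 11), crit) == ():
                empty += 1
        assert empty >= 0.90 * reps

    def test_result_subset_of_candidate(self, rng):
        crit = CriterionSpec("AIC")
        for _ in range(10):
            X = rng.standard_normal((25, 12))
            y = rng.standard_normal(25)
            ds = center(Dataset(X=X, y=y))
            cand = tuple(sorted(rng.choice(12, size=5, replace=False) + 1))
            assert set(phi_select(ds, cand, crit)) <= set(cand)

    def test_oversized_candidate_rejected(self, rng):
        ds = center(Dataset(X=rng.standard_normal((40, 30)), y=rng.standard_normal(40)))
        with pytest.raises(ValueError, match="screen"):
            phi_select(ds, range(1, 26), CriterionSpec("BIC"))

    @given(st.integers(0, 2**32 - 1), st.floats(0.5, 5.0), st.floats(1.5, 10.0))
    def test_monotone_sparsity_in_penalty(self, seed, lam1, factor):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 6))
        y = X[:, 0] + rng.standard_normal(20)
        ds = center(Dataset(X=X, y=y))
        lam2 = lam1 * factor
        s1 = phi_select(ds, range(1, 7), CriterionSpec("RAW", lambda_raw=lam1))
        s2 = phi_select(ds, range(1, 7), CriterionSpec("RAW", lambda_raw=lam2))
        assert len(s2) <= len(s1)

    def test_tie_break_prefers_smaller_then_lex(self, rng):
        # duplicated signal columns create exact ties between {1} and {2};
        # the smaller-then-lex rule must pick {1}
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        y = 2 * x + 0.1 * rng.standard_normal(30)
        ds = center(Dataset(X=X, y=y))
        sel = phi_select(ds, (1, 2, 3), CriterionSpec("BIC"))
        assert sel == (1,)
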