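"""SubBoost, RSubBoost and AdaSubBoost: reference oracles and invariants."""

import itertools
import math

import numpy as np
import pytest

from subspaceboost import (
    BoostConfig,
    CriterionSpec,
    Dataset,
    center,
    l2boost,
    preset_setting,
    rsub_adasub_boost,
    simulate_replicate,
    subboost,
)


def _reference_subboost(ds, s, crit, tau, m_max):
    """Straightforward reimplementation: itertools search + lstsq Phi."""
    n, p = ds.n, ds.p
    lam = crit.penalty(n, p)
    yty = float(ds.y @ ds.y)

    def rss_of(cols, target):
        if not cols:
            return float(target @ target)
        idx = np.array(cols) - 1
        coef, *_ = np.linalg.lstsq(ds.X[:, idx], target, rcond=None)
        r = target - ds.X[:, idx] @ coef
        return float(r @ r)

    def phi(S):
        best = None
        for size in range(len(S) + 1):
            for combo in itertools.combinations(sorted(S), size):
                rss = max(rss_of(combo, ds.y), 1e-12 * yty)
                val = n * math.log(rss / n) + lam * size
                if best is None or val < best[0] - 1e-9:
                    best = (val, combo)
        return best[1]

    beta = np.zeros(p)
    u = ds.y.copy()
    A_hist = []
    for _ in range(m_max):
        best = None
        for combo in itertools.combinations(range(1, p + 1), s):
            rss = rss_of(combo, u)
            if best is None or rss < best[1] - 1e-10:
                best = (combo, rss)
        A = phi(best[0])
        A_hist.append(A)
        if not A:
            break
        idx = np.array(A) - 1
        step, *_ = np.linalg.lstsq(ds.X[:, idx], u, rcond=None)
        beta[idx] += tau * step
        u -= tau * (ds.X[:, idx] @ step)
    return A_hist, beta


class TestSubBoost:
    def test_matches_reference_implementation(self, rng):
        X = rng.standard_normal((30, 8))
        y = 1.2 * X[:, 1] - 1.5 * X[:, 4] + 0.6 * rng.standard_normal(30)
        ds = center(Dataset(X=X, y=y))
        crit = CriterionSpec("BIC")
        cfg = BoostConfig(method="subboost", crit=crit, s=2, tau=0.1, m_max=15)
        fit = subboost(ds, cfg)
        ref_A, ref_beta = _reference_subboost(ds, 2, crit, 0.1, 15)
        assert fit.A_history == ref_A
        assert np.allclose(fit.beta, ref_beta, atol=1e-8)

    def test_null_response_stops_immediately(self):
        reps, stopped = 100, 0
        crit = CriterionSpec("EBIC", gamma=1.0)
        for i in range(reps):
            rng = np.random.default_rng(3000 + i)
            ds = Dataset(
                X=rng.standard_normal((100, 20)), y=rng.standard_normal(100)
            )
            fit = subboost(ds, BoostConfig(method="subboost", crit=crit, s=2, m_max=5))
            if fit.stop_iteration == 1 and fit.stop_reason == "auto_empty":
                assert np.all(fit.beta == 0)
                stopped += 1
        assert stopped >= 0.90 * reps

    def test_negligible_penalty_reduces_to_l2boost(self, rng):
        X = rng.standard_normal((40, 6))
        y = X[:, 0] + 0.5 * X[:, 3] + 0.3 * rng.standard_normal(40)
        ds = center(Dataset(X=X, y=y))
        crit = CriterionSpec("RAW", lambda_raw=1e-10)
        m = 25
        f_sub = subboost(ds, BoostConfig(method="subboost", crit=crit, s=1, tau=0.1, m_max=m))
        f_l2 = l2boost(ds, BoostConfig(method="l2boost", tau=0.1, m_max=m), m)
        assert f_sub.A_history[: len(f_l2.A_history)] == f_l2.A_history[: len(f_sub.A_history)]

    def test_auto_empty_is_reproducible(self, rng):
        # after an auto_empty stop the residuals are unchanged, so one more
        # iteration of a rerun must produce the same empty double-check
        X = rng.standard_normal((60, 10))
        y = 2 * X[:, 0] + rng.standard_normal(60)
        ds = center(Dataset(X=X, y=y))
        cfg = BoostConfig(method="subboost", crit=CriterionSpec("BIC"), s=2, m_max=2000)
        fit = subboost(ds, cfg)
        if fit.stop_reason == "auto_empty":
            again = subboost(ds, BoostConfig(
                method="subboost", crit=CriterionSpec("BIC"), s=2,
                m_max=fit.stop_iteration + 1,
            ))
            assert again.A_history[fit.stop_iteration - 1] == ()


class TestRandomizedVariants:
    @pytest.fixture()
    def ds(self, lowdim_replicate):
        return lowdim_replicate.dataset

    def test_same_seed_bit_identical(self, ds):
        cfg = BoostConfig(method="adasubboost", crit=CriterionSpec("BIC"),
                          s_max=7, q=10, N_stop=10, m_max=200, seed=99)
        f1 = rsub_adasub_boost(ds, cfg)
        f2 = rsub_adasub_boost(ds, cfg)
        assert f1.A_history == f2.A_history
        assert f1.S_history == f2.S_history
        assert f1.V_history == f2.V_history
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.r, f2.r)

    def test_structural_invariants(self, ds):
        cfg = BoostConfig(method="adasubboost", crit=CriterionSpec("BIC"),
                          s_max=7, q=10, N_stop=10, m_max=300, seed=5)
        fit = rsub_adasub_boost(ds, cfg)
        s = fit.s_used
        prev_S = None
        for S, V, A in zip(fit.S_history, fit.V_history, fit.A_history):
            assert set(A) <= set(S) <= set(V)
            assert len(S) == min(s, len(V))
            assert len(A) <= s
            if prev_S is not None:
                assert set(prev_S) <= set(V)
            prev_S = S
        assert np.all(fit.select_counts <= fit.consider_counts)
        assert np.all(fit.r > 0) and np.all(fit.r <= 1)
        never = fit.consider_counts == 0
        if never.any():
            assert np.allclose(fit.r[never], fit.r0)
        # selected = union of realized updates
        union = set().union(*[set(A) for A in fit.A_history])
        assert set(fit.selected) == union
        # residuals recomputable from beta
        resid = center(ds).y - center(ds).X @ fit.beta
        assert float(resid @ resid) == pytest.approx(fit.rss_history[-1], rel=1e-8)

    def test_rss_reduction_closed_form(self, ds):
        # each accepted LS-direction update reduces RSS by tau(2-tau)||X step||^2
        cfg = BoostConfig(method="rsubboost", crit=CriterionSpec("BIC"),
                          s_max=7, q=10, N_stop=10, m_max=100, seed=3)
        fit = rsub_adasub_boost(ds, cfg)
        tau = cfg.tau_resolved
        Xc = center(ds).X
        k = 0
        rss = fit.rss_history
        for t, A in enumerate(fit.A_history, 1):
            drop = rss[t - 1] - rss[t]
            if A:
                _, step = fit.updates[k]
                k += 1
                fitted = Xc[:, np.array(A) - 1] @ step
                assert drop == pytest.approx(
                    tau * (2 - tau) * float(fitted @ fitted), rel=1e-6, abs=1e-9
                )
            else:
                assert drop == pytest.approx(0.0, abs=1e-9)

    def test_rsubboost_constant_probabilities(self, ds):
        cfg = BoostConfig(method="rsubboost", crit=CriterionSpec("BIC"),
                          s=2, q=10, N_stop=10, m_max=150, seed=8)
        fit = rsub_adasub_boost(ds, cfg)
        assert np.allclose(fit.r, (10 - 2) / (ds.p - 2))

    def test_k_zero_equals_rsubboost(self, ds):
        common = dict(crit=CriterionSpec("BIC"), s=2, q=10, N_stop=10,
                      m_max=200, seed=21)
        fa = rsub_adasub_boost(ds, BoostConfig(method="adasubboost", K=0.0, **common))
        fr = rsub_adasub_boost(ds, BoostConfig(method="rsubboost", **common))
        assert fa.A_history == fr.A_history
        assert fa.V_history == fr.V_history
        assert np.array_equal(fa.beta, fr.beta)

    def test_q_equals_p_matches_subboost(self, ds):
        crit = CriterionSpec("BIC")
        f_sub = subboost(ds, BoostConfig(method="subboost", crit=crit, s=2, m_max=150))
        f_rs = rsub_adasub_boost(ds, BoostConfig(
            method="rsubboost", crit=crit, s=2, q=ds.p, N_stop=10, m_max=150, seed=0
        ))
        na = len(f_sub.A_history)
        assert f_rs.A_history[:na] == f_sub.A_history
        assert all(len(v) == ds.p for v in f_rs.V_history)
        assert all(A == () for A in f_rs.A_history[na:])

    def test_invalid_q_rejected(self, ds):
        with pytest.raises(ValueError, match="q must"):
            rsub_adasub_boost(ds, BoostConfig(
                method="rsubboost", crit=CriterionSpec("BIC"), s=5, q=5, m_max=10
            ))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="rsubboost pins"):
            BoostConfig(method="rsubboost", K=3.0)
        with pytest.raises(ValueError, match="tau"):
            BoostConfig(method="l2boost", tau=1.5)

    def test_adasub_fewer_false_positives_than_l2_cv(self):
        # strong-signal low-dimensional recovery: the double-checked subspace
        # updates should admit fewer noise variables than CV-tuned L2Boosting
        cfg_sim = preset_setting(
            "lowdim", beta_spec=("uniform", -2.0, 2.0, 0.5), test_n=0
        )
        fp_ada, fp_l2 = [], []
        from dataclasses import replace
        from subspaceboost import fit_boost, selection_metrics

        for i in range(15):
            rep = simulate_replicate(replace(cfg_sim, seed=7000 + i))
            ada = fit_boost(rep.dataset, BoostConfig(
                method="adasubboost", crit=CriterionSpec("BIC"), s_max=7,
                q=10, N_stop=10, m_max=1000, seed=i,
            ))
            l2 = fit_boost(rep.dataset, BoostConfig(
                method="l2boost", stopping="cv", m_max=1000, seed=i,
            ))
            fp_ada.append(selection_metrics(ada.selected, rep.S_true)[0])
            fp_l2.append(selection_metrics(l2.selected, rep.S_true)[0])
        assert np.mean(fp_ada) < np.mean(fp_l2)
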