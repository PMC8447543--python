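"""Boosting engines: L2Boosting, SubBoost, RSubBoost and AdaSubBoost.

All four algorithms fit the no-intercept linear model on mean-centered data
by stagewise updates ``beta <- beta + tau * step`` against the current
residuals.  They differ in how the update direction is chosen:

* ``l2boost`` — classical component-wise gradient boosting: the single
  column whose one-variable LS fit to the residuals reduces the RSS most.
  The number of iterations is the tuning parameter (10-fold CV, or the
  "earlier stopping" patience rule).
* ``subboost`` — the best subset of fixed size ``s`` over all columns is
  fit to the residuals, then *double-checked*: an l0-type information
  criterion (GIC) is minimized over all subsets of that candidate on the
  original data, and only the surviving variables ``A`` are updated.  An
  empty ``A`` stops the algorithm (no tuning of the iteration count).
* ``rsubboost`` / ``adasubboost`` — scalable randomized variants: each
  iteration searches only a random subspace ``V`` containing the previous
  best subset plus Bernoulli-drawn extra variables.  AdaSubBoost adapts the
  sampling probabilities toward variables that survived double-checking in
  earlier iterations; RSubBoost is the non-adaptive special case (K = 0).
  The algorithms stop after ``N_stop`` consecutive empty updates.

Update directions are least-squares *refits* of the current residuals on
the accepted set ``A`` (not the ``A``-subvector of the size-``s`` search
fit), so every accepted update reduces the training RSS by exactly
``tau * (2 - tau) * ||X step||^2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import PHI_SIZE_LIMIT, _phi_from_gram, phi_select
from .criteria import CriterionSpec
from .dataset import Dataset, center
from .screening import _run_screen, init_data_driven_s
from .subset_search import SearchBudget, _search_gram

__all__ = [
    "BoostConfig",
    "BoostState",
    "BoostFit",
    "l2boost",
    "cv_tune_mstop",
    "l2boost_earlier_stopping",
    "subboost",
    "rsub_adasub_boost",
    "fit_boost",
    "predict",
]

log = logging.getLogger(__name__)

_METHODS = ("l2boost", "subboost", "rsubboost", "adasubboost")


@dataclass(frozen=True)
class BoostConfig:
    """Tuning parameters of one boosting run.

    ``tau`` defaults to 0.1 for ``l2boost`` and 0.01 for the subspace
    methods.  ``s`` is the maximum update size; when ``None`` it is chosen
    data-driven (size of the GIC-best model on the screened initial set,
    capped by ``s_max``).  ``q`` is the expected search size of the
    randomized algorithms, ``K`` the adaptation rate (``None`` resolves to
    ``p/q`` for adasubboost; rsubboost pins ``K = 0``), ``N_stop`` the
    empty-update patience (``None`` resolves to ``ceil(p/s)``).
    """

    method: str = "adasubboost"
    tau: float = None
    m_max: int = 1000
    crit: CriterionSpec = field(default_factory=CriterionSpec)
    s: int = None
    s_max: int = 15
    q: int = 20
    K: float = None
    N_stop: int = None
    seed: int = 0
    cv_folds: int = 10
    patience: int = 10
    stopping: str = "cv"  # l2boost only: {"cv", "earlier", "fixed"}
    m_stop: int = None  # l2boost with stopping="fixed"
    screen: str = "auto"
    standardize: bool = False
    phi_size_limit: int = PHI_SIZE_LIMIT
    budget: SearchBudget = field(
        default_factory=lambda: SearchBudget(strategy="branch_and_bound")
    )

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.tau is not None and not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        if self.m_max < 1:
            raise ValueError("m_max must be at least 1")
        if self.K is not None and self.K < 0:
            raise ValueError("K must be nonnegative")
        if self.method == "rsubboost" and self.K not in (None, 0, 0.0):
            raise ValueError("K is an adasubboost parameter; rsubboost pins K = 0")
        if self.stopping not in ("cv", "earlier", "fixed"):
            raise ValueError("stopping must be 'cv', 'earlier' or 'fixed'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")

    @property
    def tau_resolved(self) -> float:
        if self.tau is not None:
            return self.tau
        return 0.1 if self.method == "l2boost" else 0.01


@dataclass
class BoostState:
    """Mutable per-iteration state of a boosting run."""

    t: int
    beta: np.ndarray
    residuals: np.ndarray
    S_history: list
    V_history: list
    A_history: list
    select_counts: np.ndarray
    consider_counts: np.ndarray
    r: np.ndarray
    empty_streak: int = 0


@dataclass
class BoostFit:
    """Result of a boosting run.

    ``selected`` is the union of all realized updates ``A^[t]`` (1-based).
    ``updates`` records, per realized update, the accepted set and the raw
    (pre-shrinkage) LS direction on it; ``rss_history[t]`` is the training
    RSS after iteration ``t`` (index 0 = initial ``||y||^2``).
    """

    config: BoostConfig
    beta: np.ndarray
    selected: tuple
    stop_iteration: int
    stop_reason: str
    A_history: list
    S_history: list = None
    V_history: list = None
    select_counts: np.ndarray = None
    consider_counts: np.ndarray = None
    r: np.ndarray = None
    r0: float = None
    updates: list = None
    rss_history: list = None
    s_used: int = None
    q_used: int = None
    K_used: float = None
    N_stop_used: int = None
    column_names: list = None
    x_means: np.ndarray = None
    y_mean: float = 0.0
    cv_curve: np.ndarray = None
    m_cv: int = None

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_means @ self.beta)

    @property
    def training_mse_history(self) -> np.ndarray:
        """Training mean squared error after each iteration (index 0 = null
        model); requires the fit to carry its training sample size."""
        return np.asarray(self.rss_history, dtype=float) / self._n

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        coef = {
            name: float(b)
            for name, b in zip(self.column_names, self.beta)
            if b != 0.0
        }
        d = {
            "method": self.config.method,
            "stop_iteration": int(self.stop_iteration),
            "stop_reason": self.stop_reason,
            "selected": [int(j) for j in self.selected],
            "selected_names": [self.column_names[j - 1] for j in self.selected],
            "coefficients": coef,
            "intercept": self.intercept,
            "s_used": None if self.s_used is None else int(self.s_used),
            "q_used": None if self.q_used is None else int(self.q_used),
            "K_used": None if self.K_used is None else float(self.K_used),
            "N_stop_used": (
                None if self.N_stop_used is None else int(self.N_stop_used)
            ),
            "seed": int(self.config.seed),
            "A_history": [[int(j) for j in A] for A in self.A_history],
        }
        return d

    def path_frame(self):
        """Long-format coefficient path (iteration, variable, value)."""
        import pandas as pd

        tau = self.config.tau_resolved
        beta = np.zeros_like(self.beta)
        rows = []
        k = 0
        for t, A in enumerate(self.A_history, 1):
            if not A:
                continue
            _, step = self.updates[k]
            k += 1
            idx = np.array(A) - 1
            beta[idx] += tau * np.asarray(step)
            for j in A:
                rows.append((t, self.column_names[j - 1], float(beta[j - 1])))
        return pd.DataFrame(rows, columns=["iteration", "variable", "value"])


def predict(fit: BoostFit, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for covariates on the original (uncentered) scale."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p = len(fit.beta)
    if X_new.shape[1] != p:
        raise ValueError(f"X_new has {X_new.shape[1]} columns, expected {p}")
    return fit.y_mean + (X_new - fit.x_means) @ fit.beta


def _ls_step(X: np.ndarray, u: np.ndarray, idx0: np.ndarray) -> np.ndarray:
    """Least-squares direction of the residuals on the given 0-based columns."""
    coef, *_ = np.linalg.lstsq(X[:, idx0], u, rcond=None)
    return coef


def _make_phi(ds: Dataset, crit: CriterionSpec, phi_size_limit: int):
    """Memoized double-checking procedure on the (centered) observed data."""
    lam = crit.penalty(ds.n, ds.p)
    yTy = float(ds.y @ ds.y)
    X = ds.X
    cache: dict = {}

    def phi(S: tuple) -> tuple:
        A = cache.get(S)
        if A is None:
            if len(S) > phi_size_limit:
                raise ValueError(
                    f"double-checking set of size {len(S)} exceeds the "
                    f"enumeration limit ({phi_size_limit})"
                )
            cand = np.array(S, dtype=np.int64)
            cols = cand - 1
            Xs = X[:, cols]
            G = Xs.T @ Xs
            c = Xs.T @ ds.y
            A = _phi_from_gram(G, c, yTy, cand, ds.n, ds.p, lam)
            cache[S] = A
        return A

    return phi


# --------------------------------------------------------------------------
# component-wise L2Boosting


def _l2_select(corr: np.ndarray, col_sq: np.ndarray) -> int:
    red = np.zeros_like(corr)
    ok = col_sq > 0
    red[ok] = corr[ok] ** 2 / col_sq[ok]
    return int(np.argmax(red))  # argmax keeps the smallest index on ties


def l2boost(data: Dataset, config: BoostConfig, m_stop: int = None) -> BoostFit:
    """Component-wise L2Boosting for a fixed number of iterations.

    Each iteration selects the column maximizing the RSS reduction of the
    one-variable LS fit to the current residuals (ties broken by smallest
    index) and adds ``tau`` times that fit.  Columns are not variance-scaled
    unless ``config.standardize`` is set.
    """
    ds = center(data)
    m_stop = config.m_max if m_stop is None else int(m_stop)
    if m_stop > config.m_max:
        raise ValueError("m_stop exceeds m_max")
    tau = config.tau_resolved
    X = ds.X
    sd = None
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    col_sq = (X**2).sum(axis=0)
    u = ds.y.copy()
    beta = np.zeros(ds.p)
    A_hist, updates, rss_hist = [], [], [float(u @ u)]
    for t in range(1, m_stop + 1):
        corr = X.T @ u
        j = _l2_select(corr, col_sq)
        step = corr[j] / col_sq[j] if col_sq[j] > 0 else 0.0
        beta[j] += tau * step
        u -= tau * step * X[:, j]
        A_hist.append((j + 1,))
        updates.append(((j + 1,), np.array([step])))
        rss_hist.append(float(u @ u))
        if t % 100 == 0:
            log.info("l2boost t=%d rss=%.6g", t, rss_hist[-1])
    if sd is not None:
        beta = beta / sd
    selected = tuple(sorted({A[0] for A in A_hist if A}))
    fit = BoostFit(
        config=config,
        beta=beta,
        selected=selected,
        stop_iteration=m_stop,
        stop_reason="m_max",
        A_history=A_hist,
        updates=updates,
        rss_history=rss_hist,
        column_names=ds.column_names,
        x_means=ds.x_means,
        y_mean=ds.y_mean,
    )
    fit._n = ds.n
    return fit


def _cv_folds(n: int, k: int, seed: int):
    """Contiguous blocks of a seeded permutation."""
    if n < k:
        raise ValueError(f"n = {n} is smaller than cv_folds = {k}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, k)


def _l2_test_sse_path(Xtr, ytr, Xte, yte, tau, m_max, standardize):
    """Held-out SSE after m = 0..m_max iterations of l2boost on the fold."""
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    Xc = Xtr - xm
    if standardize:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
        Xec = (Xte - xm) / sd
    else:
        Xec = Xte - xm
    yc = ytr - ym
    col_sq = (Xc**2).sum(axis=0)
    u = yc.copy()
    ete = yte - ym  # held-out residuals of the current model
    sse = np.empty(m_max + 1)
    sse[0] = float(ete @ ete)
    for t in range(1, m_max + 1):
        corr = Xc.T @ u
        j = _l2_select(corr, col_sq)
        step = corr[j] / col_sq[j] if col_sq[j] > 0 else 0.0
        u -= tau * step * Xc[:, j]
        ete -= tau * step * Xec[:, j]
        sse[t] = float(ete @ ete)
    return sse


def cv_curve(data: Dataset, config: BoostConfig) -> np.ndarray:
    """Mean 10-fold CV squared error after m = 0..m_max iterations."""
    folds = _cv_folds(data.n, config.cv_folds, config.seed)
    tau = config.tau_resolved
    total = np.zeros(config.m_max + 1)
    for fold in folds:
        mask = np.ones(data.n, dtype=bool)
        mask[fold] = False
        total += _l2_test_sse_path(
            data.X[mask],
            data.y[mask],
            data.X[fold],
            data.y[fold],
            tau,
            config.m_max,
            config.standardize,
        )
    return total / data.n


def cv_tune_mstop(data: Dataset, config: BoostConfig) -> int:
    """CV-optimal stopping iteration (first argmin of the mean CV curve)."""
    return int(np.argmin(cv_curve(data, config)))


def _patience_scan(curve: np.ndarray, patience: int):
    """First iteration at which the curve has not improved for ``patience``
    consecutive iterations; returns (iteration, triggered)."""
    best = curve[0]
    streak = 0
    for m in range(1, len(curve)):
        if curve[m] < best:
            best = curve[m]
            streak = 0
        else:
            streak += 1
            if streak >= patience:
                return m, True
    return len(curve) - 1, False


def l2boost_earlier_stopping(data: Dataset, config: BoostConfig) -> BoostFit:
    """L2Boosting stopped when the CV error stalls for ``patience`` rounds.

    Equivalent to scanning the full CV curve with the same rule; the final
    fit on the full data uses the stopping iteration of that scan.
    """
    curve = cv_curve(data, config)
    m_used, triggered = _patience_scan(curve, config.patience)
    fit = l2boost(data, config, m_used)
    fit.stop_reason = "patience" if triggered else "m_max"
    fit.cv_curve = curve
    return fit


# --------------------------------------------------------------------------
# SubBoost (non-randomized exact subspace boosting)


def _resolve_s_subboost(ds: Dataset, config: BoostConfig) -> int:
    if config.s is not None:
        return int(config.s)
    if ds.p > config.phi_size_limit:
        raise ValueError(
            "data-driven s for subboost requires p <= phi_size_limit; "
            "prespecify s or use rsubboost/adasubboost"
        )
    S0 = phi_select(ds, range(1, ds.p + 1), config.crit, config.phi_size_limit)
    return max(len(S0), 1)


def subboost(data: Dataset, config: BoostConfig) -> BoostFit:
    """Subspace boosting with exhaustive search over all ``p`` variables.

    Stops at the first iteration whose double-checked update is empty
    (``auto_empty``), or at ``m_max``.
    """
    ds = center(data)
    tau = config.tau_resolved
    s = _resolve_s_subboost(ds, config)
    if s >= ds.n:
        raise ValueError("update size s must be smaller than n")
    if math.comb(ds.p, s) > config.budget.exhaustive_limit:
        raise ValueError(
            f"C({ds.p}, {s}) exceeds the search budget; "
            "use rsubboost/adasubboost"
        )
    phi = _make_phi(ds, config.crit, config.phi_size_limit)
    X = ds.X
    cand = np.arange(1, ds.p + 1, dtype=np.int64)
    G = X.T @ X
    u = ds.y.copy()
    beta = np.zeros(ds.p)
    S_hist, A_hist, updates = [], [], []
    rss_hist = [float(u @ u)]
    stop_reason = "m_max"
    t = 0
    for t in range(1, config.m_max + 1):
        c = X.T @ u
        uTu = float(u @ u)
        S, _ = _search_gram(G, c, uTu, cand, s, config.budget)
        A = phi(S)
        S_hist.append(S)
        A_hist.append(A)
        if not A:
            stop_reason = "auto_empty"
            rss_hist.append(uTu)
            break
        idx0 = np.array(A) - 1
        step = _ls_step(X, u, idx0)
        beta[idx0] += tau * step
        u -= tau * (X[:, idx0] @ step)
        updates.append((A, step))
        rss_hist.append(float(u @ u))
        if t % 100 == 0:
            log.info("subboost t=%d |A|=%d rss=%.6g", t, len(A), rss_hist[-1])
    selected = tuple(sorted(set().union(*[set(A) for A in A_hist]) if A_hist else ()))
    fit = BoostFit(
        config=config,
        beta=beta,
        selected=selected,
        stop_iteration=t,
        stop_reason=stop_reason,
        A_history=A_hist,
        S_history=S_hist,
        updates=updates,
        rss_history=rss_hist,
        s_used=s,
        column_names=ds.column_names,
        x_means=ds.x_means,
        y_mean=ds.y_mean,
    )
    fit._n = ds.n
    return fit


# --------------------------------------------------------------------------
# RSubBoost / AdaSubBoost (randomized subspace boosting)


def rsub_adasub_boost(data: Dataset, config: BoostConfig) -> BoostFit:
    """Randomized subspace boosting with optional adaptive sampling.

    Per iteration: Bernoulli draws add variables to the subspace ``V``
    around the previous best subset, an exact size-``s`` search on the
    residuals picks ``S``, double-checking on the original data picks
    ``A ⊆ S``, and (for K > 0) the sampling probabilities are updated to
    ``r_j = (q - s + K * #selected_j) / (p - s + K * #considered_j)``.
    Stops after ``N_stop`` consecutive empty updates (at t >= N_stop) or at
    ``m_max``.
    """
    if config.method not in ("rsubboost", "adasubboost"):
        raise ValueError("config.method must be rsubboost or adasubboost")
    ds = center(data)
    tau = config.tau_resolved
    p, n = ds.p, ds.n
    if config.s is not None:
        s = int(config.s)
        screened = _run_screen(ds, min(s, p), config.screen)
        S0 = tuple(sorted(screened))
    else:
        s, S0 = init_data_driven_s(ds, config.crit, config.s_max, config.screen)
    if s >= n:
        raise ValueError("update size s must be smaller than n")
    q = int(config.q)
    if not (s < q <= p):
        raise ValueError(f"q must satisfy s < q <= p (s={s}, q={q}, p={p})")
    K = 0.0 if config.method == "rsubboost" else (
        float(config.K) if config.K is not None else p / q
    )
    N_stop = int(config.N_stop) if config.N_stop else math.ceil(p / s)
    r0 = (q - s) / (p - s) if p > s else 1.0
    rng = np.random.default_rng(config.seed)

    X = ds.X
    state = BoostState(
        t=0,
        beta=np.zeros(p),
        residuals=ds.y.copy(),
        S_history=[],
        V_history=[],
        A_history=[],
        select_counts=np.zeros(p, dtype=np.int64),
        consider_counts=np.zeros(p, dtype=np.int64),
        r=np.full(p, r0),
    )
    phi = _make_phi(ds, config.crit, config.phi_size_limit)
    updates = []
    rss_hist = [float(state.residuals @ state.residuals)]
    prev_S = np.array(S0, dtype=np.int64) - 1  # 0-based
    stop_reason = "m_max"
    qs = float(q - s)
    ps = float(p - s)
    for t in range(1, config.m_max + 1):
        state.t = t
        u = state.residuals
        # (a1)+(a2): Bernoulli draws for j outside the previous best subset,
        # ascending index order from the single seeded stream
        in_prev = np.zeros(p, dtype=bool)
        in_prev[prev_S] = True
        out_idx = np.nonzero(~in_prev)[0]
        drawn = out_idx[rng.random(out_idx.size) < state.r[out_idx]]
        V0 = np.sort(np.concatenate([prev_S, drawn]))
        # (a3): exact best subset of size s within V against the residuals
        Xv = X[:, V0]
        G = Xv.T @ Xv
        c = Xv.T @ u
        uTu = float(u @ u)
        s_eff = min(s, V0.size)
        S, _ = _search_gram(G, c, uTu, V0 + 1, s_eff, config.budget)
        # (a4): double-checking on the original data
        A = phi(S)
        V_t = tuple(int(j) + 1 for j in V0)
        state.S_history.append(S)
        state.V_history.append(V_t)
        state.A_history.append(A)
        S_idx0 = np.array(S, dtype=np.int64) - 1
        state.select_counts[S_idx0] += 1
        state.consider_counts[V0] += 1
        if A:
            idx0 = np.array(A) - 1
            step = _ls_step(X, u, idx0)
            state.beta[idx0] += tau * step
            u -= tau * (X[:, idx0] @ step)
            updates.append((A, step))
            state.empty_streak = 0
        else:
            state.empty_streak += 1
        rss_hist.append(float(u @ u))
        # (d): adapt sampling probabilities (all iterations count)
        if K > 0.0:
            state.r = (qs + K * state.select_counts) / (
                ps + K * state.consider_counts
            )
        if t % 100 == 0:
            log.info(
                "%s t=%d |V|=%d |A|=%d rss=%.6g empty_streak=%d",
                config.method, t, len(V_t), len(A), rss_hist[-1],
                state.empty_streak,
            )
        if state.empty_streak >= N_stop and t >= N_stop:
            stop_reason = "auto_empty"
            break
        prev_S = S_idx0
    selected = tuple(
        sorted(set().union(*[set(A) for A in state.A_history]))
        if state.A_history
        else ()
    )
    fit = BoostFit(
        config=config,
        beta=state.beta,
        selected=selected,
        stop_iteration=state.t,
        stop_reason=stop_reason,
        A_history=state.A_history,
        S_history=state.S_history,
        V_history=state.V_history,
        select_counts=state.select_counts,
        consider_counts=state.consider_counts,
        r=state.r,
        r0=r0,
        updates=updates,
        rss_history=rss_hist,
        s_used=s,
        q_used=q,
        K_used=K,
        N_stop_used=N_stop,
        column_names=ds.column_names,
        x_means=ds.x_means,
        y_mean=ds.y_mean,
    )
    fit._n = ds.n
    return fit


def fit_boost(data: Dataset, config: BoostConfig) -> BoostFit:
    """Dispatch a configured boosting run (the one entry point used by the
    evaluation harness and the CLI)."""
    if config.method == "l2boost":
        if config.stopping == "cv":
            m_cv = cv_tune_mstop(data, config)
            fit = l2boost(data, config, m_cv)
            fit.stop_reason = "cv_optimal"
            fit.m_cv = m_cv
            return fit
        if config.stopping == "earlier":
            return l2boost_earlier_stopping(data, config)
        return l2boost(data, config, config.m_stop)
    if config.method == "subboost":
        return subboost(data, config)
    return rsub_adasub_boost(data, config)
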