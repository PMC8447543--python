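"""Exact best-subset-of-size-s search against a residual target.

Used by the subspace boosting algorithms to find, inside a candidate
subspace ``V``, the size-``s`` subset whose least-squares fit to the current
residuals has the smallest RSS.  Exactness is a hard contract: the search
either enumerates all ``C(|V|, s)`` subsets or runs a branch-and-bound whose
pruning bound is the RSS of the fit on the partial subset joined with all
remaining candidates — a superset of every completion, hence a valid lower
bound, so the optimum is never discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np

from ._kernels import best_subset_kernel
from .core import SubsetFit

__all__ = ["SearchBudget", "best_subset_of_size", "best_full_search"]

log = logging.getLogger(__name__)

_STRATEGIES = ("exhaustive", "branch_and_bound", "auto")


@dataclass(frozen=True)
class SearchBudget:
    """Search strategy and enumeration budget.

    ``auto`` enumerates exhaustively when ``C(|V|, s)`` does not exceed
    ``exhaustive_limit`` and otherwise switches to branch-and-bound.
    """

    exhaustive_limit: int = 2_000_000
    strategy: str = "auto"

    def __post_init__(self):
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if self.exhaustive_limit < 1:
            raise ValueError("exhaustive_limit must be positive")

    def use_bound(self, n_candidates: int, s: int) -> bool:
        if self.strategy == "exhaustive":
            return False
        if self.strategy == "branch_and_bound":
            return True
        return comb(n_candidates, s) > self.exhaustive_limit


def _search_gram(G, c, uTu, cand, s, budget):
    """Run the kernel on precomputed Gram pieces; returns (tuple, rss).

    For the branch-and-bound strategy the candidates are internally ordered
    by decreasing marginal RSS reduction, which makes the incumbent strong
    early and the superset bound effective; the kernel resolves ties in the
    original index space, so the ordering never changes the answer.
    """
    v = len(cand)
    use_bound = budget.use_bound(v, s)
    G = np.ascontiguousarray(G, dtype=float)
    c = np.ascontiguousarray(c, dtype=float)
    if use_bound and v > s:
        diag = np.diag(G)
        marg = np.divide(
            c**2, diag, out=np.zeros_like(c), where=diag > 0
        )
        order = np.argsort(-marg, kind="stable").astype(np.int64)
        Gp = np.ascontiguousarray(G[np.ix_(order, order)])
        cp = np.ascontiguousarray(c[order])
        pos, rss, _ = best_subset_kernel(Gp, cp, uTu, s, True, order)
    else:
        pos, rss, _ = best_subset_kernel(
            G, c, uTu, s, use_bound, np.arange(v, dtype=np.int64)
        )
    subset = tuple(int(cand[i]) for i in sorted(pos))
    return subset, float(rss)


def best_subset_of_size(
    data_X: np.ndarray,
    target: np.ndarray,
    candidates,
    s: int,
    budget: SearchBudget = None,
) -> SubsetFit:
    """Size-``s`` subset of ``candidates`` best fitting ``target``.

    ``candidates`` holds 1-based column indices of ``data_X``.  When the
    candidate set has fewer than ``s`` members the search proceeds with the
    reduced size ``|V|`` (logged), which arises early in the randomized
    algorithms when few variables are drawn.  Ties are broken
    lexicographically.  Coefficients are the LS fit of the target on the
    winning subset (dense length-p, zero off-subset).
    """
    X = np.asarray(data_X, dtype=float)
    u = np.asarray(target, dtype=float).ravel()
    n, p = X.shape
    budget = budget or SearchBudget()
    cand = np.array(sorted({int(j) for j in candidates}), dtype=np.int64)
    if len(cand) == 0:
        raise ValueError("empty candidate set")
    if cand[0] < 1 or cand[-1] > p:
        raise ValueError(f"candidate indices must lie in 1..{p}")
    if s < 1:
        raise ValueError("s must be at least 1")
    if s >= n:
        raise ValueError(f"s = {s} must be smaller than n = {n}")
    if s > len(cand):
        log.debug("candidate set smaller than s: shrinking %d -> %d", s, len(cand))
        s = len(cand)
    cols = cand - 1
    Xv = X[:, cols]
    G = Xv.T @ Xv
    c = Xv.T @ u
    uTu = float(u @ u)
    subset, _ = _search_gram(G, c, uTu, cand, s, budget)
    # refit on the winner for coefficients and an RSS consistent with lstsq
    beta = np.zeros(p)
    sel = np.array(subset) - 1
    coef, *_ = np.linalg.lstsq(X[:, sel], u, rcond=None)
    beta[sel] = coef
    resid = u - X[:, sel] @ coef
    return SubsetFit(subset=subset, coefficients=beta, rss=float(resid @ resid))


def best_full_search(
    data_X: np.ndarray,
    target: np.ndarray,
    s: int,
    budget: SearchBudget = None,
) -> SubsetFit:
    """Best size-``s`` subset over all ``p`` columns (non-randomized search).

    Refuses problems whose ``C(p, s)`` exceeds the enumeration budget — the
    motivation for the randomized subspace variants.
    """
    budget = budget or SearchBudget()
    p = np.asarray(data_X).shape[1]
    if comb(p, s) > budget.exhaustive_limit:
        raise ValueError(
            f"C({p}, {s}) = {comb(p, s)} exceeds the search budget "
            f"({budget.exhaustive_limit}); use the randomized subspace "
            "algorithms (rsubboost/adasubboost) for problems of this size"
        )
    return best_subset_of_size(data_X, target, range(1, p + 1), s, budget)
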