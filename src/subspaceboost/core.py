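"""Restricted least squares and the GIC-based selection procedure Phi.

Indices of covariates are 1-based in all public inputs and outputs,
matching the ``x1 ... xp`` column naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import all_subsets_rss_kernel
from .criteria import CriterionSpec
from .dataset import Dataset

__all__ = ["SubsetFit", "restricted_ls", "gic", "phi_select", "PHI_SIZE_LIMIT"]

#: largest candidate set Phi will enumerate (2**PHI_SIZE_LIMIT subsets)
PHI_SIZE_LIMIT = 20

#: relative RSS floor applied before the log in the GIC
GIC_RSS_EPS = 1e-12


@dataclass(frozen=True)
class SubsetFit:
    """Least-squares fit restricted to a variable subset.

    ``subset`` is a sorted tuple of 1-based column indices; ``coefficients``
    is a dense length-p vector that is zero off the subset; ``rss`` is the
    residual sum of squares of the fit.
    """

    subset: tuple
    coefficients: np.ndarray
    rss: float


def _normalize_subset(subset, p: int) -> tuple:
    idx = tuple(sorted({int(j) for j in subset}))
    if idx and (idx[0] < 1 or idx[-1] > p):
        raise ValueError(f"subset indices must lie in 1..{p}, got {idx}")
    return idx


def restricted_ls(data: Dataset, subset) -> SubsetFit:
    """Least-squares fit of ``y`` on the columns in ``subset`` (1-based).

    The empty subset yields the zero fit with ``rss = ||y||^2``.  Rank
    deficiency is resolved by the minimum-norm solution.  Subsets of size
    ``>= n`` are rejected (saturated model; the GIC would be undefined).
    """
    idx = _normalize_subset(subset, data.p)
    if len(idx) >= data.n:
        raise ValueError(
            f"subset of size {len(idx)} saturates the model (n = {data.n})"
        )
    beta = np.zeros(data.p)
    if not idx:
        return SubsetFit(subset=idx, coefficients=beta, rss=float(data.y @ data.y))
    cols = np.array(idx) - 1
    coef, *_ = np.linalg.lstsq(data.X[:, cols], data.y, rcond=None)
    beta[cols] = coef
    resid = data.y - data.X[:, cols] @ coef
    return SubsetFit(subset=idx, coefficients=beta, rss=float(resid @ resid))


def gic(data: Dataset, subset, crit: CriterionSpec) -> float:
    """Generalized information criterion ``n log(RSS/n) + lambda |S|``.

    The RSS is floored at ``GIC_RSS_EPS * ||y||^2`` before taking the log so
    that saturated fits stay finite.  A zero response is degenerate.
    """
    yty = float(data.y @ data.y)
    if yty == 0.0:
        raise ValueError("degenerate response: ||y|| = 0")
    fit = restricted_ls(data, subset)
    n = data.n
    rss = max(fit.rss, GIC_RSS_EPS * yty)
    lam = crit.penalty(n, data.p)
    return n * np.log(rss / n) + lam * len(fit.subset)


def _phi_from_gram(G, c, uTu, cand, n, p, lam):
    """Shared Phi enumeration given the candidate Gram pieces.

    ``cand`` is the sorted array of 1-based candidate indices.  Returns the
    selected subset as a sorted tuple of 1-based indices.
    """
    m = len(cand)
    if m == 0:
        return ()
    if uTu == 0.0:
        raise ValueError("degenerate response: ||y|| = 0")
    rss = all_subsets_rss_kernel(G, c, uTu)
    masks = np.arange(1 << m, dtype=np.uint64)
    sizes = np.bitwise_count(masks).astype(np.int64)
    floored = np.maximum(rss, GIC_RSS_EPS * uTu)
    values = n * np.log(floored / n) + lam * sizes
    best = values.min()
    tol = 1e-9 * max(1.0, abs(best))
    tie = np.nonzero(values <= best + tol)[0]
    # ties: smaller cardinality first, then lexicographically smallest tuple
    def key(mask):
        members = tuple(int(cand[i]) for i in range(m) if (mask >> i) & 1)
        return (len(members), members)

    winner = min((int(t) for t in tie), key=key)
    return tuple(int(cand[i]) for i in range(m) if (winner >> i) & 1)


def phi_select(
    data: Dataset,
    candidate,
    crit: CriterionSpec,
    phi_size_limit: int = PHI_SIZE_LIMIT,
) -> tuple:
    """Best subset of ``candidate`` by exhaustive GIC minimization.

    Computed on the observed data ``(X, y)`` — in the boosting algorithms
    this double-checking step always sees the original response, never the
    residuals.  Returns a sorted tuple of 1-based indices; may be empty.
    """
    cand = np.array(_normalize_subset(candidate, data.p), dtype=np.int64)
    if len(cand) > phi_size_limit:
        raise ValueError(
            f"candidate set of size {len(cand)} exceeds the enumeration limit "
            f"({phi_size_limit}); screen the candidates first"
        )
    if len(cand) >= data.n:
        raise ValueError("candidate set saturates the model; screen first")
    cols = cand - 1
    Xc = data.X[:, cols]
    G = Xc.T @ Xc
    c = Xc.T @ data.y
    uTu = float(data.y @ data.y)
    lam = crit.penalty(data.n, data.p)
    return _phi_from_gram(G, c, uTu, cand, data.n, data.p, lam)
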