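"""Low-level exact subset-search kernels.

Both kernels work on the Gram matrix ``G = X_V' X_V`` of the candidate
columns, the inner products ``c = X_V' u`` with the target vector and the
squared norm ``uTu = u'u``.  For a subset ``S`` of candidate positions the
residual sum of squares of the least-squares fit of ``u`` on the columns in
``S`` is ``uTu - z'z`` where ``z`` solves the triangular system given by the
Cholesky factor of ``G[S, S]``.  The kernels enumerate subsets depth-first in
lexicographic order, extending the Cholesky factor by one row per added
column, so each visited subset costs O(|S|^2) flops.

Numerically singular extensions (a column lying in the span of the columns
already in the subset, up to a relative tolerance) contribute nothing to the
fit; they are absorbed by giving the factor a huge diagonal entry, which
reproduces the minimum-norm convention that adding a collinear column leaves
the RSS unchanged.
"""

import numpy as np
from numba import njit

# relative tolerance below which a Cholesky pivot is treated as zero
_SINGULAR_RTOL = 1e-12
# subtrees with fewer leaves than this are enumerated rather than bounded
_BOUND_MIN_LEAVES = 256.0


@njit(cache=True)
def _comb_table(v, s):
    """Binomial coefficients C(i, j) for i <= v, j <= s, as floats."""
    tab = np.zeros((v + 1, s + 1))
    for i in range(v + 1):
        tab[i, 0] = 1.0
        for j in range(1, min(i, s) + 1):
            tab[i, j] = tab[i - 1, j - 1] + tab[i - 1, j]
    return tab


@njit(cache=True)
def _extend_row(G, c, L, z, chosen, r, j):
    """Append column ``j`` as row ``r`` of the factor ``L`` / solution ``z``.

    ``chosen[:r]`` holds the candidate indices of rows ``0..r-1``.  Returns
    the gain ``z[r]**2`` contributed by the new column.
    """
    for i in range(r):
        acc = G[j, chosen[i]]
        for m in range(i):
            acc -= L[r, m] * L[i, m]
        L[r, i] = acc / L[i, i]
    d = G[j, j]
    for m in range(r):
        d -= L[r, m] * L[r, m]
    if d > _SINGULAR_RTOL * G[j, j] and d > 0.0:
        L[r, r] = np.sqrt(d)
    else:
        L[r, r] = 1e30  # collinear: effectively drops the column
    acc = c[j]
    for m in range(r):
        acc -= L[r, m] * z[m]
    z[r] = acc / L[r, r]
    return z[r] * z[r]


@njit(cache=True)
def _greedy_rss(G, c, uTu, s):
    """RSS of the greedy forward size-s solution; used only to initialize
    the branch-and-bound pruning cut, never as the returned answer."""
    v = G.shape[0]
    L = np.zeros((s, s))
    z = np.zeros(s)
    chosen = np.empty(s, np.int64)
    used = np.zeros(v, np.bool_)
    total = 0.0
    Lrow = np.zeros((s, s))
    zrow = np.zeros(s)
    for k in range(s):
        best_gain = -1.0
        best_j = -1
        for j in range(v):
            if used[j]:
                continue
            gain = _extend_row(G, c, L, z, chosen, k, j)
            if gain > best_gain:
                best_gain = gain
                best_j = j
                for m in range(k + 1):
                    Lrow[k, m] = L[k, m]
                zrow[k] = z[k]
        for m in range(k + 1):
            L[k, m] = Lrow[k, m]
        z[k] = zrow[k]
        chosen[k] = best_j
        used[best_j] = True
        total += best_gain
    return uTu - total


@njit(cache=True)
def _lex_smaller(a, b, s):
    """True if sorted copy of a precedes sorted copy of b (length s)."""
    sa = np.sort(a[:s])
    sb = np.sort(b[:s])
    for i in range(s):
        if sa[i] != sb[i]:
            return sa[i] < sb[i]
    return False


@njit(cache=True)
def best_subset_kernel(G, c, uTu, s, use_bound, orig):
    """Exact best subset of size ``s`` of the ``v`` candidate columns.

    Minimizes RSS of the LS fit of the target on the subset columns.
    ``orig`` maps kernel positions to the caller's original candidate
    positions (the caller may pass a permuted Gram, e.g. ordered by
    marginal gain, to sharpen pruning); ties within a relative tolerance
    are resolved toward the lexicographically smallest *original* index
    tuple, so the result does not depend on the permutation.  With
    ``use_bound`` the subtree below a partial subset ``I`` with remaining
    suffix ``R`` is pruned when ``RSS(I ∪ R)``, a lower bound for every
    completion, cannot beat the incumbent (leaps-and-bounds style); a
    greedy forward solution initializes the pruning cut.

    Returns ``(best_positions, best_rss, nodes_visited)`` with positions in
    the caller's original candidate space.
    """
    v = G.shape[0]
    tol = 1e-9 * (uTu if uTu > 0.0 else 1.0)

    best_orig = np.empty(s, np.int64)
    if s == v:
        # single subset; evaluate directly
        L = np.zeros((v, v))
        z = np.zeros(v)
        ch = np.arange(v)
        gain = 0.0
        for r in range(v):
            gain += _extend_row(G, c, L, z, ch, r, r)
        for i in range(s):
            best_orig[i] = orig[i]
        return best_orig, max(uTu - gain, 0.0), 1

    best_rss = np.inf
    have_best = False
    # pruning cut from the greedy solution, inflated by tol so subsets tying
    # the optimum are still visited and the tie rule below can see them
    prune_cut = _greedy_rss(G, c, uTu, s) + tol if use_bound else np.inf
    chosen = np.empty(s, np.int64)
    pos = np.empty(s, np.int64)
    L = np.zeros((s, s))
    z = np.zeros(s)
    zsq = np.zeros(s + 1)
    cand_orig = np.empty(s, np.int64)
    # scratch for the bound computation (factor over chosen + suffix)
    Lb = np.zeros((v, v))
    zb = np.zeros(v)
    comb = _comb_table(v, s) if use_bound else np.zeros((1, 1))

    nodes = 0
    k = 0
    pos[0] = -1
    while k >= 0:
        pos[k] += 1
        if pos[k] > v - (s - k):
            k -= 1
            continue
        j = pos[k]
        gain = _extend_row(G, c, L, z, chosen, k, j)
        chosen[k] = j
        zsq[k + 1] = zsq[k] + gain
        nodes += 1
        if k == s - 1:
            rss = uTu - zsq[s]
            if rss < best_rss - tol:
                best_rss = rss
                have_best = True
                for i in range(s):
                    best_orig[i] = orig[chosen[i]]
            elif have_best and rss <= best_rss + tol:
                # near-tie: keep the lexicographically smallest original tuple
                for i in range(s):
                    cand_orig[i] = orig[chosen[i]]
                if _lex_smaller(cand_orig, best_orig, s):
                    if rss < best_rss:
                        best_rss = rss
                    for i in range(s):
                        best_orig[i] = cand_orig[i]
            continue
        # decide whether to descend into completions of chosen[:k+1]
        descend = True
        if use_bound:
            rem = v - (j + 1)
            m_tot = k + 1 + rem
            # bound costs ~m_tot^3/3 flops; the subtree it may remove costs
            # ~leaves * (k+2)^2 — only bound when the subtree is the bigger
            leaves = comb[rem, s - k - 1]
            if leaves * (k + 2) * (k + 2) > 1.0 * m_tot * m_tot * m_tot:
                # bound: RSS of chosen[:k+1] together with the whole suffix
                for i in range(k + 1):
                    for m in range(i + 1):
                        Lb[i, m] = L[i, m]
                    zb[i] = z[i]
                gain_b = 0.0
                r = k + 1
                for jj in range(j + 1, v):
                    # rows beyond k reference suffix columns
                    for i in range(r):
                        ci = chosen[i] if i <= k else (j + 1 + (i - k - 1))
                        acc = G[jj, ci]
                        for m in range(i):
                            acc -= Lb[r, m] * Lb[i, m]
                        Lb[r, i] = acc / Lb[i, i]
                    d = G[jj, jj]
                    for m in range(r):
                        d -= Lb[r, m] * Lb[r, m]
                    if d > _SINGULAR_RTOL * G[jj, jj] and d > 0.0:
                        Lb[r, r] = np.sqrt(d)
                    else:
                        Lb[r, r] = 1e30
                    acc = c[jj]
                    for m in range(r):
                        acc -= Lb[r, m] * zb[m]
                    zb[r] = acc / Lb[r, r]
                    gain_b += zb[r] * zb[r]
                    r += 1
                bound = uTu - zsq[k + 1] - gain_b
                # keep subtrees that may contain ties (within tol)
                cut = best_rss + tol
                if prune_cut < cut:
                    cut = prune_cut
                if bound > cut:
                    descend = False
        if descend:
            k += 1
            pos[k] = j  # incremented to j+1 at the top of the loop
    if not np.isfinite(best_rss):
        best_rss = uTu
    return best_orig, max(best_rss, 0.0), nodes


@njit(cache=True)
def all_subsets_rss_kernel(G, c, uTu):
    """RSS of the LS fit for every subset of the ``m`` candidate columns.

    Returns an array of length ``2**m`` indexed by bitmask (bit ``i`` set
    means candidate position ``i`` is in the subset); entry 0 is ``uTu``
    (empty model).  Requires ``m <= 25``.
    """
    m = G.shape[0]
    out = np.empty(1 << m, np.float64)
    out[0] = uTu
    if m == 0:
        return out
    chosen = np.empty(m, np.int64)
    pos = np.empty(m, np.int64)
    masks = np.empty(m, np.int64)
    L = np.zeros((m, m))
    z = np.zeros(m)
    zsq = np.zeros(m + 1)
    k = 0
    pos[0] = -1
    while k >= 0:
        pos[k] += 1
        if pos[k] >= m:
            k -= 1
            continue
        j = pos[k]
        gain = _extend_row(G, c, L, z, chosen, k, j)
        chosen[k] = j
        zsq[k + 1] = zsq[k] + gain
        mask = (masks[k - 1] if k > 0 else 0) | (1 << j)
        masks[k] = mask
        out[mask] = max(uTu - zsq[k + 1], 0.0)
        if j < m - 1:
            k += 1
            pos[k] = j  # incremented to j+1 at the top of the loop
    return out
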