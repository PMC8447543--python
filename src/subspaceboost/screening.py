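"""Screening initializers for the randomized subspace algorithms.

The first candidate subspace must contain a reasonable set of variables,
otherwise early iterations update noise.  Forward regression is the default
screen; sure independence screening (marginal correlation ranking) is the
cheap alternative for very wide data (auto-substituted when p > 5000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import phi_select
from .criteria import CriterionSpec
from .dataset import Dataset, center

__all__ = ["ScreenConfig", "forward_screen", "sis_screen", "init_data_driven_s"]

log = logging.getLogger(__name__)

#: above this dimension the default screen switches from forward to SIS
SIS_AUTO_P = 5000


@dataclass(frozen=True)
class ScreenConfig:
    method: str = "forward"  # one of {"forward", "sis", "auto"}
    size: int = 15

    def __post_init__(self):
        if self.method not in ("forward", "sis", "auto"):
            raise ValueError("screen method must be 'forward', 'sis' or 'auto'")
        if self.size < 1:
            raise ValueError("screen size must be at least 1")


def forward_screen(data: Dataset, k: int) -> list:
    """Greedy forward regression: ``k`` steps of adding the variable with
    the largest RSS reduction of the joint least-squares fit.

    Returns the 1-based indices in selection order.  Implemented by keeping
    the not-yet-chosen columns orthogonalized against the span of the chosen
    ones, so each step costs O(np).
    """
    if k >= data.n:
        raise ValueError(f"k = {k} must be smaller than n = {data.n}")
    ds = center(data)
    Xp = ds.X.copy()  # columns progressively orthogonalized
    r = ds.y.copy()
    p = ds.p
    col_sq0 = (Xp**2).sum(axis=0)
    chosen: list = []
    available = np.ones(p, dtype=bool)
    for _ in range(min(k, p)):
        col_sq = (Xp**2).sum(axis=0)
        # degenerate (exhausted/constant) columns cannot reduce the RSS
        ok = available & (col_sq > 1e-12 * np.maximum(col_sq0, 1e-300))
        if not ok.any():
            break
        red = np.zeros(p)
        proj = Xp.T @ r
        red[ok] = proj[ok] ** 2 / col_sq[ok]
        j = int(np.argmax(red))  # ties -> smallest index
        if red[j] <= 0:
            break
        q = Xp[:, j] / np.sqrt(col_sq[j])
        r = r - q * (q @ r)
        Xp = Xp - np.outer(q, q @ Xp)
        available[j] = False
        chosen.append(j + 1)
    return chosen


def sis_screen(data: Dataset, k: int) -> list:
    """Sure independence screening: top-``k`` by |Pearson correlation|.

    Zero-variance columns rank last; the sort is stable, so equal scores
    keep ascending index order.
    """
    if k > data.p:
        k = data.p
    ds = center(data)
    sx = np.sqrt((ds.X**2).sum(axis=0))
    sy = np.sqrt(float(ds.y @ ds.y))
    score = np.zeros(ds.p)
    nz = sx > 0
    if sy > 0:
        score[nz] = np.abs(ds.X[:, nz].T @ ds.y) / (sx[nz] * sy)
    order = np.argsort(-score, kind="stable")
    return [int(j) + 1 for j in order[:k]]


def _run_screen(data: Dataset, k: int, method: str) -> list:
    if method == "auto":
        method = "sis" if data.p > SIS_AUTO_P else "forward"
    if method == "forward":
        return forward_screen(data, k)
    return sis_screen(data, k)


def init_data_driven_s(
    data: Dataset,
    crit: CriterionSpec,
    s_max: int = 15,
    screen_method: str = "auto",
):
    """Data-driven maximum update size and initial subset.

    Screens ``V0`` of size ``s_max``, evaluates ``S0 = Phi(data, V0)`` and
    sets ``s = max(|S0|, 1)``.  The floor of 1 keeps the algorithm able to
    move when Phi selects the empty model (it will then auto-stop almost
    immediately under a true null).  Returns ``(s, S0)`` with ``S0`` a
    sorted tuple of 1-based indices.
    """
    if s_max >= data.n:
        raise ValueError(f"s_max = {s_max} must be smaller than n = {data.n}")
    ds = center(data)
    V0 = _run_screen(ds, min(s_max, ds.p), screen_method)
    S0 = phi_select(ds, V0, crit)
    s = len(S0)
    if s == 0:
        log.info("Phi selected the empty model on the screened set; s floored to 1")
        s = 1
    return s, S0
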