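"""Synthetic data generators for correlated sparse linear regression.

Covariate rows are i.i.d. N_p(0, Sigma) with the Toeplitz (AR(1))
correlation ``Sigma_{j,k} = rho^{|j-k|}``; the response is
``y = X beta + eps`` with Gaussian noise.  The named presets reproduce the
standard benchmark conditions used throughout the package's evaluation:
a correlated low-dimensional design, two sparse high-dimensional designs
(fixed adjacent support vs. randomly scattered support), a non-sparse
design, and the illustrative example with coefficients (-2, -1, 1, 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .dataset import Dataset

__all__ = [
    "SimConfig",
    "SimReplicate",
    "toeplitz_cov",
    "simulate_replicate",
    "preset_setting",
    "PRESETS",
]


@dataclass(frozen=True)
class SimConfig:
    """Data-generating configuration.

    ``s_true_spec`` is either ``("fixed", indices)`` for a fixed support or
    ``("random_k", k)`` for a support of size ``k`` drawn uniformly without
    replacement per replicate.  ``beta_spec`` is ``("fixed", vector)``
    (length p or length |S_true|) or ``("uniform", low, high)`` for i.i.d.
    uniform coefficients on the support.
    """

    n: int = 100
    p: int = 20
    rho: float = 0.8
    s_true_spec: tuple = ("fixed", (1, 2, 3, 4))
    beta_spec: tuple = ("uniform", -2.0, 2.0)
    noise_sd: float = 1.0
    seed: int = 0
    test_n: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        kind = self.s_true_spec[0]
        if kind == "fixed":
            S = tuple(sorted(int(j) for j in self.s_true_spec[1]))
            if S and (S[0] < 1 or S[-1] > self.p):
                raise ValueError("fixed S_true must be a subset of 1..p")
            object.__setattr__(self, "s_true_spec", ("fixed", S))
        elif kind == "random_k":
            if int(self.s_true_spec[1]) > self.p:
                raise ValueError("random_k support size exceeds p")
        else:
            raise ValueError("s_true_spec kind must be 'fixed' or 'random_k'")
        bkind = self.beta_spec[0]
        if bkind == "uniform":
            if not self.beta_spec[1] < self.beta_spec[2]:
                raise ValueError("uniform beta bounds must satisfy low < high")
        elif bkind != "fixed":
            raise ValueError("beta_spec kind must be 'fixed' or 'uniform'")


@dataclass(frozen=True)
class SimReplicate:
    """One simulated dataset with its generating truth."""

    dataset: Dataset
    beta_true: np.ndarray
    S_true: tuple
    test_dataset: Dataset = None
    seed: int = 0


def toeplitz_cov(p: int, rho: float) -> np.ndarray:
    """Covariance matrix with entries ``rho**|j-k|``."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    return toeplitz(rho ** np.arange(p))


def _ar1_columns(Z: np.ndarray, rho: float) -> np.ndarray:
    """Map iid standard-normal columns to the Toeplitz-correlated design.

    The sequential recursion ``X_1 = Z_1``,
    ``X_j = rho X_{j-1} + sqrt(1-rho^2) Z_j`` is exactly the Cholesky factor
    of the AR(1) covariance applied to ``Z`` (lower-triangular with positive
    diagonal, hence unique), so small-p Cholesky construction and this O(np)
    recursion generate identical data from identical draws.
    """
    X = np.empty_like(Z)
    X[:, 0] = Z[:, 0]
    if Z.shape[1] > 1:
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, Z.shape[1]):
            X[:, j] = rho * X[:, j - 1] + c * Z[:, j]
    return X


def simulate_replicate(cfg: SimConfig) -> SimReplicate:
    """Draw one seeded replicate (and optional test set) from the DGP."""
    rng = np.random.default_rng(cfg.seed)
    kind, val = cfg.s_true_spec
    if kind == "fixed":
        S_true = val
    else:
        S_true = tuple(sorted(rng.choice(cfg.p, size=int(val), replace=False) + 1))
    beta = np.zeros(cfg.p)
    bkind = cfg.beta_spec[0]
    if bkind == "fixed":
        vec = np.asarray(cfg.beta_spec[1], dtype=float)
        if vec.shape[0] == cfg.p:
            beta = vec.copy()
            S_true = tuple(int(j) + 1 for j in np.nonzero(beta)[0])
        else:
            if vec.shape[0] != len(S_true):
                raise ValueError("fixed beta must have length p or |S_true|")
            if vec.size:
                beta[np.array(S_true, dtype=int) - 1] = vec
    else:
        low, high = cfg.beta_spec[1], cfg.beta_spec[2]
        min_abs = cfg.beta_spec[3] if len(cfg.beta_spec) > 3 else 0.0
        vals = rng.uniform(low, high, size=len(S_true))
        if min_abs > 0:  # redraw coefficients too close to zero
            while True:
                small = np.abs(vals) < min_abs
                if not small.any():
                    break
                vals[small] = rng.uniform(low, high, size=int(small.sum()))
        if vals.size:
            beta[np.array(S_true, dtype=int) - 1] = vals

    def draw(n):
        Z = rng.standard_normal((n, cfg.p))
        X = _ar1_columns(Z, cfg.rho)
        y = X @ beta + cfg.noise_sd * rng.standard_normal(n)
        return Dataset(X=X, y=y)

    ds = draw(cfg.n)
    test = draw(cfg.test_n) if cfg.test_n else None
    return SimReplicate(
        dataset=ds, beta_true=beta, S_true=S_true, test_dataset=test, seed=cfg.seed
    )


PRESETS = {
    "lowdim": SimConfig(
        n=100, p=20, rho=0.8,
        s_true_spec=("fixed", (1, 2, 3, 4)),
        beta_spec=("uniform", -2.0, 2.0),
    ),
    "sparse_a": SimConfig(
        n=100, p=1000, rho=0.8,
        s_true_spec=("fixed", tuple(range(1, 11))),
        beta_spec=("uniform", -2.0, 2.0),
    ),
    "sparse_b": SimConfig(
        n=100, p=1000, rho=0.8,
        s_true_spec=("random_k", 10),
        beta_spec=("uniform", -2.0, 2.0),
    ),
    "nonsparse": SimConfig(
        n=1000, p=1000, rho=0.8,
        s_true_spec=("fixed", tuple(range(1, 101))),
        beta_spec=("uniform", -2.0, 2.0),
    ),
    "illustrative": SimConfig(
        n=100, p=1000, rho=0.8,
        s_true_spec=("fixed", (1, 2, 3, 4)),
        beta_spec=("fixed", (-2.0, -1.0, 1.0, 2.0)),
    ),
}


def preset_setting(name: str, **overrides) -> SimConfig:
    """Named benchmark configuration; keyword overrides are applied on top."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def export_replicate(rep: SimReplicate, csv_path, sidecar_path=None) -> None:
    """Write the replicate as CSV (x1..xp, y) plus a JSON truth sidecar."""
    ds = rep.dataset
    df = pd.DataFrame(ds.X, columns=ds.column_names)
    df["y"] = ds.y
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "beta_true": list(map(float, rep.beta_true)),
            "S_true": list(map(int, rep.S_true)),
            "seed": int(rep.seed),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)
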