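"""Design-matrix container, mean-centering and delimited-text input.

The linear model used throughout the package has no intercept: covariates
and response are mean-centered before fitting, and the centering offsets are
retained so predictions on new data can reconstruct the intercept
``y_mean - sum_j beta_j * x_mean_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Dataset", "center", "read_dataset"]


@dataclass(frozen=True)
class Dataset:
    """An ``n x p`` design matrix with a continuous response.

    Attributes
    ----------
    X : ndarray of shape (n, p)
    y : ndarray of shape (n,)
    column_names : list of str, one per covariate
    x_means, y_mean : centering offsets (zero for raw data)
    centered : whether ``X`` and ``y`` are mean-centered
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list = field(default=None)
    x_means: np.ndarray = None
    y_mean: float = 0.0
    centered: bool = False

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        n, p = X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible lengths")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must not contain missing or infinite values")
        names = self.column_names
        if names is None:
            names = [f"x{j + 1}" for j in range(p)]
        elif len(names) != p:
            raise ValueError("column_names length must equal p")
        xm = self.x_means
        if xm is None:
            xm = np.zeros(p)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "column_names", list(names))
        object.__setattr__(self, "x_means", np.asarray(xm, dtype=float))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, rows) -> "Dataset":
        """A new (uncentered-offsets preserved) dataset with the given rows."""
        return replace(self, X=self.X[rows], y=self.y[rows])


def center(dataset: Dataset) -> Dataset:
    """Mean-center covariates and response, storing the offsets.

    Idempotent: a dataset flagged as centered is returned unchanged.
    Constant (zero-variance) columns are retained with a warning; they can
    never reduce the RSS, so downstream selection simply ignores them.
    """
    if dataset.centered:
        return dataset
    x_means = dataset.X.mean(axis=0)
    y_mean = float(dataset.y.mean())
    Xc = dataset.X - x_means
    scale = np.maximum(np.abs(dataset.X).max(axis=0), 1.0)
    const = np.abs(Xc).max(axis=0) <= 1e-12 * scale
    if const.any():
        bad = [dataset.column_names[j] for j in np.nonzero(const)[0]]
        warnings.warn(
            f"constant column(s) retained after centering: {bad}",
            UserWarning,
            stacklevel=2,
        )
    return Dataset(
        X=Xc,
        y=dataset.y - y_mean,
        column_names=dataset.column_names,
        x_means=x_means,
        y_mean=y_mean,
        centered=True,
    )


def read_dataset(path, response: str) -> Dataset:
    """Read a delimited text file (comma/tab/semicolon, autodetected).

    ``response`` names the response column; all remaining columns become
    covariates, in file order.  Returns an uncentered :class:`Dataset`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if response not in df.columns:
        raise ValueError(
            f"response column {response!r} not found; columns: {list(df.columns)}"
        )
    y = df[response].to_numpy(dtype=float)
    Xdf = df.drop(columns=[response])
    if Xdf.shape[1] == 0:
        raise ValueError("no covariate columns besides the response")
    X = Xdf.to_numpy(dtype=float)
    return Dataset(X=X, y=y, column_names=list(Xdf.columns))
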