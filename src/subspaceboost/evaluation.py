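"""Selection/prediction metrics, replicate runner and external LOOCV.

The replicate runner reproduces the benchmark protocol: fresh training and
test draws per replicate, every method fit on the training data, and false
positives / false negatives / estimation error / prediction error recorded
in a long-format table.  External LOOCV reruns the *entire* selection and
fitting pipeline on each leave-one-out training set, so model-size and
prediction-error summaries are honest out-of-sample quantities.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .boosting import BoostConfig, BoostFit, fit_boost, predict
from .criteria import CriterionSpec
from .dataset import Dataset
from .synthetic_data import SimConfig, SimReplicate, simulate_replicate

__all__ = [
    "EvalMetrics",
    "LoocvResult",
    "selection_metrics",
    "prediction_mse",
    "run_replicates",
    "external_loocv",
    "study_methods",
    "application_defaults",
    "derive_seed",
]

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-fold / per-replicate seed below 2**31, independent of
    execution order."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class EvalMetrics:
    """Selection and error metrics of one fit against the generating truth."""

    fp: int
    fn: int
    tp: int
    est_mse: float
    pred_mse: float
    pred_rmse: float
    model_size: int


def selection_metrics(selected, S_true):
    """False positives, false negatives and true positives of a selection."""
    sel = set(int(j) for j in selected)
    true = set(int(j) for j in S_true)
    fp = len(sel - true)
    fn = len(true - sel)
    tp = len(sel & true)
    return fp, fn, tp


def prediction_mse(fit: BoostFit, test) -> float:
    """Mean squared prediction error on a test Dataset or SimReplicate."""
    ds = test.dataset if isinstance(test, SimReplicate) else test
    resid = ds.y - predict(fit, ds.X)
    return float(resid @ resid) / ds.n


def evaluate_fit(fit: BoostFit, rep: SimReplicate) -> EvalMetrics:
    fp, fn, tp = selection_metrics(fit.selected, rep.S_true)
    est = float(((fit.beta - rep.beta_true) ** 2).sum())
    pm = prediction_mse(fit, rep.test_dataset) if rep.test_dataset else np.nan
    return EvalMetrics(
        fp=fp,
        fn=fn,
        tp=tp,
        est_mse=est,
        pred_mse=pm,
        pred_rmse=float(np.sqrt(pm)),
        model_size=len(fit.selected),
    )


def run_replicates(
    setting: SimConfig,
    methods: dict,
    n_reps: int,
    seed: int = 0,
    test_n: int = 1000,
):
    """Fit every method on ``n_reps`` fresh replicates of the setting.

    ``methods`` maps a display name to a :class:`BoostConfig`.  Returns
    ``(long, summary)``: a long-format table (replicate, method, metric,
    value) and a per-method/metric summary with mean, median and quartiles.
    Per-replicate failures are recorded as rows with NaN values and logged,
    never silently dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rows = []
    metrics = ("fp", "fn", "tp", "est_mse", "pred_mse", "pred_rmse", "model_size")
    for i in range(n_reps):
        rep_seed = derive_seed(seed, i)
        rep = simulate_replicate(replace(setting, seed=rep_seed, test_n=test_n))
        for name, cfg in methods.items():
            # stable per-(replicate, method) seed; zlib.crc32 is not salted
            cfg_i = replace(cfg, seed=derive_seed(rep_seed, zlib.crc32(name.encode())))
            try:
                fit = fit_boost(rep.dataset, cfg_i)
                em = evaluate_fit(fit, rep)
                vals = {m: getattr(em, m) for m in metrics}
            except Exception:  # noqa: BLE001 - recorded, not dropped
                log.exception("replicate %d method %s failed", i, name)
                vals = {m: np.nan for m in metrics}
            for m, v in vals.items():
                rows.append((i, name, m, float(v)))
    long = pd.DataFrame(rows, columns=["replicate", "method", "metric", "value"])
    summary = (
        long.groupby(["method", "metric"])["value"]
        .agg(
            mean="mean",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return long, summary


@dataclass
class LoocvResult:
    """Per-fold records and summaries of external leave-one-out CV.

    For an even number of folds the median is the midpoint of the two
    middle order statistics, which are also reported (``*_mid_pair``).
    """

    folds: pd.DataFrame  # fold, model_size, abs_error, selected
    median_model_size: float
    mean_model_size: float
    median_abs_error: float
    mean_abs_error: float
    model_size_mid_pair: tuple
    abs_error_mid_pair: tuple


def _mid_pair(values: np.ndarray) -> tuple:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n % 2:
        return (float(v[n // 2]), float(v[n // 2]))
    return (float(v[n // 2 - 1]), float(v[n // 2]))


def external_loocv(data: Dataset, method: BoostConfig, seed: int = 0) -> LoocvResult:
    """External LOOCV: the full pipeline is rerun on each n-1 training set.

    Centering, screening and fitting use only the training rows; the
    held-out row is predicted with the intercept reconstructed from the
    training offsets.  Per-fold seeds derive from ``seed``.
    """
    n = data.n
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = data.subset_rows(mask)
        cfg = replace(method, seed=derive_seed(seed, i))
        try:
            fit = fit_boost(train, cfg)
            pred = float(predict(fit, data.X[i][None, :])[0])
            rows.append(
                {
                    "fold": i,
                    "model_size": len(fit.selected),
                    "abs_error": abs(pred - float(data.y[i])),
                    "selected": fit.selected,
                    "train_y_mean": fit.y_mean,
                }
            )
        except Exception:  # noqa: BLE001
            log.exception("LOOCV fold %d failed", i)
            rows.append(
                {
                    "fold": i,
                    "model_size": np.nan,
                    "abs_error": np.nan,
                    "selected": (),
                    "train_y_mean": np.nan,
                }
            )
    folds = pd.DataFrame(rows)
    sizes = folds["model_size"].to_numpy(dtype=float)
    errs = folds["abs_error"].to_numpy(dtype=float)
    return LoocvResult(
        folds=folds,
        median_model_size=float(np.nanmedian(sizes)),
        mean_model_size=float(np.nanmean(sizes)),
        median_abs_error=float(np.nanmedian(errs)),
        mean_abs_error=float(np.nanmean(errs)),
        model_size_mid_pair=_mid_pair(sizes[~np.isnan(sizes)]),
        abs_error_mid_pair=_mid_pair(errs[~np.isnan(errs)]),
    )


def application_defaults(p: int) -> dict:
    """Boosting parameters used for real biomedical datasets.

    Low-dimensional data (p <= 20): BIC, s_max = 4, m_max = 1000.
    High-dimensional data: EBIC(gamma=1), s_max = 15, m_max = 10000, with
    sure independence screening above p = 5000.  In both regimes
    q = min(20, p/2) and K = p/q.
    """
    lowdim = p <= 20
    q = max(2, min(20, p // 2))
    return dict(
        crit=CriterionSpec("BIC") if lowdim else CriterionSpec("EBIC", gamma=1.0),
        s_max=4 if lowdim else 15,
        m_max=1000 if lowdim else 10_000,
        q=q,
        K=p / q,
        screen="auto",  # forward regression; SIS above p = 5000
    )


def study_methods(preset: str, p: int, include_subboost: bool = None) -> dict:
    """Benchmark method configurations for a named simulation preset.

    Mirrors the benchmark study settings: learning rate 0.1 for L2Boosting
    and 0.01 for the subspace methods; BIC with s_max = 7, q = 10 and
    m_max = 1000 in the low-dimensional setting; EBIC(gamma=1) with
    s_max = 15, q = 20 and m_max = 5000 in the sparse high-dimensional
    settings (10000 non-sparse); K = p/q; N_stop = p/2 as in the
    experiments (the general-purpose default would be ceil(p/s)).
    SubBoost (full search) is included only where tractable.
    """
    if preset == "lowdim":
        crit = CriterionSpec("BIC")
        s_max, q, m_max = 7, 10, 1000
    elif preset in ("sparse_a", "sparse_b", "illustrative"):
        crit = CriterionSpec("EBIC", gamma=1.0)
        s_max, q, m_max = 15, 20, 5000
    elif preset == "nonsparse":
        crit = CriterionSpec("EBIC", gamma=1.0)
        s_max, q, m_max = 15, 20, 10000
    else:
        raise ValueError(f"unknown preset {preset!r}")
    N_stop = max(p // 2, 1)
    K = p / q
    methods = {
        "l2boost_cv": BoostConfig(method="l2boost", stopping="cv", m_max=m_max),
        "l2boost_earlier": BoostConfig(
            method="l2boost", stopping="earlier", m_max=m_max
        ),
        "rsubboost": BoostConfig(
            method="rsubboost", crit=crit, s_max=s_max, q=q, N_stop=N_stop,
            m_max=m_max,
        ),
        "adasubboost": BoostConfig(
            method="adasubboost", crit=crit, s_max=s_max, q=q, K=K,
            N_stop=N_stop, m_max=m_max,
        ),
    }
    if include_subboost is None:
        include_subboost = p <= 20
    if include_subboost:
        methods["subboost"] = BoostConfig(
            method="subboost", crit=crit, m_max=m_max, s_max=s_max
        )
    return methods
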