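"""Blood-pressure estimation error metrics and the AAMI model criterion.

The error convention is ``error = estimate - reference``, so a positive
mean error (ME) means over-estimation.  The standard deviation of error
(SDE) uses the sample (n-1) denominator.  R-squared is normalized by the
total sum of squares of the references; the Pearson correlation R is
reported separately because it can stay high in the presence of large
systematic error and is therefore not an error metric by itself.

A model shows potential compliance with the AAMI criterion when, over the
AAMI testing set, |ME| <= 5 mmHg and SDE <= 8 mmHg for both SBP and DBP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "ErrorMetrics",
    "compute_metrics",
    "aami_model_check",
    "track_training_metrics",
]


@dataclass
class ErrorMetrics:
    me: float  # mean error, mmHg
    sde: float  # standard deviation of error (n-1), mmHg
    mae: float  # mean absolute error, mmHg
    rmse: float  # root mean squared error, mmHg
    r2: float  # coefficient of determination (NaN if reference variance is 0)
    r: float  # Pearson correlation (NaN if reference variance is 0)
    n: int


def compute_metrics(references, estimates) -> ErrorMetrics:
    """Error metrics of BP estimates against references.

    Requires equal-length finite inputs with n >= 2.  When the references
    have zero variance, R and R-squared are undefined and reported as NaN.
    """
    ref = np.asarray(references, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("references and estimates must be equal-length 1-d arrays")
    n = len(ref)
    if n < 2:
        raise ValueError("at least 2 paired values are required")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(est))):
        raise ValueError("non-finite values in input")
    err = est - ref
    me = float(np.mean(err))
    sde = float(np.std(err, ddof=1))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        r2 = float("nan")
        r = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
        if np.std(est) == 0:
            r = float("nan")
        else:
            r = float(sp_stats.pearsonr(ref, est).statistic)
    return ErrorMetrics(me=me, sde=sde, mae=mae, rmse=rmse, r2=r2, r=r, n=n)


def aami_model_check(
    metrics: ErrorMetrics,
    me_limit: float = 5.0,
    sde_limit: float = 8.0,
) -> bool:
    """AAMI model criterion: |ME| within +-5 mmHg and SDE within 8 mmHg.

    Bounds are inclusive ("within"); pass exactly at the boundary.
    """
    return bool(abs(metrics.me) <= me_limit and metrics.sde <= sde_limit)


def track_training_metrics(
    estimator_by_epoch: Sequence[Callable[[pd.DataFrame], np.ndarray]],
    subsets: Mapping[str, pd.DataFrame],
    value_col: str = "sbp_ref",
) -> pd.DataFrame:
    """Record error-metric trajectories of an estimator across epochs.

    ``estimator_by_epoch`` holds one callable per epoch mapping a subset's
    segment table to an estimate per row; ``subsets`` maps subset names
    (e.g. training / calibration-based / calibration-free) to tables
    containing ``value_col`` references.  Returns a tidy table with one row
    per (epoch, subset) carrying ME, SDE, MSE, MAE, RMSE, R2, R and n,
    suitable for over-fitting-gap analysis with any estimator (including a
    mean-predictor baseline).  The table round-trips losslessly through
    CSV.
    """
    for name, df in subsets.items():
        if len(df) == 0:
            raise ValueError(f"subset {name!r} is empty")
    rows = []
    for epoch, predict in enumerate(estimator_by_epoch):
        for name, df in subsets.items():
            ref = df[value_col].to_numpy(dtype=float)
            est = np.asarray(predict(df), dtype=float)
            m = compute_metrics(ref, est)
            rows.append(
                {
                    "epoch": epoch,
                    "subset": name,
                    "me": m.me,
                    "sde": m.sde,
                    "mse": m.rmse**2,
                    "mae": m.mae,
                    "rmse": m.rmse,
                    "r2": m.r2,
                    "r": m.r,
                    "n": m.n,
                }
            )
    return pd.DataFrame(rows)
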