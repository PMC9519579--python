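"""Shared model-scoring primitives: adjusted R-squared and the Gaussian LRT."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["adjusted_r2", "lrt_significance"]


def adjusted_r2(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    """Adjusted R-squared between an outcome and a prediction.

    R-squared is the squared Pearson correlation between ``y`` and ``yhat``
    (0 when either is constant), adjusted for ``p`` predictors:
    ``1 - (1 - R2) * (n - 1) / (n - p - 1)``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if y.std() == 0 or yhat.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def lrt_significance(y: np.ndarray, predictors: np.ndarray) -> tuple[float, float]:
    """Likelihood ratio test of a linear model against the intercept-only null.

    ``predictors`` is an (n,) vector or (n, k) matrix with k in {1, 2}; constant
    columns are dropped before fitting.  The Gaussian profile-likelihood
    statistic is ``n * log(RSS0 / RSS1)`` with a chi-square null on k degrees of
    freedom.  Returns ``(statistic, p_value)``; a perfect fit (RSS1 = 0) gives
    p = 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    df = X.shape[1]
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if df == 0 or rss0 == 0:
        return 0.0, 1.0
    Xd = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    rss1 = float(np.sum((y - Xd @ coef) ** 2))
    if rss1 <= 0:
        return np.inf, 0.0
    stat = n * np.log(rss0 / rss1)
    if stat < 0:  # numerical round-off
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df))
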