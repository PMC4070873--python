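"""Between-sample quantile normalization and the beta <-> M transform.

Statistics downstream are computed on M values, the log2 odds of the
methylation proportion: M = log2(beta / (1 - beta)). M values are
approximately homoscedastic across the beta range, which is what the
per-probe linear models assume; effect sizes are still reported as
delta-beta on the proportion scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the across-sample mean quantile function.

    After normalization each sample's sorted values equal the mean of the
    order statistics across samples; ties within a sample receive the mean
    of the target values over their rank range.
    """
    if beta.shape[1] < 2:
        return beta.copy()
    values = beta.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize requires complete data; "
                         "impute or drop probes with missing values first")
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def beta_to_m(beta, eps: float = 0.001):
    """M = log2(b / (1-b)) after clipping b into [eps, 1-eps]."""
    if not 0.0 < eps < 0.1:
        raise ValueError("eps must be in (0, 0.1)")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` on clipped inputs: b = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b
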