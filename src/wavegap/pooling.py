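"""Rubin's rules for combining estimates across imputed datasets."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledEffect", "pool_rubin"]


@dataclass
class PooledEffect:
    """Rubin-pooled estimate with its variance decomposition.

    point
        Mean of the per-dataset estimates (Q-bar).
    within_var, between_var, total_var
        W = mean per-dataset variance; B = sample variance of the
        estimates; T = W + (1 + 1/m) B.
    df
        Rubin degrees of freedom, (m - 1) (1 + W / ((1 + 1/m) B))^2;
        infinite when B = 0.
    ci95
        point +/- t_{df, 0.975} sqrt(T).
    """

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci95: tuple
    m: int


def pool_rubin(estimates, variances) -> PooledEffect:
    """Combine m per-imputation (estimate, variance) pairs.

    Q-bar = mean(estimates); W = mean(variances); B = sample variance of
    the estimates (ddof 1); T = W + (1 + 1/m) B.  The 95% interval uses
    the t distribution with the classic large-m degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = q.size
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite estimate or variance")
    if np.any(w < 0):
        raise ValueError("variances must be nonnegative")

    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0.0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        tcrit = stats.t.ppf(0.975, df)
    else:
        df = math.inf
        tcrit = stats.norm.ppf(0.975)
    half = tcrit * math.sqrt(T)
    return PooledEffect(
        point=qbar, within_var=W, between_var=B, total_var=T,
        df=df, ci95=(qbar - half, qbar + half), m=m,
    )
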