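"""Rubin's rules for combining estimates across imputations.

For m completed-data estimates q_l with model-based variances U_l:

    qbar = mean(q_l)
    W    = mean(U_l)                (within-imputation variance)
    B    = var(q_l)                 (between, m-1 denominator)
    T    = W + (1 + 1/m) B          (total variance)

and a t reference with Barnard-Rubin degrees of freedom, which blends the
large-sample rule (m-1)/lambda^2 with an observed-data adjustment when the
complete-data degrees of freedom are finite.

Variance components, for which the analysis fit reports no standard error,
are pooled as the simple mean across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PooledResult", "rubin_pool", "pool_variance_components"]


@dataclass(frozen=True)
class PooledResult:
    """Rubin-pooled estimate with its variance decomposition."""

    qbar: float
    W: float
    B: float
    T: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_com: float = np.inf,
    level: float = 0.95,
) -> PooledResult:
    """Pool m estimates and their squared standard errors.

    ``df_com`` is the complete-data degrees of freedom (rows minus fixed
    effects); pass ``inf`` for the large-sample Rubin df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin's rules need m >= 2 (between-variance undefined)")
    if u.size != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")

    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B

    if B > 0:
        lam = (1.0 + 1.0 / m) * B / T
        df_large = (m - 1) / lam**2
        if np.isfinite(df_com):
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
        else:
            df = df_large
    else:
        df = df_com if np.isfinite(df_com) else np.inf

    tcrit = stats.norm.ppf(0.5 + level / 2) if np.isinf(df) else stats.t.ppf(
        0.5 + level / 2, df
    )
    half = tcrit * np.sqrt(T)
    return PooledResult(qbar, W, B, T, float(df), qbar - half, qbar + half, m)


def pool_variance_components(values: Sequence[Sequence[float]]) -> np.ndarray:
    """Mean of (sigma2_l1, sigma2_l2, sigma2_l3) across imputations."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected one row of components per imputation")
    return arr.mean(axis=0)
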