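"""Shared sampler utilities: conjugate draws, convergence diagnostics,
and the sparse-cluster failure raised by dummy-indicator engines."""

from __future__ import annotations

import numpy as np
from scipy import stats


class SparseClusterError(RuntimeError):
    """A dummy-indicator (or random-effect) imputation model is unidentified
    because some clusters contribute no observed values of the target."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "imputation model is rank deficient due to sparse data; "
            f"offending columns: {self.columns}"
        )


def check_di_support(X: np.ndarray, names: list[str], rows: np.ndarray) -> None:
    """Raise if any indicator-like column is constant on the given rows."""
    sub = X[rows]
    if sub.shape[0] == 0:
        raise SparseClusterError(names)
    bad = [
        name
        for j, name in enumerate(names)
        if name != "intercept" and np.ptp(sub[:, j]) == 0.0 and "_di_" in name
    ]
    if bad:
        raise SparseClusterError(bad)


def draw_inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray
                     ) -> np.ndarray:
    """Inverse-Wishart draw; the 1x1 case reduces to an inverse-gamma."""
    if scale.shape == (1, 1):
        return np.array([[scale[0, 0] / rng.chisquare(df)]])
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def draw_inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def split_chain_psr(draws: np.ndarray) -> float:
    """Potential scale reduction from splitting one chain into two halves.

    Values near 1 indicate the two halves explore the same distribution;
    above ~1.10 is conventionally flagged.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[x.size - n:]])
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def psr_table(monitor: dict[str, list[float]], burn_in: int) -> dict[str, float]:
    return {
        name: split_chain_psr(np.asarray(vals[burn_in:]))
        for name, vals in monitor.items()
    }
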