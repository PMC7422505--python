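"""Joint-modelling (JM) imputation engines.

Two samplers are provided, both assuming joint normality of the incomplete
variables given the complete predictors:

* :func:`impute_jm_single_level` — multivariate-normal data augmentation
  for ``Y | X ~ MVN(XB, Sigma)``: an I-step draws each row's missing
  entries from their conditional normal given the observed entries and the
  current parameters, and a P-step draws ``(B, Sigma)`` from the
  complete-data posterior (flat prior on ``B``, inverse-Wishart on
  ``Sigma``).  Cluster membership is carried by dummy-indicator predictor
  columns (the "JM-1L-DI-wide" recipe when run on wide-format data).

* :func:`impute_jm_two_level` — a Gibbs sampler for the multivariate
  random-intercept model ``Y_ij = X_ij B + b_i + e_ij`` with
  ``b_i ~ N(0, Psi)`` and ``e_ij ~ N(0, Sigma)``.  With schools as the
  cluster and wide-format data this is "JM-2L-wide"; with children as the
  cluster, long-format rows, and school dummy indicators among the
  predictors it is "JM-2L-DI".

Both run one long chain: imputations are saved every ``between``
iterations after ``burn_in``.  Split-chain potential-scale-reduction (PSR)
statistics on monitored parameters are reported in the diagnostics and a
warning (not a failure) is emitted above 1.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._mcmc import SparseClusterError, check_di_support, draw_inv_wishart, psr_table

__all__ = [
    "ImputationSpec",
    "MCMCSettings",
    "ImputedSet",
    "impute_jm_single_level",
    "impute_jm_two_level",
    "build_jm_spec",
    "JM_ENGINES",
]

JM_ENGINES = ("jm-1l-di-wide", "jm-2l-wide", "jm-2l-di")


@dataclass(frozen=True)
class ImputationSpec:
    """Which variables an engine imputes, and from what.

    ``incomplete_vars`` enter the joint model as outcomes; the (fully
    observed) ``predictor_vars`` as covariates.  ``cluster_var`` names the
    random-intercept grouping for the two-level engine and must be None
    for the single-level one.
    """

    incomplete_vars: tuple[str, ...]
    predictor_vars: tuple[str, ...]
    cluster_var: str | None = None
    layout: Literal["wide", "long"] = "wide"

    def __post_init__(self) -> None:
        overlap = set(self.incomplete_vars) & set(self.predictor_vars)
        if overlap:
            raise ValueError(f"variables cannot be both outcome and predictor: {overlap}")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length controls: ``burn_in`` iterations, then one imputation
    saved every ``between`` iterations until ``m`` are collected."""

    burn_in: int = 1000
    between: int = 100
    m: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 1 or self.between < 1:
            raise ValueError("burn_in and between must be >= 1")
        if self.m < 2:
            raise ValueError("m must be >= 2")


@dataclass
class ImputedSet:
    """m completed datasets plus engine metadata and chain diagnostics."""

    datasets: list[pd.DataFrame]
    engine: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _design(data: pd.DataFrame, predictors: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in predictors]
    )
    names = ["intercept"] + list(predictors)
    if np.isnan(X).any():
        bad = [n for n, col in zip(names, X.T) if np.isnan(col).any()]
        raise ValueError(f"predictors must be fully observed; NaN in {bad}")
    return X, names


def _patterns(mis: np.ndarray):
    """Group row indices by missingness pattern (patterns with any miss)."""
    out = []
    if not mis.any():
        return out
    keys = np.packbits(mis, axis=1) if mis.shape[1] > 1 else mis.astype(np.uint8)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    for u in range(len(uniq)):
        rows = np.flatnonzero(inv == u)
        pat = mis[rows[0]]
        if pat.any():
            out.append((rows, np.flatnonzero(pat), np.flatnonzero(~pat)))
    return out


def _impute_rows(Y, mu, Sigma, patterns, rng):
    """Draw missing entries row-block-wise from the conditional normal."""
    for rows, mis_ix, obs_ix in patterns:
        S_mm = Sigma[np.ix_(mis_ix, mis_ix)]
        if obs_ix.size:
            S_mo = Sigma[np.ix_(mis_ix, obs_ix)]
            S_oo = Sigma[np.ix_(obs_ix, obs_ix)]
            K = np.linalg.solve(S_oo, S_mo.T).T            # Sigma_mo Sigma_oo^-1
            cond_mean = mu[np.ix_(rows, mis_ix)] + (
                (Y[np.ix_(rows, obs_ix)] - mu[np.ix_(rows, obs_ix)]) @ K.T
            )
            cond_cov = S_mm - K @ S_mo.T
        else:
            cond_mean = mu[np.ix_(rows, mis_ix)]
            cond_cov = S_mm
        L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(len(mis_ix)))
        z = rng.standard_normal((rows.size, mis_ix.size))
        Y[np.ix_(rows, mis_ix)] = cond_mean + z @ L.T


def _init_missing(Y, mis, rng):
    """Start missing entries at the observed mean plus observed-SD noise."""
    for j in range(Y.shape[1]):
        obs = Y[~mis[:, j], j]
        if obs.size == 0:
            raise ValueError(f"variable column {j} has no observed values")
    for j in range(Y.shape[1]):
        rows = np.flatnonzero(mis[:, j])
        if rows.size:
            obs = Y[~mis[:, j], j]
            sd = obs.std() if obs.size > 1 else 1.0
            Y[rows, j] = obs.mean() + sd * rng.standard_normal(rows.size)


def _finalize(data, spec, completed, engine, monitor, mcmc) -> ImputedSet:
    psr = psr_table(monitor, mcmc.burn_in)
    chain_mean = {
        name: float(np.mean(vals[mcmc.burn_in:])) if len(vals) > mcmc.burn_in
        else float(np.mean(vals))
        for name, vals in monitor.items()
    }
    worst = max((v for v in psr.values() if np.isfinite(v)), default=np.nan)
    if np.isfinite(worst) and worst > 1.10:
        warnings.warn(
            f"{engine}: split-chain PSR {worst:.3f} exceeds 1.10; consider a "
            "longer burn-in",
            RuntimeWarning,
            stacklevel=3,
        )
    sets = []
    for Y in completed:
        df = data.copy()
        for j, v in enumerate(spec.incomplete_vars):
            df[v] = Y[:, j]
        sets.append(df)
    return ImputedSet(
        sets, engine, {"psr": psr, "chain_mean": chain_mean, "settings": mcmc}
    )


def impute_jm_single_level(
    data: pd.DataFrame, spec: ImputationSpec, mcmc: MCMCSettings
) -> ImputedSet:
    """Multivariate-normal data augmentation (single-level joint model)."""
    if spec.cluster_var is not None:
        raise ValueError("single-level engine takes no cluster_var")
    rng = np.random.default_rng(mcmc.seed)
    X, names = _design(data, spec.predictor_vars)
    Y = data[list(spec.incomplete_vars)].to_numpy(dtype=float).copy()
    n, q = X.shape
    r = Y.shape[1]
    mis = np.isnan(Y)
    obs_any = ~mis.all(axis=1)
    check_di_support(X, names, np.flatnonzero(obs_any))
    XtX = X.T @ X
    try:
        np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as err:
        zero_var = [nm for nm, col in zip(names, X.T) if np.ptp(col) == 0.0
                    and nm != "intercept"]
        raise SparseClusterError(zero_var or list(names)) from err
    XtX_inv = np.linalg.inv(XtX)
    A = np.linalg.cholesky(XtX_inv)
    patterns = _patterns(mis)
    _init_missing(Y, mis, rng)

    nu0, S0 = r + 1, np.eye(r)
    completed, monitor = [], {f"sigma_{v}": [] for v in spec.incomplete_vars}
    total = mcmc.burn_in + (mcmc.m - 1) * mcmc.between
    for it in range(1, total + 1):
        # P-step: (B, Sigma) from the completed-data posterior
        Bhat = np.linalg.solve(XtX, X.T @ Y)
        resid = Y - X @ Bhat
        Sigma = draw_inv_wishart(rng, nu0 + n - q, S0 + resid.T @ resid)
        L_s = np.linalg.cholesky(Sigma)
        B = Bhat + A @ rng.standard_normal((q, r)) @ L_s.T
        # I-step
        mu = X @ B
        _impute_rows(Y, mu, Sigma, patterns, rng)
        for j, v in enumerate(spec.incomplete_vars):
            monitor[f"sigma_{v}"].append(Sigma[j, j])
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.between == 0:
            completed.append(Y.copy())
    return _finalize(data, spec, completed, "jm-1l", monitor, mcmc)


def impute_jm_two_level(
    data: pd.DataFrame, spec: ImputationSpec, mcmc: MCMCSettings
) -> ImputedSet:
    """Gibbs sampler for the random-intercept multivariate linear mixed
    imputation model (cluster given by ``spec.cluster_var``)."""
    if spec.cluster_var is None:
        raise ValueError("two-level engine requires cluster_var")
    rng = np.random.default_rng(mcmc.seed)
    X, names = _design(data, spec.predictor_vars)
    Y = data[list(spec.incomplete_vars)].to_numpy(dtype=float).copy()
    n, q = X.shape
    r = Y.shape[1]
    mis = np.isnan(Y)
    codes, _ = pd.factorize(data[spec.cluster_var], sort=True)
    n_clust = codes.max() + 1
    if n_clust < 2:
        raise ValueError("two-level engine needs at least 2 clusters")
    counts = np.bincount(codes)
    check_di_support(X, names, np.flatnonzero(~mis.all(axis=1)))

    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
        A = np.linalg.cholesky(XtX_inv)
    except np.linalg.LinAlgError as err:
        raise SparseClusterError(list(names)) from err
    patterns = _patterns(mis)
    _init_missing(Y, mis, rng)

    nu0, S0 = r + 1, np.eye(r)
    b = np.zeros((n_clust, r))
    Sigma = np.eye(r)
    Psi = np.eye(r)
    completed = []
    monitor = {f"sigma_{v}": [] for v in spec.incomplete_vars}
    monitor.update({f"psi_{v}": [] for v in spec.incomplete_vars})

    total = mcmc.burn_in + (mcmc.m - 1) * mcmc.between
    for it in range(1, total + 1):
        # fixed effects | b, Sigma
        Bhat = np.linalg.solve(XtX, X.T @ (Y - b[codes]))
        L_s = np.linalg.cholesky(Sigma)
        B = Bhat + A @ rng.standard_normal((q, r)) @ L_s.T
        mu = X @ B
        # random effects | B, Sigma, Psi  (shared precision per cluster size)
        R = Y - mu
        Rsum = np.zeros((n_clust, r))
        np.add.at(Rsum, codes, R)
        Sig_inv = np.linalg.inv(Sigma)
        Psi_inv = np.linalg.inv(Psi)
        for n_i in np.unique(counts):
            cl = np.flatnonzero(counts == n_i)
            Lam = Psi_inv + n_i * Sig_inv
            cov = np.linalg.inv(Lam)
            Lc = np.linalg.cholesky(cov)
            mean = Rsum[cl] @ (Sig_inv @ cov).T
            b[cl] = mean + rng.standard_normal((cl.size, r)) @ Lc.T
        # covariances
        E = R - b[codes]
        Sigma = draw_inv_wishart(rng, nu0 + n, S0 + E.T @ E)
        Psi = draw_inv_wishart(rng, nu0 + n_clust, S0 + b.T @ b)
        # I-step given (B, b, Sigma)
        _impute_rows(Y, mu + b[codes], Sigma, patterns, rng)
        for j, v in enumerate(spec.incomplete_vars):
            monitor[f"sigma_{v}"].append(Sigma[j, j])
            monitor[f"psi_{v}"].append(Psi[j, j])
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.between == 0:
            completed.append(Y.copy())
    return _finalize(data, spec, completed, "jm-2l", monitor, mcmc)


def build_jm_spec(engine_name: str, data: pd.DataFrame) -> ImputationSpec:
    """Default variable roles for each JM engine, given a prepared table
    (wide or long, with SES dummies and any DI columns already added)."""
    di_cols = tuple(c for c in data.columns if "_di_" in c)
    ses_cols = tuple(c for c in data.columns if c.startswith("ses_") and c != "ses_w1")
    base = ("naplan_z_w1", "sex", "age_w1") + ses_cols
    if engine_name in ("jm-1l-di-wide", "jm-2l-wide"):
        dep = tuple(c for c in data.columns if c.startswith("depression_w"))
        sdq = tuple(c for c in data.columns if c.startswith("sdq_w"))
        nap = tuple(
            c for c in data.columns
            if c.startswith("naplan_z_w") and c != "naplan_z_w1"
        )
        preds = sdq + nap + base
        if engine_name == "jm-1l-di-wide":
            if not di_cols:
                raise ValueError("jm-1l-di-wide requires dummy-indicator columns")
            return ImputationSpec(dep, preds + di_cols, None, "wide")
        return ImputationSpec(dep, preds, "school_id", "wide")
    if engine_name == "jm-2l-di":
        if not di_cols:
            raise ValueError("jm-2l-di requires dummy-indicator columns")
        preds = ("naplan_z", "sdq", "wave") + base + di_cols
        return ImputationSpec(("depression",), preds, "child_id", "long")
    raise ValueError(f"unknown JM engine {engine_name!r}; choose from {JM_ENGINES}")
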