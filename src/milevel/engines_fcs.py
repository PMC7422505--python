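"""Fully-conditional-specification (FCS, "chained equations") engines.

Missing values are imputed one variable at a time from a univariate
conditional model for each incomplete variable given all others:

* single-level: Bayesian normal linear regression — draw the residual
  variance from its scaled inverse-chi-square posterior, the coefficients
  from their conditional normal, then impute with residual noise (the
  classic "norm" step);
* two-/three-level: a univariate linear mixed model with random intercepts
  for the listed grouping factors, updated by a short Gibbs run (fixed
  effects, per-level random intercepts, inverse-gamma variance draws), and
  imputation from the conditional normal given the drawn parameters and
  random effects.

Each of the ``m`` imputations uses an independent, freshly initialized
chain run for ``cycles`` burn-in cycles (missing values start as random
draws from the observed margin).  Engine recipes:

=============== ======= ======================= =======================
engine          layout  school clustering       repeated-measures
=============== ======= ======================= =======================
fcs-1l-di-wide  wide    dummy indicators        wide-format columns
fcs-2l-wide     wide    random intercepts       wide-format columns
fcs-2l-di       long    dummy indicators        child random intercepts
fcs-3l          long    school random intercepts child random intercepts
=============== ======= ======================= =======================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import SparseClusterError, draw_inv_gamma
from .engines_jm import ImputedSet

__all__ = [
    "ConditionalModel",
    "impute_fcs",
    "build_default_models",
    "FCS_ENGINES",
]

FCS_ENGINES = ("fcs-1l-di-wide", "fcs-2l-wide", "fcs-2l-di", "fcs-3l")

# weakly informative inverse-gamma(0.001, 0.001) on every variance
_IG_A = 0.001
_IG_B = 0.001


@dataclass(frozen=True)
class ConditionalModel:
    """One univariate imputation model of the FCS cycle.

    ``random_intercepts`` holds grouping column names: empty for a
    single-level model, ``("school_id",)`` or ``("child_id",)`` for
    two-level, ``("school_id", "child_id")`` for three-level.
    """

    target: str
    predictors: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target in self.predictors:
            raise ValueError(f"target {self.target!r} cannot be a predictor")
        if len(self.random_intercepts) > 2:
            raise ValueError("at most two random-intercept levels supported")


class _LmmState:
    """Persistent Gibbs state of one univariate LMM across FCS cycles."""

    def __init__(self, n_levels: int, q: int):
        self.beta = np.zeros(q)
        self.sigma2_e = 1.0
        self.sigma2_u = [1.0] * n_levels
        self.u = None  # list of per-group intercept vectors


def _bayes_lm_draw(X, y, rng):
    """(beta, sigma) draw from the normal-regression posterior (flat prior
    on beta, Jeffreys on the variance)."""
    n, q = X.shape
    XtX = X.T @ X
    try:
        L = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as err:
        raise SparseClusterError(["<design>"]) from err
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    rss = float(np.sum((y - X @ beta_hat) ** 2))
    dof = max(n - q, 1)
    sigma2 = rss / rng.chisquare(dof)
    z = rng.standard_normal(q)
    # beta ~ N(beta_hat, sigma2 (X'X)^-1): solve L' w = z
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return beta, np.sqrt(sigma2)


def _gibbs_lmm_step(X, y, groups, state: _LmmState, rng, n_steps: int):
    """Advance the univariate LMM sampler on the observed-target rows.

    ``groups`` is a list of integer code arrays (one per random level,
    aligned with rows of X).  Group sizes may vary; groups absent from the
    observed rows keep prior-drawn intercepts at imputation time.
    """
    n, q = X.shape
    XtX = X.T @ X
    try:
        np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as err:
        raise SparseClusterError(["<design>"]) from err
    n_groups = [g.max() + 1 for g in groups]
    if state.u is None:
        state.u = [np.zeros(ng) for ng in n_groups]
    counts = [np.bincount(g, minlength=ng) for g, ng in zip(groups, n_groups)]

    for _ in range(n_steps):
        # fixed effects | random effects, sigma2_e
        offset = sum(state.u[l][groups[l]] for l in range(len(groups)))
        resid_y = y - offset
        beta_hat = np.linalg.solve(XtX, X.T @ resid_y)
        covL = np.linalg.cholesky(np.linalg.inv(XtX))
        state.beta = beta_hat + np.sqrt(state.sigma2_e) * covL @ rng.standard_normal(q)
        xb = X @ state.beta
        # each level's intercepts | rest
        for l, g in enumerate(groups):
            other = sum(state.u[j][groups[j]] for j in range(len(groups)) if j != l)
            r = y - xb - other
            rsum = np.bincount(g, weights=r, minlength=n_groups[l])
            prec = counts[l] / state.sigma2_e + 1.0 / state.sigma2_u[l]
            mean = rsum / state.sigma2_e / prec
            state.u[l] = mean + rng.standard_normal(n_groups[l]) / np.sqrt(prec)
            state.sigma2_u[l] = draw_inv_gamma(
                rng, _IG_A + 0.5 * n_groups[l], _IG_B + 0.5 * float(state.u[l] @ state.u[l])
            )
        # residual variance
        offset = sum(state.u[l][groups[l]] for l in range(len(groups)))
        rss = float(np.sum((y - xb - offset) ** 2))
        state.sigma2_e = draw_inv_gamma(rng, _IG_A + 0.5 * n, _IG_B + 0.5 * rss)
    return state


def _model_matrix(frame_cols, predictors):
    n = len(next(iter(frame_cols.values())))
    X = np.empty((n, len(predictors) + 1))
    X[:, 0] = 1.0
    for j, c in enumerate(predictors, start=1):
        X[:, j] = frame_cols[c]
    return X


def impute_fcs(
    data: pd.DataFrame,
    models: list[ConditionalModel],
    cycles: int = 10,
    m: int = 20,
    seed: int | None = None,
    gibbs_steps: int = 10,
) -> ImputedSet:
    """Run the FCS algorithm and return ``m`` completed datasets.

    Observed entries are preserved exactly; identical inputs and seed give
    identical output.  A dummy-indicator model whose cluster has no
    observed target values raises :class:`SparseClusterError` naming the
    offending columns.
    """
    targets = [mdl.target for mdl in models]
    if len(set(targets)) != len(targets):
        raise ValueError("one ConditionalModel per incomplete variable")
    for mdl in models:
        for c in (mdl.target, *mdl.predictors, *mdl.random_intercepts):
            if c not in data.columns:
                raise ValueError(f"column {c!r} not in data")
    other_incomplete = [
        c for c in data.columns
        if data[c].isna().any() and c not in targets and not c.startswith("r_")
    ]
    if other_incomplete:
        raise ValueError(f"incomplete variables without a model: {other_incomplete}")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(m)

    # numeric working copies
    cols = {c: data[c].to_numpy(dtype=float)
            for c in data.columns
            if np.issubdtype(np.asarray(data[c]).dtype, np.number)}
    mis = {t: np.isnan(cols[t]) for t in targets}
    group_codes: dict[str, np.ndarray] = {}
    for mdl in models:
        for gcol in mdl.random_intercepts:
            if gcol not in group_codes:
                group_codes[gcol], _ = pd.factorize(data[gcol], sort=True)

    # sparse-cluster screen: DI columns with no observed-target support
    for mdl in models:
        di = [p for p in mdl.predictors if "_di_" in p]
        if di:
            obs_rows = np.flatnonzero(~mis[mdl.target])
            Xdi = np.column_stack([cols[p] for p in di])
            bad = [p for j, p in enumerate(di) if Xdi[obs_rows, j].sum() == 0]
            if bad:
                raise SparseClusterError(bad)

    completed_sets = []
    for d in range(m):
        rng = np.random.default_rng(child_seeds[d])
        work = {c: v.copy() for c, v in cols.items()}
        for t in targets:
            rows = np.flatnonzero(mis[t])
            obs = cols[t][~mis[t]]
            if obs.size == 0:
                raise ValueError(f"target {t!r} has no observed values")
            if rows.size:
                work[t][rows] = rng.choice(obs, size=rows.size, replace=True)
        states = {mdl.target: _LmmState(len(mdl.random_intercepts),
                                        len(mdl.predictors) + 1)
                  for mdl in models if mdl.random_intercepts}

        for _cycle in range(cycles):
            for mdl in models:
                t = mdl.target
                mrows = np.flatnonzero(mis[t])
                orows = np.flatnonzero(~mis[t])
                X = _model_matrix(work, mdl.predictors)
                y = work[t]
                if not mdl.random_intercepts:
                    try:
                        beta, sigma = _bayes_lm_draw(X[orows], y[orows], rng)
                    except SparseClusterError:
                        raise SparseClusterError(
                            [p for p in mdl.predictors if "_di_" in p]
                            or list(mdl.predictors)
                        ) from None
                    if mrows.size:
                        work[t][mrows] = (
                            X[mrows] @ beta + sigma * rng.standard_normal(mrows.size)
                        )
                else:
                    groups_all = [group_codes[g] for g in mdl.random_intercepts]
                    groups_obs = [g[orows] for g in groups_all]
                    st = _gibbs_lmm_step(
                        X[orows], y[orows], groups_obs, states[t], rng, gibbs_steps
                    )
                    if mrows.size:
                        pred = X[mrows] @ st.beta
                        for l, g in enumerate(groups_all):
                            u = st.u[l]
                            gm = g[mrows]
                            # groups never observed draw fresh prior intercepts
                            extra = gm >= len(u)
                            u_full = np.concatenate([
                                u,
                                np.sqrt(st.sigma2_u[l])
                                * rng.standard_normal(max(gm.max() + 1 - len(u), 0)),
                            ]) if extra.any() else u
                            pred = pred + u_full[gm]
                        work[t][mrows] = pred + np.sqrt(st.sigma2_e) * (
                            rng.standard_normal(mrows.size)
                        )
        completed_sets.append({t: work[t].copy() for t in targets})

    datasets = []
    for filled in completed_sets:
        df = data.copy()
        for t, v in filled.items():
            df[t] = v
        datasets.append(df)
    return ImputedSet(datasets, "fcs", {"cycles": cycles, "gibbs_steps": gibbs_steps})


def build_default_models(engine_name: str, data: pd.DataFrame
                         ) -> list[ConditionalModel]:
    """Default conditional-model set for each FCS engine.

    ``data`` must already be in the engine's layout with SES dummies (and
    DI columns for the DI engines) appended.  Wide engines regress each
    incomplete exposure wave on the exposures at all other waves, the
    auxiliary and outcome at every wave, and the baseline covariates; long
    engines regress the exposure on the concurrent-row outcome, auxiliary
    and wave plus the baseline covariates.
    """
    di_cols = tuple(c for c in data.columns if "_di_" in c)
    ses_cols = tuple(c for c in data.columns if c.startswith("ses_") and c != "ses_w1")
    base = ("naplan_z_w1", "sex", "age_w1") + ses_cols

    if engine_name in ("fcs-1l-di-wide", "fcs-2l-wide"):
        dep = sorted(c for c in data.columns if c.startswith("depression_w"))
        sdq = tuple(sorted(c for c in data.columns if c.startswith("sdq_w")))
        nap = tuple(sorted(
            c for c in data.columns
            if c.startswith("naplan_z_w") and c != "naplan_z_w1"
        ))
        models = []
        for t in dep:  # ascending wave order
            others = tuple(c for c in dep if c != t)
            preds = others + sdq + nap + base
            if engine_name == "fcs-1l-di-wide":
                if not di_cols:
                    raise ValueError("fcs-1l-di-wide requires dummy-indicator columns")
                models.append(ConditionalModel(t, preds + di_cols, ()))
            else:
                models.append(ConditionalModel(t, preds, ("school_id",)))
        return models

    if engine_name in ("fcs-2l-di", "fcs-3l"):
        preds = ("naplan_z", "sdq", "wave") + base
        if engine_name == "fcs-2l-di":
            if not di_cols:
                raise ValueError("fcs-2l-di requires dummy-indicator columns")
            return [ConditionalModel("depression", preds + di_cols, ("child_id",))]
        return [ConditionalModel("depression", preds,
                                 ("school_id", "child_id"))]

    raise ValueError(f"unknown FCS engine {engine_name!r}; choose from {FCS_ENGINES}")
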