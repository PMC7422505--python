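"""Three-level random-intercept linear mixed model (the target analysis).

The substantive model for the outcome y (standardized academic score of
child j in school i at occasion k) is

    y_ijk = b0 + b1*depression_ij(k-1) + b2*wave_k + b3*baseline_ij
            + b4*sex_ij + sum_a b5a*I[SES_ij = a] + b6*age_ij
            + alpha_i + alpha_ij + eps_ijk

with independent normal random intercepts alpha_i ~ N(0, sigma2_l3) for
schools, alpha_ij ~ N(0, sigma2_l2) for children, and occasion residuals
eps_ijk ~ N(0, sigma2_l1).  The exposure coefficient b1 and the three
variance components are the parameters of interest.

Estimation is REML.  For nested random intercepts the per-school marginal
covariance is

    V_i = a I + b blockdiag_j(J_{k_ij}) + c J_{n_i}

(a, b, c) = (sigma2_l1, sigma2_l2, sigma2_l3), whose inverse and log
determinant have closed forms: the child-block part inverts blockwise,

    (a I + b J_k)^{-1} = (1/a)(I - b/(a + k b) J_k),

and the school term is a rank-one update handled by Sherman-Morrison.  All
quantities entering the REML criterion reduce to child-level sums, so one
criterion evaluation is O(N p^2) and the whole fit takes milliseconds even
at cohort scale.  The criterion is minimized over log-variances by
L-BFGS-B; variances driven to the boundary are returned as 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datagen import GeneratorParams, VarianceComponents

__all__ = [
    "FIXED_TERMS",
    "FitResult",
    "fit_three_level_lmm",
    "available_case_filter",
    "true_fixed_effects",
]

#: Fixed-effect terms of the analysis model, in design-matrix order.
FIXED_TERMS = [
    "intercept",
    "depression",
    "wave",
    "naplan_z_w1",
    "sex",
    "ses_2",
    "ses_3",
    "ses_4",
    "ses_5",
    "age_w1",
]

_MODEL_COLUMNS = [
    "naplan_z", "depression", "wave", "naplan_z_w1", "sex", "ses_w1", "age_w1",
]

_LOG_LB = np.log(1e-7)  # lower optimizer bound; below ~1e-5 treated as 0
_ZERO_TOL = 1e-5


def build_design(data: pd.DataFrame, terms: list[str] | None = None) -> np.ndarray:
    """Fixed-effect design matrix (SES as contrasts against quintile 1).

    ``terms`` restricts to a subset of :data:`FIXED_TERMS` (e.g.
    ``["intercept"]`` for a pure variance-decomposition fit).
    """
    use = FIXED_TERMS if terms is None else list(terms)
    unknown = set(use) - set(FIXED_TERMS)
    if unknown:
        raise ValueError(f"unknown terms {unknown}")
    n = len(data)
    cols = []
    for t in use:
        if t == "intercept":
            cols.append(np.ones(n))
        elif t.startswith("ses_"):
            cols.append((data["ses_w1"].to_numpy() == int(t[4:])).astype(float))
        else:
            cols.append(data[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def true_fixed_effects(params: GeneratorParams) -> pd.Series:
    """Generator coefficients arranged in analysis-model term order."""
    vals = [
        params.beta0, params.beta1, params.beta_wave, params.beta_baseline,
        params.beta_male, *params.beta_ses, params.beta_age,
    ]
    return pd.Series(vals, index=FIXED_TERMS)


@dataclass
class FitResult:
    """REML fit of the three-level model."""

    beta: pd.Series
    se: pd.Series
    sigma2_l1: float
    sigma2_l2: float
    sigma2_l3: float
    n_rows: int
    n_children: int
    n_clusters: int
    converged: bool
    loglik: float
    boundary: tuple[bool, bool, bool] = (False, False, False)
    cov_beta: np.ndarray = field(default=None, repr=False)

    @property
    def beta1(self) -> float:
        return float(self.beta["depression"])

    @property
    def se_beta1(self) -> float:
        return float(self.se["depression"])

    @property
    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(self.sigma2_l1, self.sigma2_l2, self.sigma2_l3)


class _NestedREML:
    """Precomputed sufficient statistics for the nested REML criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 school: np.ndarray, child: np.ndarray):
        order = np.lexsort((child, school))
        X, y, school, child = X[order], y[order], school[order], child[order]
        self.n, self.p = X.shape
        M = np.column_stack([X, y])

        # contiguous child blocks (children are nested within schools)
        _, child_starts, counts = np.unique(
            child, return_index=True, return_counts=True
        )
        child_starts = np.sort(child_starts)
        self.k = np.diff(np.append(child_starts, self.n)).astype(float)
        self.S = np.add.reduceat(M, child_starts, axis=0)  # child sums of [X y]
        self.MtM = M.T @ M

        school_of_child = school[child_starts]
        _, sc_starts = np.unique(school_of_child, return_index=True)
        self.sc_starts = np.sort(sc_starts)
        self.n_children = len(child_starts)
        self.n_schools = len(self.sc_starts)

    def profile(self, a: float, b: float, c: float):
        """M'V^{-1}M and log|V| at variance components (a, b, c)."""
        k, S = self.k, self.S
        denom = a + k * b                      # per child: a + k_j b
        w = 1.0 / denom
        coef = b / (a * denom)
        C = self.MtM / a - S.T @ (coef[:, None] * S)
        U = np.add.reduceat(w[:, None] * S, self.sc_starts, axis=0)
        s = np.add.reduceat(k * w, self.sc_starts)
        g = c / (1.0 + c * s)
        C -= U.T @ (g[:, None] * U)
        logdet = (
            float(np.sum((k - 1.0) * np.log(a)))
            + float(np.sum(np.log(denom)))
            + float(np.sum(np.log1p(c * s)))
        )
        return C, logdet

    def neg2_reml(self, theta: np.ndarray) -> float:
        a, b, c = np.exp(theta)
        C, logdet = self.profile(a, b, c)
        p = self.p
        XtVX, XtVy, ytVy = C[:p, :p], C[:p, p], C[p, p]
        try:
            L = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - XtVy @ beta
        logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(L))))
        return logdet + logdet_xtvx + max(quad, 0.0)

    def gls(self, a: float, b: float, c: float):
        C, logdet = self.profile(a, b, c)
        p = self.p
        XtVX, XtVy, ytVy = C[:p, :p], C[:p, p], C[p, p]
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy
        quad = float(ytVy - XtVy @ beta)
        sign, logdet_xtvx = np.linalg.slogdet(XtVX)
        neg2 = logdet + logdet_xtvx + quad + (self.n - p) * np.log(2.0 * np.pi)
        return beta, cov, -0.5 * neg2


def fit_three_level_lmm(
    data: pd.DataFrame,
    fixed_vc: VarianceComponents | tuple[float, float, float] | None = None,
    terms: list[str] | None = None,
) -> FitResult:
    """Fit the target model by REML (or GLS at fixed variance components).

    ``data`` is a long-layout table; rows with a missing exposure must be
    removed first (see :func:`available_case_filter`) — missing values in
    any model variable raise.  Passing ``fixed_vc`` skips the variance
    optimization and returns the GLS solution at those components;
    ``terms`` restricts the fixed-effect design (default: the full model).
    """
    check_cols = _MODEL_COLUMNS if terms is None else (
        ["naplan_z"] + [t for t in terms if t in data.columns]
    )
    missing = [c for c in check_cols if data[c].isna().any()]
    if missing:
        raise ValueError(
            f"missing values in model variables {missing}; apply an "
            "available-case filter or impute first"
        )
    school = data["school_id"].to_numpy()
    child = data["child_id"].to_numpy()
    if np.unique(school).size < 2:
        raise ValueError("need at least 2 school clusters")

    term_names = FIXED_TERMS if terms is None else list(terms)
    X = build_design(data, terms)
    y = data["naplan_z"].to_numpy(dtype=float)
    prob = _NestedREML(X, y, school, child)
    prob.term_names = term_names

    if fixed_vc is not None:
        if isinstance(fixed_vc, VarianceComponents):
            a, b, c = fixed_vc.as_tuple()
        else:
            a, b, c = fixed_vc
        beta, cov, ll = prob.gls(a, max(b, 0.0), max(c, 0.0))
        return _result(prob, beta, cov, ll, a, b, c, True, school, child)

    x_hat, converged = _optimize_reml(prob, y)
    a, b, c = np.exp(x_hat)
    boundary = (a <= _ZERO_TOL, b <= _ZERO_TOL, c <= _ZERO_TOL)
    b = 0.0 if boundary[1] else b
    c = 0.0 if boundary[2] else c
    beta, cov, ll = prob.gls(a, b, c)
    return _result(prob, beta, cov, ll, a, b, c, converged, school, child,
                   boundary)


def _fd_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty(x.size)
    for j in range(x.size):
        e = np.zeros(x.size)
        e[j] = h
        g[j] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def _optimize_reml(prob: _NestedREML, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Minimize the REML criterion over log-variances.

    L-BFGS-B with finite-difference gradients occasionally stalls on its
    first line search, so the solution is verified by a central-difference
    gradient check and polished by Nelder-Mead (then re-refined) whenever
    the check fails.  Boundary components are allowed to run to the lower
    bound and are zeroed by the caller.
    """
    bounds = [(_LOG_LB, 12.0)] * 3
    opts = {"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500}
    v0 = max(float(np.var(y)), 1e-4)
    starts = [np.log([0.6 * v0, 0.3 * v0, 0.1 * v0]),
              np.log([v0 / 3.0, v0 / 3.0, v0 / 3.0])]

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(prob.neg2_reml, x0, method="L-BFGS-B",
                       bounds=bounds, options=opts)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    def _grad_ok(x: np.ndarray) -> bool:
        interior = x > _LOG_LB + 1e-6
        g = _fd_grad(prob.neg2_reml, x)
        return bool(np.all(np.abs(g[interior]) < 0.5))

    if not _grad_ok(best_x):
        nm = minimize(prob.neg2_reml, best_x, method="Nelder-Mead",
                      options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000})
        if nm.fun < best_f:
            best_x, best_f = nm.x, nm.fun
        res = minimize(prob.neg2_reml, best_x, method="L-BFGS-B",
                       bounds=bounds, options=opts)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        best_x = np.clip(best_x, _LOG_LB, 12.0)
        return best_x, _grad_ok(best_x)
    return best_x, True


def _result(prob, beta, cov, ll, a, b, c, converged, school, child,
            boundary=(False, False, False)) -> FitResult:
    se = np.sqrt(np.diag(cov))
    names = getattr(prob, "term_names", FIXED_TERMS)
    return FitResult(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma2_l1=float(a),
        sigma2_l2=float(b),
        sigma2_l3=float(c),
        n_rows=prob.n,
        n_children=prob.n_children,
        n_clusters=prob.n_schools,
        converged=converged,
        loglik=float(ll),
        boundary=tuple(bool(x) for x in boundary),
        cov_beta=cov,
    )


def available_case_filter(data: pd.DataFrame) -> pd.DataFrame:
    """Drop the occasion rows whose exposure is missing (available-case
    analysis); a child's remaining occasions are retained."""
    keep = data["depression"].notna()
    out = data.loc[keep].drop(columns=["r_depression"], errors="ignore")
    return out.reset_index(drop=True)
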