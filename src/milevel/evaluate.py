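"""Simulation orchestration and performance evaluation.

:func:`run_scenario` reproduces one cell of the simulation grid: per
replication it generates a complete cohort, imposes missingness, applies
each requested method (an imputation engine followed by the three-level
analysis and Rubin pooling, the available-case comparator, or the
full-data reference), and aggregates the replication estimates of the
exposure coefficient and the three variance components into a tidy
performance table.

Performance measures (estimates q_r, truth q, R replications):

* bias           mean(q_r) - q
* pct_bias       100 * bias / q
* emp_se         SD of q_r (R-1 denominator)
* mod_se         mean of the per-replication standard errors
* coverage       fraction of 95% intervals containing q
* mcse_bias      emp_se / sqrt(R)
* mcse_coverage  sqrt(coverage * (1 - coverage) / R)

Method comparisons are paired: every method within a replication sees the
same generated dataset and the same missingness realization, and all
randomness descends deterministically from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import missingness as ms
from .analysis import FIXED_TERMS, available_case_filter, fit_three_level_lmm
from .datagen import (
    GeneratorParams,
    VarianceComponents,
    derive_variance_components,
    generate_complete,
    sample_cluster_plan,
)
from .engines_fcs import FCS_ENGINES, build_default_models, impute_fcs
from .engines_jm import (
    JM_ENGINES,
    MCMCSettings,
    build_jm_spec,
    impute_jm_single_level,
    impute_jm_two_level,
)
from .pooling import pool_variance_components, rubin_pool
from .reshape import add_dummy_indicators, add_ses_dummies, to_long, to_wide

__all__ = [
    "PerformanceMetrics",
    "ScenarioConfig",
    "compute_performance",
    "run_scenario",
    "apply_method",
    "ALL_METHODS",
]

logger = logging.getLogger(__name__)

_WIDE_ENGINES = ("jm-1l-di-wide", "fcs-1l-di-wide", "jm-2l-wide", "fcs-2l-wide")
_DI_ENGINES = ("jm-1l-di-wide", "fcs-1l-di-wide", "jm-2l-di", "fcs-2l-di")
ALL_METHODS = ("full", "aca") + JM_ENGINES + FCS_ENGINES

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class PerformanceMetrics:
    """Simulation performance of one method for one parameter."""

    bias: float
    pct_bias: float
    emp_se: float
    mod_se: float
    coverage: float
    mcse_bias: float
    mcse_coverage: float
    n_reps: int
    truth: float


def compute_performance(
    estimates: Sequence[float],
    ses: Sequence[float] | None,
    truth: float,
    ci_lower: Sequence[float] | None = None,
    ci_upper: Sequence[float] | None = None,
) -> PerformanceMetrics:
    """Aggregate per-replication estimates into performance measures.

    Coverage uses the supplied intervals when given (MI methods pool with a
    t reference, so their intervals are not plain normal ones); otherwise
    normal intervals ``est +/- 1.96 se`` are formed from ``ses``.  With no
    SEs at all (variance components) mod_se and coverage are NaN.
    """
    q = np.asarray(estimates, dtype=float)
    n = q.size
    if n < 2:
        raise ValueError("need at least 2 replications")
    bias = float(q.mean() - truth)
    pct = 100.0 * bias / truth if truth != 0 else np.nan
    emp_se = float(q.std(ddof=1))

    if ses is not None:
        s = np.asarray(ses, dtype=float)
        mod_se = float(s.mean())
    else:
        s, mod_se = None, np.nan

    if ci_lower is not None and ci_upper is not None:
        lo, hi = np.asarray(ci_lower, float), np.asarray(ci_upper, float)
        cov = float(np.mean((lo <= truth) & (truth <= hi)))
    elif s is not None:
        cov = float(np.mean((q - _Z975 * s <= truth) & (truth <= q + _Z975 * s)))
    else:
        cov = np.nan

    mcse_cov = float(np.sqrt(cov * (1 - cov) / n)) if np.isfinite(cov) else np.nan
    return PerformanceMetrics(
        bias=bias,
        pct_bias=pct,
        emp_se=emp_se,
        mod_se=mod_se,
        coverage=cov,
        mcse_bias=emp_se / np.sqrt(n),
        mcse_coverage=mcse_cov,
        n_reps=n,
        truth=truth,
    )


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid.

    Defaults follow the study conditions: 40 schools, 1200 children,
    exposure missingness only, m=20 imputations, 10 FCS cycles, JM chains
    with burn-in 1000 and 100 between-imputation iterations.
    """

    cluster_mode: str = "fixed"
    n_clusters: int = 40
    total_n: int = 1200
    size_range: tuple[int, int] = (8, 66)
    icc_l2: float = 0.5
    icc_l3: float = 0.15
    mechanism: str = "mcar"  # "none" | "mcar" | "mar"
    target_props: tuple[float, float, float] = (0.10, 0.15, 0.20)
    mar_inflate: bool = False
    methods: tuple[str, ...] = ("fcs-1l-di-wide",)
    m: int = 20
    fcs_cycles: int = 10
    fcs_gibbs_steps: int = 10
    jm_burn_in: int = 1000
    jm_between: int = 100
    params: GeneratorParams = field(default_factory=GeneratorParams)
    calibration_children: int = 34000

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {ALL_METHODS}")
        if self.mechanism not in ("none", "mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def variance_components(self) -> VarianceComponents:
        return derive_variance_components(self.icc_l2, self.icc_l3)


def _mar_config(config: ScenarioConfig, rng: np.random.Generator) -> ms.MissingnessConfig:
    """Calibrate per-occasion MAR intercepts on a large fresh sample."""
    n_child = config.calibration_children
    n_clust = config.n_clusters
    n_child -= n_child % n_clust
    plan = sample_cluster_plan("fixed", n_clust, n_child)
    calib = generate_complete(plan, config.params, config.variance_components, rng)
    return ms.calibrated_config(
        "mar",
        config.target_props,
        config.params.zeta1,
        config.params.zeta2,
        calibration_data=calib,
        inflate=config.mar_inflate,
    )


def apply_method(
    method: str,
    incomplete: pd.DataFrame,
    complete: pd.DataFrame,
    config: ScenarioConfig,
    rng_seed,
) -> dict:
    """Run one method on one replication; returns the beta1 estimate, its
    SE, the 95% interval and the (pooled) variance components."""
    if method == "full":
        fit = fit_three_level_lmm(complete)
        return _normal_ci_record(fit)
    if method == "aca":
        fit = fit_three_level_lmm(available_case_filter(incomplete))
        return _normal_ci_record(fit)

    if not isinstance(rng_seed, np.random.SeedSequence):
        rng_seed = np.random.SeedSequence(rng_seed)
    seed = int(rng_seed.generate_state(1)[0] % (2**31))
    if method in _WIDE_ENGINES:
        frame = to_wide(incomplete)
    else:
        frame = incomplete.copy()
    frame, _ = add_ses_dummies(frame)
    if method in _DI_ENGINES:
        frame, _ = add_dummy_indicators(frame, "school_id")

    if method in JM_ENGINES:
        spec = build_jm_spec(method, frame)
        mcmc = MCMCSettings(config.jm_burn_in, config.jm_between, config.m, seed)
        if method == "jm-1l-di-wide":
            imputed = impute_jm_single_level(frame, spec, mcmc)
        else:
            imputed = impute_jm_two_level(frame, spec, mcmc)
    else:
        models = build_default_models(method, frame)
        imputed = impute_fcs(
            frame,
            models,
            cycles=config.fcs_cycles,
            m=config.m,
            seed=seed,
            gibbs_steps=config.fcs_gibbs_steps,
        )

    est, var, vcs = [], [], []
    df_com = np.inf
    for d in imputed.datasets:
        long_d = to_long(d) if method in _WIDE_ENGINES else d
        fit = fit_three_level_lmm(long_d)
        est.append(fit.beta1)
        var.append(fit.se_beta1**2)
        vcs.append((fit.sigma2_l1, fit.sigma2_l2, fit.sigma2_l3))
        df_com = fit.n_rows - len(FIXED_TERMS)
    pooled = rubin_pool(est, var, df_com=df_com)
    s1, s2, s3 = pool_variance_components(vcs)
    return {
        "beta1": pooled.qbar,
        "se": pooled.se,
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "sigma2_l1": s1,
        "sigma2_l2": s2,
        "sigma2_l3": s3,
    }


def _normal_ci_record(fit) -> dict:
    return {
        "beta1": fit.beta1,
        "se": fit.se_beta1,
        "ci_low": fit.beta1 - _Z975 * fit.se_beta1,
        "ci_high": fit.beta1 + _Z975 * fit.se_beta1,
        "sigma2_l1": fit.sigma2_l1,
        "sigma2_l2": fit.sigma2_l2,
        "sigma2_l3": fit.sigma2_l3,
    }


def run_scenario(
    config: ScenarioConfig,
    n_reps: int,
    seed: int | None = None,
    return_raw: bool = False,
):
    """Run the scenario for ``n_reps`` replications.

    Returns a tidy performance table with one row per (method, parameter)
    and the performance-measure columns; with ``return_raw`` also returns
    the per-replication estimates for audit.  Identical master seed gives
    an identical table.  Per-method failures are logged and counted, never
    silently dropped; a replication failing for every method aborts.
    """
    ss = np.random.SeedSequence(seed)
    calib_ss, *rep_ss = ss.spawn(n_reps + 1)
    vc = config.variance_components

    mar_cfg = None
    if config.mechanism == "mar":
        mar_cfg = _mar_config(config, np.random.default_rng(calib_ss))

    records = []
    for rep in range(n_reps):
        gen_ss, miss_ss, *meth_ss = rep_ss[rep].spawn(2 + len(config.methods))
        gen_rng = np.random.default_rng(gen_ss)
        if config.cluster_mode == "fixed":
            plan = sample_cluster_plan("fixed", config.n_clusters, config.total_n)
        else:
            plan = sample_cluster_plan(
                "variable", config.n_clusters, config.total_n,
                config.size_range, gen_rng,
            )
        complete = generate_complete(plan, config.params, vc, gen_rng)
        if config.mechanism == "none":
            incomplete = complete
        elif config.mechanism == "mcar":
            incomplete = ms.impose_mcar(complete, config.target_props, miss_ss)
        else:
            incomplete = ms.impose_mar(complete, mar_cfg, miss_ss)

        n_ok = 0
        for method, m_ss in zip(config.methods, meth_ss):
            try:
                rec = apply_method(method, incomplete, complete, config, m_ss)
            except Exception:
                logger.exception("replication %d: method %s failed", rep, method)
                records.append({"rep": rep, "method": method, "ok": False})
                continue
            n_ok += 1
            records.append({"rep": rep, "method": method, "ok": True, **rec})
        if n_ok == 0:
            raise RuntimeError(f"replication {rep}: every method failed; aborting")

    raw = pd.DataFrame(records)
    rows = []
    truths = {
        "beta1": config.params.beta1,
        "sigma2_l1": vc.sigma2_l1,
        "sigma2_l2": vc.sigma2_l2,
        "sigma2_l3": vc.sigma2_l3,
    }
    for method in config.methods:
        sub = raw[(raw["method"] == method) & raw["ok"]]
        n_fail = int((raw["method"] == method).sum() - len(sub))
        for param, truth in truths.items():
            if param == "beta1":
                pm = compute_performance(
                    sub["beta1"], sub["se"], truth,
                    sub["ci_low"], sub["ci_high"],
                )
            else:
                pm = compute_performance(sub[param], None, truth)
            rows.append({
                "method": method,
                "parameter": param,
                "n_fail": n_fail,
                **pm.__dict__,
            })
    table = pd.DataFrame(rows)
    return (table, raw) if return_raw else table
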