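"""Synthetic three-level longitudinal data generator.

Emulates a school cohort study (children nested in schools, measured at
three paired exposure/outcome waves) in which a time-varying exposure
(depressive-symptom score, measured at waves 2, 4, 6) precedes a
time-varying outcome (standardized academic test z-score at waves 3, 5, 7),
with a time-varying auxiliary (a behaviour-problems questionnaire score at
waves 2, 4, 6) and time-fixed covariates (age, sex, a 5-level SES quintile
and a baseline academic z-score, all at wave 1).

Generation is sequential:

1. age ~ Uniform(a, b); sex ~ Bernoulli(prop male); SES quintile from
   cumulative probabilities.
2. Baseline academic z-score: linear regression on sex, age, SES.
3. Exposure at the three exposure waves: linear mixed model on age, sex,
   baseline score, SES and wave, with school- and child-level random
   intercepts.
4. Outcome at the three outcome waves: linear mixed model on the
   previous-wave exposure, wave, age, sex, baseline score and SES, with
   school- and child-level random intercepts whose variances are set by an
   intra-cluster-correlation (ICC) pair under a unit-total-variance
   constraint.
5. Auxiliary score: linear mixed model on the concurrent exposure and wave,
   with its own school- and child-level random intercepts.

The outcome model in step 4 is exactly the target analysis model fitted by
:mod:`milevel.analysis`, so every generator coefficient is a known truth
for the simulation study.

Wave coding: the three measurement occasions are coded 1, 2, 3 in all
models; the cohort-style wave labels (exposure waves 2/4/6, outcome waves
3/5/7) are kept only as column-name suffixes in wide layout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterPlan",
    "VarianceComponents",
    "GeneratorParams",
    "LONG_COLUMNS",
    "derive_variance_components",
    "sample_cluster_plan",
    "generate_complete",
]

#: Column order of the long-format complete-data table.
LONG_COLUMNS = [
    "school_id",
    "child_id",
    "wave",
    "age_w1",
    "sex",
    "ses_w1",
    "naplan_z_w1",
    "depression",
    "sdq",
    "naplan_z",
]

#: Cohort wave labels for the three occasions (metadata only).
EXPOSURE_WAVE_LABELS = (2, 4, 6)
OUTCOME_WAVE_LABELS = (3, 5, 7)


@dataclass(frozen=True)
class ClusterPlan:
    """Cluster (school) sizes for one simulated cohort.

    Attributes
    ----------
    n_clusters:
        Number of schools.
    sizes:
        Children per school; ``sum(sizes)`` equals the configured total.
    mode:
        ``"fixed"`` (all schools equal) or ``"variable"`` (truncated
        log-normal sizes rescaled to the total).
    size_range:
        Bounds for the variable mode (inclusive).
    """

    n_clusters: int
    sizes: tuple[int, ...]
    mode: Literal["fixed", "variable"]
    size_range: tuple[int, int] = (8, 66)

    def __post_init__(self) -> None:
        if len(self.sizes) != self.n_clusters:
            raise ValueError("len(sizes) must equal n_clusters")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("all cluster sizes must be positive")

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variance decomposition of the outcome model.

    ``sigma2_l1`` is the occasion-level residual variance, ``sigma2_l2``
    the child random-intercept variance and ``sigma2_l3`` the school
    random-intercept variance.  When derived from an ICC pair the three
    components sum to one.
    """

    sigma2_l1: float
    sigma2_l2: float
    sigma2_l3: float

    def __post_init__(self) -> None:
        for name in ("sigma2_l1", "sigma2_l2", "sigma2_l3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.sigma2_l1 + self.sigma2_l2 + self.sigma2_l3

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma2_l1, self.sigma2_l2, self.sigma2_l3)


def derive_variance_components(icc_l2: float, icc_l3: float) -> VarianceComponents:
    """Variance components implied by an ICC pair under unit total variance.

    The adopted ICC definitions are the correlations between observations
    sharing a level: level-3 ICC = sigma2_l3 / total (two children in one
    school), level-2 ICC = (sigma2_l2 + sigma2_l3) / total (two repeated
    measures of one child).  With total variance fixed at 1 this gives

        sigma2_l3 = icc_l3
        sigma2_l2 = icc_l2 - icc_l3
        sigma2_l1 = 1 - icc_l2
    """
    if not (0.0 <= icc_l3 <= 1.0 and 0.0 <= icc_l2 <= 1.0):
        raise ValueError("ICC values must lie in [0, 1]")
    if icc_l3 >= icc_l2:
        raise ValueError(
            "icc_l3 must be smaller than icc_l2: the level-2 ICC includes the "
            "school-level variance in its numerator, so icc_l3 >= icc_l2 would "
            f"imply a negative child-level variance (got icc_l2={icc_l2}, "
            f"icc_l3={icc_l3})"
        )
    return VarianceComponents(
        sigma2_l1=1.0 - icc_l2,
        sigma2_l2=icc_l2 - icc_l3,
        sigma2_l3=icc_l3,
    )


@dataclass
class GeneratorParams:
    """All coefficients and variances of the sequential generating models.

    The exposure effect ``beta1`` is the headline simulation truth.  The
    remaining defaults are chosen to be plausible for a school cohort in
    which the academic score is a z-score, the exposure score has a
    standard deviation near 1.8 on a 0-8 scale, and the auxiliary score a
    standard deviation near 4 on a 0-40 scale; every value can be
    overridden.
    """

    # step i-iii: time-fixed covariates
    age_bounds: tuple[float, float] = (8.0, 10.0)
    prop_female: float = 0.5
    ses_cum_probs: tuple[float, float, float, float] = (0.2, 0.4, 0.6, 0.8)

    # step iv: baseline academic z-score regression
    eta0: float = 0.0
    eta_male: float = -0.1
    eta_age: float = 0.05
    eta_ses: tuple[float, float, float, float] = (0.1, 0.2, 0.3, 0.4)
    sigma2_baseline: float = 0.9

    # step v: exposure (depressive symptoms) mixed model
    delta0: float = 2.5
    delta_age: float = -0.05
    delta_male: float = -0.2
    delta_baseline: float = -0.3
    delta_ses: tuple[float, float, float, float] = (-0.05, -0.1, -0.15, -0.2)
    delta_wave: float = 0.1
    sigma2_exp_l1: float = 2.0
    sigma2_exp_l2: float = 1.0
    sigma2_exp_l3: float = 0.1

    # step vi: outcome mixed model (the analysis-model truth)
    beta0: float = 0.0
    beta1: float = -0.025  # exposure effect: the target parameter
    beta_wave: float = 0.02
    beta_age: float = 0.02
    beta_male: float = -0.05
    beta_baseline: float = 0.6
    beta_ses: tuple[float, float, float, float] = (0.05, 0.1, 0.15, 0.2)

    # step vii: auxiliary (behaviour problems) mixed model
    gamma0: float = 6.0
    gamma_dep: float = 1.0
    gamma_wave: float = -0.1
    sigma2_aux_l1: float = 9.0
    sigma2_aux_l2: float = 4.0
    sigma2_aux_l3: float = 0.5

    # missingness selection model (used by milevel.missingness):
    # log-odds of being OBSERVED per unit of next-wave outcome / concurrent
    # auxiliary.  Chosen so one marginal SD of each predictor moves the
    # response odds by factors ~0.6 and ~1.3 respectively.
    zeta1: float = -0.43
    zeta2: float = 0.061

    def __post_init__(self) -> None:
        if not 0.0 < self.prop_female < 1.0:
            raise ValueError("prop_female must be in (0, 1)")
        cp = self.ses_cum_probs
        if not (0.0 < cp[0] < cp[1] < cp[2] < cp[3] < 1.0):
            raise ValueError("ses_cum_probs must be strictly increasing in (0, 1)")
        for name in (
            "sigma2_baseline",
            "sigma2_exp_l1",
            "sigma2_exp_l2",
            "sigma2_exp_l3",
            "sigma2_aux_l1",
            "sigma2_aux_l2",
            "sigma2_aux_l3",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def sample_cluster_plan(
    mode: Literal["fixed", "variable"],
    n_clusters: int,
    total_n: int,
    size_range: tuple[int, int] = (8, 66),
    rng_seed: int | np.random.Generator | None = None,
    lognorm_median: float = 27.0,
    lognorm_sdlog: float = 0.5,
) -> ClusterPlan:
    """Draw per-school cluster sizes summing exactly to ``total_n``.

    Fixed mode gives every school ``total_n / n_clusters`` children.
    Variable mode samples sizes from a log-normal truncated by rejection to
    ``size_range``, multiplies by ``total_n / sum(sizes)``, rounds, and then
    adds any deficit to (or removes any excess from) the last school.
    """
    if n_clusters < 1 or total_n < 1:
        raise ValueError("n_clusters and total_n must be positive")
    if mode == "fixed":
        if total_n % n_clusters:
            raise ValueError(
                f"fixed mode needs total_n divisible by n_clusters "
                f"({total_n} / {n_clusters})"
            )
        size = total_n // n_clusters
        return ClusterPlan(n_clusters, (size,) * n_clusters, "fixed", size_range)
    if mode != "variable":
        raise ValueError(f"unknown mode {mode!r}")

    lo, hi = size_range
    if lo > hi or n_clusters * lo > total_n or n_clusters * hi < total_n:
        raise ValueError(
            f"infeasible size range {size_range} for {n_clusters} clusters "
            f"and total {total_n}"
        )
    rng = np.random.default_rng(rng_seed)
    meanlog = np.log(lognorm_median)
    sizes = np.empty(n_clusters)
    for i in range(n_clusters):
        while True:  # rejection sampling onto [lo, hi]
            s = rng.lognormal(meanlog, lognorm_sdlog)
            if lo <= s <= hi:
                sizes[i] = s
                break
    scaled = np.rint(sizes * (total_n / sizes.sum())).astype(int)
    scaled = np.clip(scaled, 1, None)
    scaled[-1] += total_n - scaled.sum()  # deficit/excess to last cluster
    if scaled[-1] <= 0:
        raise ValueError("last-cluster adjustment produced a non-positive size")
    return ClusterPlan(n_clusters, tuple(int(s) for s in scaled), "variable", size_range)


def _ses_effect(ses: np.ndarray, coefs: Sequence[float]) -> np.ndarray:
    """Sum of quintile-indicator effects; quintile 1 is the reference."""
    out = np.zeros(ses.shape[0])
    for a, c in enumerate(coefs, start=2):
        out += c * (ses == a)
    return out


def generate_complete(
    plan: ClusterPlan,
    params: GeneratorParams | None = None,
    vc: VarianceComponents | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one complete cohort in long layout.

    Returns a DataFrame with one row per (school, child, occasion) and the
    columns of :data:`LONG_COLUMNS`: the exposure and auxiliary measured at
    the occasion's exposure wave, and the outcome at the following outcome
    wave.  Identical seed and configuration give an identical table.
    """
    params = params or GeneratorParams()
    vc = vc or derive_variance_components(0.5, 0.15)
    rng = np.random.default_rng(rng_seed)

    sizes = np.asarray(plan.sizes)
    n_children = int(sizes.sum())
    n_schools = plan.n_clusters
    school_of_child = np.repeat(np.arange(1, n_schools + 1), sizes)
    child_id = np.arange(1, n_children + 1)

    a, b = params.age_bounds
    age = rng.uniform(a, b, n_children)
    sex = (rng.random(n_children) >= params.prop_female).astype(int)  # 1 = male
    ses = 1 + np.searchsorted(np.asarray(params.ses_cum_probs), rng.random(n_children))

    baseline = (
        params.eta0
        + params.eta_male * sex
        + params.eta_age * age
        + _ses_effect(ses, params.eta_ses)
        + rng.normal(0.0, np.sqrt(params.sigma2_baseline), n_children)
    )

    # expand to long: 3 occasions per child, occasion index 1..3
    n_rows = n_children * 3
    wave = np.tile(np.array([1, 2, 3]), n_children)
    child_l = np.repeat(child_id, 3)
    school_l = np.repeat(school_of_child, 3)
    age_l = np.repeat(age, 3)
    sex_l = np.repeat(sex, 3)
    ses_l = np.repeat(ses, 3)
    base_l = np.repeat(baseline, 3)

    def _re(sig2_l3: float, sig2_l2: float, sig2_l1: float) -> np.ndarray:
        """School + child random intercepts plus occasion residual, in long."""
        u3 = rng.normal(0.0, np.sqrt(sig2_l3), n_schools)
        u2 = rng.normal(0.0, np.sqrt(sig2_l2), n_children)
        e1 = rng.normal(0.0, np.sqrt(sig2_l1), n_rows)
        return u3[school_l - 1] + u2[child_l - 1] + e1

    depression = (
        params.delta0
        + params.delta_age * age_l
        + params.delta_male * sex_l
        + params.delta_baseline * base_l
        + _ses_effect(ses_l, params.delta_ses)
        + params.delta_wave * wave
        + _re(params.sigma2_exp_l3, params.sigma2_exp_l2, params.sigma2_exp_l1)
    )

    naplan_z = (
        params.beta0
        + params.beta1 * depression
        + params.beta_wave * wave
        + params.beta_age * age_l
        + params.beta_male * sex_l
        + params.beta_baseline * base_l
        + _ses_effect(ses_l, params.beta_ses)
        + _re(vc.sigma2_l3, vc.sigma2_l2, vc.sigma2_l1)
    )

    sdq = (
        params.gamma0
        + params.gamma_dep * depression
        + params.gamma_wave * wave
        + _re(params.sigma2_aux_l3, params.sigma2_aux_l2, params.sigma2_aux_l1)
    )

    return pd.DataFrame(
        {
            "school_id": school_l,
            "child_id": child_l,
            "wave": wave,
            "age_w1": age_l,
            "sex": sex_l,
            "ses_w1": ses_l,
            "naplan_z_w1": base_l,
            "depression": depression,
            "sdq": sdq,
            "naplan_z": naplan_z,
        }
    )
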