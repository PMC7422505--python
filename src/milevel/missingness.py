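"""Impose MCAR and MAR missingness on the time-varying exposure.

Only the exposure (depression score at the three exposure waves) is ever
masked; the outcome, auxiliary and time-fixed covariates stay fully
observed.  Under MAR the probability of observing the exposure at an
occasion depends on the *subsequent-wave outcome* and the *concurrent
auxiliary* through a logistic selection model

    logit P(R = 1) = zeta0_k + zeta1 * outcome_k + zeta2 * auxiliary_k

(R = 1 observed, R = 0 missing; k indexes the occasion), so the mechanism
is missing-at-random by construction.  The per-occasion intercepts are
calibrated by bisection so the marginal missingness proportions hit their
targets; the "inflated" variant doubles (zeta1, zeta2) and recalibrates.

MCAR uses exact-count simple random sampling: with target proportion p and
N children, exactly round(p*N) exposures per occasion are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "MissingnessConfig",
    "impose_mcar",
    "impose_mar",
    "calibrate_mar_intercepts",
]


@dataclass(frozen=True)
class MissingnessConfig:
    """Mechanism and parameters of the exposure missingness model.

    ``target_props`` are the per-occasion missingness proportions, e.g.
    (0.10, 0.15, 0.20) for the low and (0.20, 0.30, 0.40) for the high
    scenario.  ``zeta0`` holds the calibrated per-occasion intercepts and is
    required before :func:`impose_mar` can run.  ``inflate`` doubles
    (zeta1, zeta2) — the strong-MAR variant.
    """

    mechanism: str  # "mcar" | "mar"
    target_props: tuple[float, float, float]
    zeta1: float = 0.0
    zeta2: float = 0.0
    zeta0: tuple[float, float, float] | None = None
    inflate: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if len(self.target_props) != 3:
            raise ValueError("target_props must have one entry per occasion")
        if any(not 0.0 <= p < 1.0 for p in self.target_props):
            raise ValueError("target proportions must lie in [0, 1)")

    @property
    def effective_zetas(self) -> tuple[float, float]:
        f = 2.0 if self.inflate else 1.0
        return (f * self.zeta1, f * self.zeta2)


def _as_incomplete(data: pd.DataFrame, observed: np.ndarray) -> pd.DataFrame:
    """Attach the response indicator and blank masked exposure entries."""
    out = data.copy()
    out["r_depression"] = observed.astype(int)
    out.loc[~observed, "depression"] = np.nan
    return out


def impose_mcar(
    data: pd.DataFrame,
    target_props: Sequence[float],
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mask exactly round(p*N) exposures per occasion, chosen by SRS.

    Adds an ``r_depression`` indicator column (1 observed, 0 missing) and
    sets masked ``depression`` entries to NaN.  All other entries are
    returned unchanged.
    """
    rng = np.random.default_rng(rng_seed)
    observed = np.ones(len(data), dtype=bool)
    waves = data["wave"].to_numpy()
    for w, p in zip((1, 2, 3), target_props):
        idx = np.flatnonzero(waves == w)
        n_mask = int(round(p * idx.size))
        if n_mask:
            masked = rng.choice(idx, size=n_mask, replace=False)
            observed[masked] = False
    return _as_incomplete(data, observed)


def _response_probability(
    data: pd.DataFrame, zeta0: Sequence[float], zeta1: float, zeta2: float
) -> np.ndarray:
    waves = data["wave"].to_numpy()
    z0 = np.asarray(zeta0)[waves - 1]
    lin = z0 + zeta1 * data["naplan_z"].to_numpy() + zeta2 * data["sdq"].to_numpy()
    return expit(lin)


def calibrate_mar_intercepts(
    data_source: Callable[[np.random.Generator], pd.DataFrame] | pd.DataFrame,
    zeta1: float,
    zeta2: float,
    target_props: Sequence[float],
    tol: float = 1e-3,
    rng_seed: int | np.random.Generator | None = None,
    bracket: tuple[float, float] = (-30.0, 30.0),
) -> tuple[float, float, float]:
    """Find per-occasion intercepts hitting the target missingness.

    ``data_source`` is either a large calibration dataset (long layout) or
    a callable ``rng -> DataFrame`` producing one; the Monte-Carlo mean of
    ``1 - expit(zeta0 + zeta1*outcome + zeta2*auxiliary)`` over that sample
    is driven to each occasion's target by bisection on zeta0 (the mean is
    strictly decreasing in zeta0, so the root is unique).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(rng_seed)
    sample = data_source(rng) if callable(data_source) else data_source

    waves = sample["wave"].to_numpy()
    base = (
        zeta1 * sample["naplan_z"].to_numpy() + zeta2 * sample["sdq"].to_numpy()
    )
    zeta0 = []
    for w, target in zip((1, 2, 3), target_props):
        lin = base[waves == w]
        if target == 0.0:
            zeta0.append(float(bracket[1]))
            continue

        def miss_rate(z0: float) -> float:
            return float(np.mean(1.0 - expit(z0 + lin)))

        lo, hi = bracket
        if not (miss_rate(hi) <= target <= miss_rate(lo)):
            raise ValueError(
                f"bisection bracket {bracket} does not contain the target "
                f"missingness {target} at occasion {w}: rate({lo})="
                f"{miss_rate(lo):.4f}, rate({hi})={miss_rate(hi):.4f}"
            )
        # bisection: miss_rate is strictly decreasing in z0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            r = miss_rate(mid)
            if abs(r - target) < tol and (hi - lo) < 1e-6:
                break
            if r > target:
                lo = mid
            else:
                hi = mid
        zeta0.append(0.5 * (lo + hi))
    return tuple(zeta0)


def calibrated_config(
    mechanism: str,
    target_props: Sequence[float],
    zeta1: float,
    zeta2: float,
    calibration_data: pd.DataFrame | None = None,
    inflate: bool = False,
    tol: float = 1e-3,
) -> MissingnessConfig:
    """Build a ready-to-use config, calibrating MAR intercepts if needed."""
    cfg = MissingnessConfig(
        mechanism=mechanism,
        target_props=tuple(target_props),
        zeta1=zeta1,
        zeta2=zeta2,
        inflate=inflate,
    )
    if mechanism == "mar":
        if calibration_data is None:
            raise ValueError("MAR calibration requires a calibration dataset")
        z1, z2 = cfg.effective_zetas
        zeta0 = calibrate_mar_intercepts(
            calibration_data, z1, z2, cfg.target_props, tol=tol
        )
        cfg = replace(cfg, zeta0=zeta0)
    return cfg


def impose_mar(
    data: pd.DataFrame,
    config: MissingnessConfig,
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mask exposures by independent Bernoulli draws from the MAR model.

    Requires calibrated intercepts in ``config.zeta0``.  Realized
    missingness proportions converge to the targets as N grows.
    """
    if config.zeta0 is None:
        raise ValueError("config.zeta0 not calibrated; run calibrate_mar_intercepts")
    rng = np.random.default_rng(rng_seed)
    z1, z2 = config.effective_zetas
    p_obs = _response_probability(data, config.zeta0, z1, z2)
    observed = rng.random(len(data)) < p_obs
    return _as_incomplete(data, observed)


def impose_missingness(
    data: pd.DataFrame,
    config: MissingnessConfig,
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dispatch on ``config.mechanism``."""
    if config.mechanism == "mcar":
        return impose_mcar(data, config.target_props, rng_seed)
    return impose_mar(data, config, rng_seed)
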