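import numpy as np
import pandas as pd
import pytest

import milevel as ml
from milevel.evaluate import ScenarioConfig, run_scenario


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Complete cohort: 10 schools x 12 children, high-high ICC."""
    plan = ml.sample_cluster_plan("fixed", 10, 120)
    vc = ml.derive_variance_components(0.5, 0.15)
    return ml.generate_complete(plan, ml.GeneratorParams(), vc, rng_seed=101)


@pytest.fixture(scope="session")
def small_incomplete(small_cohort) -> pd.DataFrame:
    return ml.impose_mcar(small_cohort, (0.10, 0.15, 0.20), rng_seed=202)


@pytest.fixture(scope="session")
def full_cohort() -> pd.DataFrame:
    """Study-sized cohort: 40 schools x 30 children."""
    plan = ml.sample_cluster_plan("fixed", 40, 1200)
    vc = ml.derive_variance_components(0.5, 0.15)
    return ml.generate_complete(plan, ml.GeneratorParams(), vc, rng_seed=303)


@pytest.fixture(scope="session")
def bivariate_toy():
    """Jointly normal (y1, y2), rho = 0.6, half of y2 missing at random."""
    rng = np.random.default_rng(42)
    n, rho = 600, 0.6
    y1 = rng.standard_normal(n)
    y2 = rho * y1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    df = pd.DataFrame({"y1": y1, "y2": y2})
    miss = rng.choice(n, size=n // 2, replace=False)
    obs = df.copy()
    obs.loc[miss, "y2"] = np.nan
    return df, obs, rho


@pytest.fixture(scope="session")
def mcar_mi_run():
    """200-replication MCAR scenario: FCS-1L-DI-wide, m=20, high-high ICC,
    low missingness — the headline nominal-coverage configuration."""
    cfg = ScenarioConfig(
        cluster_mode="fixed",
        icc_l2=0.5,
        icc_l3=0.15,
        mechanism="mcar",
        target_props=(0.10, 0.15, 0.20),
        methods=("fcs-1l-di-wide",),
        m=20,
        fcs_cycles=10,
    )
    return cfg, run_scenario(cfg, n_reps=200, seed=20200812)


@pytest.fixture(scope="session")
def strong_mar_aca_run():
    """200-replication strong-MAR scenario (doubled selection coefficients,
    20/30/40% missingness, low-low ICC) analysed by available cases."""
    cfg = ScenarioConfig(
        cluster_mode="fixed",
        icc_l2=0.2,
        icc_l3=0.05,
        mechanism="mar",
        mar_inflate=True,
        target_props=(0.20, 0.30, 0.40),
        methods=("aca",),
    )
    return cfg, run_scenario(cfg, n_reps=200, seed=20200813)


@pytest.fixture(scope="session")
def full_data_run():
    """200-replication no-missingness reference fit."""
    cfg = ScenarioConfig(
        cluster_mode="fixed",
        icc_l2=0.5,
        icc_l3=0.15,
        mechanism="none",
        methods=("full",),
    )
    return cfg, run_scenario(cfg, n_reps=200, seed=20200814)
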