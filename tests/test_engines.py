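import numpy as np
import pandas as pd
import pytest

import milevel as ml
from milevel import SparseClusterError
from milevel.engines_fcs import ConditionalModel
from milevel.engines_jm import ImputationSpec, MCMCSettings

SMALL_MCMC = MCMCSettings(burn_in=30, between=3, m=3, seed=7)


def _prepared(incomplete, engine):
    """Layout + dummy columns as the scenario runner prepares them."""
    wide = engine.endswith("wide")
    frame = ml.to_wide(incomplete) if wide else incomplete.copy()
    frame, _ = ml.add_ses_dummies(frame)
    if "di" in engine:
        frame, _ = ml.add_dummy_indicators(frame, "school_id")
    return frame


def _run_engine(engine, frame, seed=7):
    if engine in ml.JM_ENGINES:
        spec = ml.build_jm_spec(engine, frame)
        mcmc = MCMCSettings(burn_in=30, between=3, m=3, seed=seed)
        if engine == "jm-1l-di-wide":
            return ml.impute_jm_single_level(frame, spec, mcmc)
        return ml.impute_jm_two_level(frame, spec, mcmc)
    models = ml.build_default_models(engine, frame)
    return ml.impute_fcs(frame, models, cycles=3, m=3, seed=seed, gibbs_steps=5)


ALL_ENGINES = ml.JM_ENGINES + ml.FCS_ENGINES


class TestEngineContracts:
    @pytest.mark.parametrize("engine", ALL_ENGINES)
    def test_observed_preservation_and_completeness(self, small_incomplete, engine):
        frame = _prepared(small_incomplete, engine)
        imputed = _run_engine(engine, frame)
        assert imputed.m == 3
        targets = [c for c in frame.columns if frame[c].isna().any()]
        assert targets
        obs_mask = {t: frame[t].notna().to_numpy() for t in targets}
        for d in imputed.datasets:
            for t in targets:
                assert not d[t].isna().any()
                np.testing.assert_array_equal(
                    d.loc[obs_mask[t], t].to_numpy(),
                    frame.loc[obs_mask[t], t].to_numpy(),
                )
            other = [c for c in frame.columns if c not in targets]
            pd.testing.assert_frame_equal(d[other], frame[other])

    @pytest.mark.parametrize("engine", ALL_ENGINES)
    def test_seed_determinism(self, small_incomplete, engine):
        frame = _prepared(small_incomplete, engine)
        a = _run_engine(engine, frame, seed=11)
        b = _run_engine(engine, frame, seed=11)
        c = _run_engine(engine, frame, seed=12)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        changed = any(
            not da.equals(dc) for da, dc in zip(a.datasets, c.datasets)
        )
        assert changed

    @pytest.mark.parametrize("engine", ["jm-1l-di-wide", "fcs-1l-di-wide", "fcs-3l"])
    def test_no_missing_gives_identical_copies(self, small_cohort, engine):
        complete = small_cohort.copy()
        complete["r_depression"] = 1
        frame = _prepared(complete, engine)
        imputed = _run_engine(engine, frame)
        for d in imputed.datasets:
            pd.testing.assert_frame_equal(d, frame)


class TestConditionalMeanOracle:
    """On a bivariate normal with one variable half-missing MCAR, imputed
    values must scatter around the analytic conditional mean
    mu2 + rho*(sigma2/sigma1)*(y1 - mu1)."""

    def _check(self, imputed_sets, obs, rho):
        mask = obs["y2"].isna().to_numpy()
        cond_mean = rho * obs.loc[mask, "y1"].to_numpy()
        devs = [
            d.loc[mask, "y2"].to_numpy() - cond_mean for d in imputed_sets.datasets
        ]
        dev = np.concatenate(devs)
        # MC error of the mean deviation: sd ~ sqrt(1-rho^2 + param noise)
        assert abs(dev.mean()) < 4 * dev.std(ddof=1) / np.sqrt(dev.size)
        assert dev.std(ddof=1) == pytest.approx(np.sqrt(1 - rho**2), rel=0.15)

    def test_jm_single_level(self, bivariate_toy):
        _, obs, rho = bivariate_toy
        spec = ImputationSpec(("y2",), ("y1",))
        imputed = ml.impute_jm_single_level(
            obs, spec, MCMCSettings(burn_in=50, between=5, m=20, seed=3)
        )
        self._check(imputed, obs, rho)

    def test_fcs_single_level(self, bivariate_toy):
        _, obs, rho = bivariate_toy
        models = [ConditionalModel("y2", ("y1",))]
        imputed = ml.impute_fcs(obs, models, cycles=3, m=20, seed=4)
        self._check(imputed, obs, rho)

    def test_jm_fcs_distributional_equivalence(self, bivariate_toy):
        # single-level JM and FCS draw from the same posterior predictive
        _, obs, rho = bivariate_toy
        jm = ml.impute_jm_single_level(
            obs, ImputationSpec(("y2",), ("y1",)),
            MCMCSettings(burn_in=50, between=5, m=30, seed=5),
        )
        fcs = ml.impute_fcs(
            obs, [ConditionalModel("y2", ("y1",))], cycles=3, m=30, seed=6
        )
        means_jm = np.array([d["y2"].mean() for d in jm.datasets])
        means_fcs = np.array([d["y2"].mean() for d in fcs.datasets])
        mcse = np.sqrt(
            means_jm.var(ddof=1) / means_jm.size
            + means_fcs.var(ddof=1) / means_fcs.size
        )
        assert abs(means_jm.mean() - means_fcs.mean()) < 3 * mcse + 1e-3

    def test_between_variance_grows_with_missingness(self, bivariate_toy):
        full, _, rho = bivariate_toy
        rng = np.random.default_rng(9)
        spec = ImputationSpec(("y2",), ("y1",))
        B = {}
        for frac in (0.1, 0.4):
            obs = full.copy()
            miss = rng.choice(len(full), size=int(frac * len(full)), replace=False)
            obs.loc[miss, "y2"] = np.nan
            imputed = ml.impute_jm_single_level(
                obs, spec, MCMCSettings(burn_in=50, between=5, m=20, seed=10)
            )
            means = np.array([d["y2"].mean() for d in imputed.datasets])
            B[frac] = means.var(ddof=1)
        assert B[0.4] > B[0.1]


class TestTwoLevelJM:
    def test_icc_recovery(self):
        # two-level data with intercept ICC 0.3; the sampler's Psi/(Psi+Sigma)
        # should concentrate near the truth
        rng = np.random.default_rng(21)
        n_clust, per = 150, 8
        cl = np.repeat(np.arange(n_clust), per)
        x = rng.standard_normal(n_clust * per)
        y = 0.5 * x + rng.normal(0, np.sqrt(0.3), n_clust)[cl] + rng.normal(
            0, np.sqrt(0.7), n_clust * per
        )
        df = pd.DataFrame({"cl": cl, "x": x, "y": y})
        miss = rng.choice(len(df), size=len(df) // 5, replace=False)
        df.loc[miss, "y"] = np.nan
        spec = ImputationSpec(("y",), ("x",), cluster_var="cl")
        imputed = ml.impute_jm_two_level(
            df, spec, MCMCSettings(burn_in=300, between=20, m=5, seed=22)
        )
        cm = imputed.diagnostics["chain_mean"]
        icc = cm["psi_y"] / (cm["psi_y"] + cm["sigma_y"])
        assert icc == pytest.approx(0.3, abs=0.07)
        assert cm["psi_y"] > 0 and cm["sigma_y"] > 0

    def test_needs_cluster_var(self, bivariate_toy):
        _, obs, _ = bivariate_toy
        with pytest.raises(ValueError, match="cluster_var"):
            ml.impute_jm_two_level(
                obs, ImputationSpec(("y2",), ("y1",)), SMALL_MCMC
            )


class TestSparseClusters:
    @pytest.mark.parametrize("engine", ["fcs-1l-di-wide", "fcs-2l-di", "jm-1l-di-wide"])
    def test_cluster_without_observed_target_fails_informatively(
        self, small_cohort, engine
    ):
        d = small_cohort.copy()
        last = d["school_id"].max()
        d.loc[d["school_id"] == last, "depression"] = np.nan
        d["r_depression"] = d["depression"].notna().astype(int)
        frame = _prepared(d, engine)
        with pytest.raises(SparseClusterError) as exc:
            _run_engine(engine, frame)
        assert any(str(last) in c for c in exc.value.columns)


class TestDefaultModels:
    def test_fcs_1l_di_wide_has_all_di_predictors(self, small_incomplete):
        frame = _prepared(small_incomplete, "fcs-1l-di-wide")
        models = ml.build_default_models("fcs-1l-di-wide", frame)
        assert len(models) == 3
        for mdl in models:
            di = [p for p in mdl.predictors if "_di_" in p]
            assert len(di) == small_incomplete["school_id"].nunique() - 1
            assert mdl.random_intercepts == ()
            # other-wave exposures, all auxiliary and outcome waves present
            assert sum(p.startswith("depression_w") for p in mdl.predictors) == 2
            assert sum(p.startswith("sdq_w") for p in mdl.predictors) == 3

    def test_fcs_2l_wide_uses_school_random_effects(self, small_incomplete):
        frame = _prepared(small_incomplete, "fcs-2l-wide")
        models = ml.build_default_models("fcs-2l-wide", frame)
        for mdl in models:
            assert mdl.random_intercepts == ("school_id",)
            assert not any("_di_" in p for p in mdl.predictors)

    def test_fcs_3l_has_both_random_levels(self, small_incomplete):
        frame = _prepared(small_incomplete, "fcs-3l")
        (mdl,) = ml.build_default_models("fcs-3l", frame)
        assert mdl.random_intercepts == ("school_id", "child_id")
        assert mdl.target == "depression"

    def test_unknown_engine_rejected(self, small_incomplete):
        with pytest.raises(ValueError, match="unknown"):
            ml.build_default_models("fcs-9l", small_incomplete)
        with pytest.raises(ValueError, match="unknown"):
            ml.build_jm_spec("jm-9l", small_incomplete)

    def test_target_cannot_be_predictor(self):
        with pytest.raises(ValueError):
            ConditionalModel("y", ("y", "x"))


class TestFCSBehaviour:
    def test_cycle_count_invariance_single_target(self, bivariate_toy):
        # with one incomplete variable, FCS reduces to repeated Bayesian
        # regression draws: extra cycles do not shift the distribution
        _, obs, _ = bivariate_toy
        models = [ConditionalModel("y2", ("y1",))]
        one = ml.impute_fcs(obs, models, cycles=1, m=25, seed=13)
        five = ml.impute_fcs(obs, models, cycles=5, m=25, seed=14)
        m1 = np.array([d["y2"].mean() for d in one.datasets])
        m5 = np.array([d["y2"].mean() for d in five.datasets])
        mcse = np.sqrt(m1.var(ddof=1) / m1.size + m5.var(ddof=1) / m5.size)
        assert abs(m1.mean() - m5.mean()) < 3 * mcse + 1e-3

    def test_three_level_engine_school_variance(self):
        # imputations from the three-level engine reproduce between-school
        # variation in the exposure
        plan = ml.sample_cluster_plan("fixed", 30, 900)
        params = ml.GeneratorParams(sigma2_exp_l3=0.5)
        vc = ml.derive_variance_components(0.5, 0.15)
        d = ml.generate_complete(plan, params, vc, 61)
        inc = ml.impose_mcar(d, (0.3, 0.3, 0.3), 62)
        frame = _prepared(inc, "fcs-3l")
        models = ml.build_default_models("fcs-3l", frame)
        imputed = ml.impute_fcs(frame, models, cycles=8, m=5, seed=63)
        mask = frame["depression"].isna().to_numpy()
        school_vars = []
        for dd in imputed.datasets:
            imp = dd.loc[mask]
            centred = imp.groupby("school_id")["depression"].mean()
            school_vars.append(centred.var(ddof=1))
        assert np.mean(school_vars) > 0.1  # substantial school-level spread

    def test_mismatched_model_set_rejected(self, small_incomplete):
        frame = _prepared(small_incomplete, "fcs-3l")
        with pytest.raises(ValueError, match="without a model"):
            ml.impute_fcs(frame, [ConditionalModel("sdq", ("wave",))], m=2)
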