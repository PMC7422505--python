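import numpy as np
import pandas as pd
import pytest

import milevel as ml
from milevel.analysis import build_design, FIXED_TERMS


def _balanced_intercept_data(I=10, J=10, K=3, a=0.5, b=0.3, c=0.2, seed=5):
    """Pure variance-component data: y = school + child + noise."""
    rng = np.random.default_rng(seed)
    school = np.repeat(np.arange(I), J * K)
    child = np.repeat(np.arange(I * J), K)
    y = (
        rng.normal(0, np.sqrt(c), I)[school]
        + rng.normal(0, np.sqrt(b), I * J)[child]
        + rng.normal(0, np.sqrt(a), I * J * K)
    )
    return pd.DataFrame(
        {
            "school_id": school + 1,
            "child_id": child + 1,
            "wave": np.tile([1, 2, 3], I * J),
            "naplan_z": y,
        }
    )


def _nested_anova_components(d, K=3):
    """Method-of-moments estimators from the balanced nested ANOVA."""
    I = d["school_id"].nunique()
    J = d.groupby("school_id")["child_id"].nunique().iloc[0]
    child_means = d.groupby("child_id")["naplan_z"].mean()
    school_means = d.groupby("school_id")["naplan_z"].mean()
    grand = d["naplan_z"].mean()
    child_of = d.drop_duplicates("child_id").set_index("child_id")["school_id"]

    ss_e = ((d["naplan_z"] - child_means[d["child_id"]].to_numpy()) ** 2).sum()
    ms_e = ss_e / (I * J * (K - 1))
    ss_c = K * ((child_means - school_means[child_of].to_numpy()) ** 2).sum()
    ms_c = ss_c / (I * (J - 1))
    ss_s = J * K * ((school_means - grand) ** 2).sum()
    ms_s = ss_s / (I - 1)
    return ms_e, (ms_c - ms_e) / K, (ms_s - ms_c) / (J * K)


class TestREMLOracles:
    def test_matches_balanced_nested_anova(self):
        d = _balanced_intercept_data()
        mom = _nested_anova_components(d)
        assert min(mom) > 0  # interior solution required for equality
        fit = ml.fit_three_level_lmm(d, terms=["intercept"])
        est = (fit.sigma2_l1, fit.sigma2_l2, fit.sigma2_l3)
        for e, m in zip(est, mom):
            assert abs(e - m) / m < 1e-6

    def test_matches_dense_gls_at_fixed_components(self, small_cohort):
        d = small_cohort[small_cohort["school_id"] <= 5].reset_index(drop=True)
        a, b, c = 0.5, 0.3, 0.2
        X = build_design(d)
        y = d["naplan_z"].to_numpy()
        Zc = pd.get_dummies(d["child_id"]).to_numpy(dtype=float)
        Zs = pd.get_dummies(d["school_id"]).to_numpy(dtype=float)
        V = a * np.eye(len(d)) + b * Zc @ Zc.T + c * Zs @ Zs.T
        Vi = np.linalg.inv(V)
        cov = np.linalg.inv(X.T @ Vi @ X)
        beta = cov @ X.T @ Vi @ y

        fit = ml.fit_three_level_lmm(d, fixed_vc=(a, b, c))
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(
            fit.se.to_numpy(), np.sqrt(np.diag(cov)), atol=1e-8
        )

    def test_matches_statsmodels_mixedlm(self, small_incomplete):
        smf = pytest.importorskip("statsmodels.formula.api")
        aca = ml.available_case_filter(small_incomplete)
        fit = ml.fit_three_level_lmm(aca)
        m = smf.mixedlm(
            "naplan_z ~ depression + wave + naplan_z_w1 + sex + C(ses_w1) + age_w1",
            aca,
            groups="school_id",
            re_formula="1",
            vc_formula={"child": "0 + C(child_id)"},
        ).fit(reml=True)
        assert fit.beta1 == pytest.approx(m.params["depression"], abs=1e-6)
        assert fit.se_beta1 == pytest.approx(m.bse["depression"], rel=1e-2)
        assert fit.sigma2_l1 == pytest.approx(m.scale, rel=1e-2)
        assert fit.sigma2_l2 == pytest.approx(float(m.vcomp[0]), rel=1e-2)
        assert fit.sigma2_l3 == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-2)


class TestFitBehaviour:
    def test_invariant_to_relabeling_and_row_order(self, small_cohort):
        fit = ml.fit_three_level_lmm(small_cohort)
        perm = {s: t for s, t in zip(range(1, 11), [7, 3, 9, 1, 10, 5, 2, 8, 6, 4])}
        shuffled = small_cohort.copy()
        shuffled["school_id"] = shuffled["school_id"].map(perm)
        shuffled = shuffled.sample(frac=1.0, random_state=0)
        fit2 = ml.fit_three_level_lmm(shuffled)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert fit2.beta1 == pytest.approx(fit.beta1, abs=1e-8)

    def test_zero_school_variance_detected(self):
        plan = ml.sample_cluster_plan("fixed", 40, 1200)
        vc = ml.derive_variance_components(0.2, 0.0)
        d = ml.generate_complete(plan, None, vc, 55)
        fit = ml.fit_three_level_lmm(d)
        assert fit.sigma2_l3 < 0.01

    def test_se_shrinks_with_replication(self, small_cohort):
        fit1 = ml.fit_three_level_lmm(small_cohort)
        copies = []
        for i in range(4):
            c = small_cohort.copy()
            c["school_id"] = c["school_id"] + 100 * i
            c["child_id"] = c["child_id"] + 100000 * i
            copies.append(c)
        fit4 = ml.fit_three_level_lmm(pd.concat(copies, ignore_index=True))
        assert fit4.se_beta1 / fit1.se_beta1 == pytest.approx(0.5, abs=0.02)

    def test_missing_values_rejected(self, small_incomplete):
        with pytest.raises(ValueError, match="missing values"):
            ml.fit_three_level_lmm(small_incomplete)

    def test_needs_two_clusters(self, small_cohort):
        one = small_cohort[small_cohort["school_id"] == 1]
        with pytest.raises(ValueError, match="2 school clusters"):
            ml.fit_three_level_lmm(one)

    def test_design_terms(self, small_cohort):
        X = build_design(small_cohort)
        assert X.shape[1] == len(FIXED_TERMS)
        assert np.all(X[:, 0] == 1.0)
        sub = build_design(small_cohort, ["intercept", "depression"])
        assert sub.shape[1] == 2


class TestAvailableCaseFilter:
    def test_identity_without_missingness(self, small_cohort):
        pd.testing.assert_frame_equal(
            ml.available_case_filter(small_cohort), small_cohort
        )

    def test_exact_count_bookkeeping(self, full_cohort):
        inc = ml.impose_mcar(full_cohort, (0.10, 0.15, 0.20), 1)
        aca = ml.available_case_filter(inc)
        assert len(aca) == 3600 - (120 + 180 + 240)
        assert not aca["depression"].isna().any()

    def test_fully_missing_child_contributes_no_rows(self, small_cohort):
        d = small_cohort.copy()
        child = d["child_id"].iloc[0]
        d.loc[d["child_id"] == child, "depression"] = np.nan
        aca = ml.available_case_filter(d)
        assert child not in set(aca["child_id"])
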