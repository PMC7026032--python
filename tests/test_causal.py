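"""IV estimator correctness: Wald-ratio oracle, algebraic identities,
cross-check against an independent 2SLS implementation, invariances and
confounding behaviour."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from grsmr import (ModelSpec, MVMRRegressor, OLSRegressor, TSLSRegressor,
                   first_stage_f, fit_mvmr, fit_ols, fit_tsls,
                   sw_conditional_f)
from conftest import COVARIATES


def iv_dataset(rng, n=2000, beta=0.5, confound=0.0, covariates=False):
    g = rng.binomial(2, 0.3, n).astype(float)
    u = rng.standard_normal(n)
    x = 0.25 * g + confound * u + rng.standard_normal(n)
    y = beta * x + confound * u + rng.standard_normal(n)
    df = pd.DataFrame({"G": g, "X": x, "Y": y})
    if covariates:
        df["age"] = rng.uniform(40, 70, n)
        df["sex"] = rng.integers(0, 2, n).astype(float)
    return df


class TestWaldOracle:
    def test_tsls_equals_wald_ratio_exactly(self, wald_data):
        res = fit_tsls(ModelSpec("Y", ("X",), ("G",)), wald_data)
        assert res.term("X")["estimate"] == pytest.approx(1.0, abs=1e-10)

    def test_ols_differs(self, wald_data):
        res = fit_ols(ModelSpec("Y", ("X",)), wald_data)
        assert res.term("X")["estimate"] == pytest.approx(14 / 11, abs=1e-10)

    def test_wald_ratio_identity_random_data(self, rng):
        """Just-identified no-covariate TSLS equals cov(G,Y)/cov(G,X)."""
        for _ in range(5):
            df = iv_dataset(rng, n=150)
            res = fit_tsls(ModelSpec("Y", ("X",), ("G",)), df)
            wald = np.cov(df.G, df.Y)[0, 1] / np.cov(df.G, df.X)[0, 1]
            assert res.term("X")["estimate"] == pytest.approx(wald, abs=1e-10)

    def test_instrument_equal_to_exposure_reduces_to_ols(self, rng):
        df = iv_dataset(rng, n=300)
        df["Xcopy"] = df["X"]
        tsls = fit_tsls(ModelSpec("Y", ("X",), ("Xcopy",)), df)
        ols = fit_ols(ModelSpec("Y", ("X",)), df)
        assert tsls.term("X")["estimate"] == pytest.approx(
            ols.term("X")["estimate"], abs=1e-10)


class TestAgainstStatsmodels:
    def test_coefficients_and_ses_match_iv2sls(self, rng):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        df = iv_dataset(rng, n=800, confound=0.4, covariates=True)
        spec = ModelSpec("Y", ("X",), ("G",), ("age", "sex"), "tsls")
        res = fit_tsls(spec, df)
        Xf = np.column_stack([df.X, np.ones(len(df)), df.age, df.sex])
        Zf = np.column_stack([df.G, np.ones(len(df)), df.age, df.sex])
        ref = IV2SLS(df.Y.to_numpy(), Xf, instrument=Zf).fit()
        assert res.term("X")["estimate"] == pytest.approx(ref.params[0],
                                                          abs=1e-10)
        assert res.term("X")["se"] == pytest.approx(ref.bse[0], rel=1e-8)

    def test_ols_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        df = iv_dataset(rng, n=300, covariates=True)
        res = fit_ols(ModelSpec("Y", ("X",), covariates=("age", "sex")), df)
        ref = sm.OLS(df.Y, sm.add_constant(df[["X", "age", "sex"]])).fit()
        assert res.term("X")["estimate"] == pytest.approx(ref.params["X"],
                                                          abs=1e-12)
        assert res.term("X")["se"] == pytest.approx(ref.bse["X"], rel=1e-10)
        assert res.term("X")["p"] == pytest.approx(ref.pvalues["X"], rel=1e-8)


class TestDiagnostics:
    def test_single_instrument_f_equals_t_squared(self, rng):
        import statsmodels.api as sm

        df = iv_dataset(rng, n=400, covariates=True)
        spec = ModelSpec("X", ("X",), ("G",), ("age", "sex"), "tsls")
        f = first_stage_f(spec, df).iloc[0]
        fs = sm.OLS(df.X, sm.add_constant(df[["age", "sex", "G"]])).fit()
        assert f == pytest.approx(fs.tvalues["G"] ** 2, rel=1e-10)

    def test_conditional_f_reduces_to_standard_f_single_exposure(self, rng):
        df = iv_dataset(rng, n=400, covariates=True)
        spec = ModelSpec("Y", ("X",), ("G",), ("age", "sex"), "tsls")
        assert sw_conditional_f(spec, df).iloc[0] == pytest.approx(
            first_stage_f(spec, df).iloc[0], rel=1e-12)

    def test_null_instrument_f_near_one(self, rng):
        fs = []
        for _ in range(40):
            df = iv_dataset(rng, n=1500)
            df["G0"] = rng.binomial(2, 0.3, len(df)).astype(float)
            spec = ModelSpec("Y", ("X",), ("G0",), (), "tsls")
            fs.append(first_stage_f(spec, df).iloc[0])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.75)

    def test_conditional_f_vanishes_when_exposure_explained(self, rng):
        """If a second exposure fully explains the first, no residual
        instrument signal remains."""
        n = 3000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        x2 = 0.4 * g1 + 0.4 * g2 + rng.standard_normal(n)
        x1 = 2.0 * x2  # fully determined by x2
        y = x1 + rng.standard_normal(n)
        df = pd.DataFrame({"G1": g1, "G2": g2, "X1": x1, "X2": x2, "Y": y})
        spec = ModelSpec("Y", ("X1", "X2"), ("G1", "G2"), (), "mvmr")
        swf = sw_conditional_f(spec, df)
        assert swf["X1"] == pytest.approx(0.0, abs=1e-12)

    def test_conditional_near_standard_f_for_independent_blocks(self, rng):
        n = 50_000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        x1 = 0.2 * g1 + rng.standard_normal(n)
        x2 = 0.2 * g2 + rng.standard_normal(n)
        y = x1 - x2 + rng.standard_normal(n)
        df = pd.DataFrame({"G1": g1, "G2": g2, "X1": x1, "X2": x2, "Y": y})
        spec = ModelSpec("Y", ("X1", "X2"), ("G1", "G2"), (), "mvmr")
        swf = sw_conditional_f(spec, df)
        f = first_stage_f(spec, df)
        for k in ("X1", "X2"):
            assert swf[k] == pytest.approx(f[k], rel=0.1)


class TestInvariances:
    def test_row_permutation(self, rng):
        df = iv_dataset(rng, n=500, covariates=True)
        spec = ModelSpec("Y", ("X",), ("G",), ("age", "sex"), "tsls")
        r1 = fit_tsls(spec, df)
        r2 = fit_tsls(spec, df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(r1.table, r2.table, atol=1e-10,
                                      check_exact=False)

    def test_affine_rescaling(self, rng):
        df = iv_dataset(rng, n=500)
        spec = ModelSpec("Y", ("X",), ("G",), (), "tsls")
        base = fit_tsls(spec, df).term("X")["estimate"]
        # instrument rescaling leaves the estimate unchanged
        df2 = df.assign(G=5.0 * df.G - 3.0)
        assert fit_tsls(spec, df2).term("X")["estimate"] == pytest.approx(
            base, abs=1e-10)
        # exposure scaling divides, outcome scaling multiplies
        df3 = df.assign(X=2.0 * df.X)
        assert fit_tsls(spec, df3).term("X")["estimate"] == pytest.approx(
            base / 2.0, abs=1e-10)
        df4 = df.assign(Y=-3.0 * df.Y)
        assert fit_tsls(spec, df4).term("X")["estimate"] == pytest.approx(
            -3.0 * base, abs=1e-10)

    def test_ci_reproduces_normal_band(self, rng):
        df = iv_dataset(rng, n=400)
        res = fit_tsls(ModelSpec("Y", ("X",), ("G",)), df)
        t = res.term("X")
        z = 1.959963984540054
        assert t["ci_low"] == pytest.approx(t["estimate"] - z * t["se"])
        assert t["ci_high"] == pytest.approx(t["estimate"] + z * t["se"])


class TestModelBehaviour:
    def test_exact_fit_recovers_noiseless_slope(self):
        x = np.arange(30.0)
        df = pd.DataFrame({"X": x, "Y": 2.0 * x + 1.0})
        res = fit_ols(ModelSpec("Y", ("X",)), df)
        assert res.term("X")["estimate"] == pytest.approx(2.0, abs=1e-10)
        assert res.term("X")["se"] == pytest.approx(0.0, abs=1e-8)

    def test_confounded_ols_biased_tsls_not(self, clean_cohort):
        """With confounding on and pleiotropy off, the observational slope is
        pulled away from the causal one (by the confounder loading product)
        while TSLS stays centred."""
        _, data, _ = clean_cohort
        spec = ModelSpec("job_satisfaction", ("z_neuroticism",),
                         ("grs_neuroticism",), COVARIATES, "tsls")
        tsls = fit_tsls(spec, data).term("z_neuroticism")
        ols = fit_ols(spec, data).term("z_neuroticism")
        # OLS bias ~ +0.06 with tight SE; TSLS CI covers the truth
        assert ols["estimate"] > -0.29
        assert tsls["ci_low"] <= -0.31 <= tsls["ci_high"]

    def test_ols_tsls_agree_without_confounding(self, rng):
        df = iv_dataset(rng, n=20_000, beta=0.5, confound=0.0)
        spec = ModelSpec("Y", ("X",), ("G",), (), "tsls")
        t = fit_tsls(spec, df).term("X")
        o = fit_ols(spec, df).term("X")
        assert abs(t["estimate"] - o["estimate"]) < 3 * t["se"]

    def test_mvmr_matches_univariable_for_independent_exposures(self, rng):
        n = 30_000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        x1 = 0.3 * g1 + rng.standard_normal(n)
        x2 = 0.3 * g2 + rng.standard_normal(n)
        y = 0.5 * x1 - 0.2 * x2 + rng.standard_normal(n)
        df = pd.DataFrame({"G1": g1, "G2": g2, "X1": x1, "X2": x2, "Y": y})
        mv = fit_mvmr(ModelSpec("Y", ("X1", "X2"), ("G1", "G2"), (), "mvmr"),
                      df)
        for exp, g in (("X1", "G1"), ("X2", "G2")):
            uni = fit_tsls(ModelSpec("Y", (exp,), (g,), (), "tsls"), df)
            assert mv.term(exp)["estimate"] == pytest.approx(
                uni.term(exp)["estimate"], abs=3 * uni.term(exp)["se"])

    def test_own_and_all_modes_agree_without_cross_effects(self, rng):
        """When each instrument predicts only its own exposure, the two MVMR
        instrumenting modes estimate the same quantity."""
        n = 40_000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        x1 = 0.3 * g1 + rng.standard_normal(n)
        x2 = 0.3 * g2 + rng.standard_normal(n)
        y = 0.5 * x1 - 0.2 * x2 + rng.standard_normal(n)
        df = pd.DataFrame({"G1": g1, "G2": g2, "X1": x1, "X2": x2, "Y": y})
        own = fit_mvmr(ModelSpec("Y", ("X1", "X2"), ("G1", "G2"), (),
                                 "mvmr", mode="own"), df)
        al = fit_mvmr(ModelSpec("Y", ("X1", "X2"), ("G1", "G2"), (),
                                "mvmr", mode="all"), df)
        for exp in ("X1", "X2"):
            assert own.term(exp)["estimate"] == pytest.approx(
                al.term(exp)["estimate"], abs=2 * own.term(exp)["se"])


class TestValidationAndAPI:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("Y", ("X1", "X2"), ("G",), estimator="tsls")
        with pytest.raises(ValueError):
            ModelSpec("Y", ("X",), (), estimator="tsls")
        with pytest.raises(ValueError):
            ModelSpec("Y", ("X1", "X2"), ("G",), estimator="mvmr")
        with pytest.raises(ValueError):
            ModelSpec("Y", ("X",), ("G",), estimator="tsls", dof="bogus")

    def test_rank_deficiency_raises(self, rng):
        df = iv_dataset(rng, n=100)
        df["X2"] = df["X"]
        with pytest.raises(ValueError, match="rank"):
            fit_ols(ModelSpec("Y", ("X", "X2")), df)

    def test_zero_partial_instrument_variance_raises(self, rng):
        df = iv_dataset(rng, n=100, covariates=True)
        df["Gbad"] = 2.0 * df["age"] + 1.0
        with pytest.raises(ValueError, match="partial variance"):
            fit_tsls(ModelSpec("Y", ("X",), ("Gbad",), ("age", "sex"),
                               "tsls"), df)

    def test_sklearn_estimator_protocol(self, rng):
        df = iv_dataset(rng, n=300, covariates=True)
        est = TSLSRegressor(outcome="Y", exposure="X", instruments=("G",),
                            covariates=("age", "sex"))
        cloned = clone(est)
        assert cloned.get_params()["exposure"] == "X"
        est.fit(df)
        assert est.nobs_ == 300
        assert "X" in est.params_.index
        assert est.first_stage_f_.iloc[0] > 0
        est.set_params(dof="n").fit(df)
        pred = est.predict(df)
        assert len(pred) == 300

    def test_estimator_classes_match_wrappers(self, rng):
        df = iv_dataset(rng, n=400, covariates=True)
        r1 = OLSRegressor("Y", ("X",), ("age", "sex")).fit(df).params_["X"]
        r2 = fit_ols(ModelSpec("Y", ("X",), covariates=("age", "sex")),
                     df).term("X")["estimate"]
        assert r1 == pytest.approx(r2, abs=1e-12)
        m = MVMRRegressor("Y", ("X",), ("G",), ("age", "sex")).fit(df)
        assert hasattr(m, "conditional_f_")

    def test_missing_rows_dropped(self, rng):
        df = iv_dataset(rng, n=200)
        df.loc[:9, "Y"] = np.nan
        res = fit_tsls(ModelSpec("Y", ("X",), ("G",)), df)
        assert res.n == 190
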