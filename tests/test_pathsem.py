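import numpy as np
import pandas as pd
import pytest

from rwlr.errors import GraphError, IdentificationError, ParameterError
from rwlr.pathsem import PathFit, PathSpec, accept_model, fit_path_model, total_effects
from rwlr.synthetic import gen_czu_table

CHAIN = PathSpec.from_text("rwlr ~ br_ca\nnpp ~ rwlr + mat")


def std_slope(y, x):
    return float(np.corrcoef(x, y)[0, 1])


class TestPathSpec:
    def test_parse(self):
        assert CHAIN.endogenous == ["rwlr", "npp"]
        assert set(CHAIN.exogenous) == {"br_ca", "mat"}
        assert ("rwlr", "npp") in CHAIN.paths

    def test_cycle_rejected(self):
        with pytest.raises(GraphError):
            PathSpec.from_text("a ~ b\nb ~ a")

    def test_bad_line(self):
        with pytest.raises(GraphError):
            PathSpec.from_text("npp rwlr")


class TestFitPathModel:
    def test_saturated_model_chisq_zero(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.standard_normal(n)
        m = 0.8 * x + rng.standard_normal(n)
        y = 0.5 * m - 0.3 * x + rng.standard_normal(n)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(data, PathSpec.from_text("m ~ x\ny ~ m + x"))
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0
        assert fit.accepted
        assert any("zero df" in w for w in fit.warnings)

    def test_recovers_ground_truth_as_noise_vanishes(self):
        table = gen_czu_table(n=23, noise_sd=1e-9, seed=1)
        fit = fit_path_model(table.frame, CHAIN)
        by_path = {(r["source"], r["target"]): r["estimate"]
                   for r in fit.coef.to_dict("records")}
        assert by_path[("br_ca", "rwlr")] == pytest.approx(1.0, abs=1e-3)
        # npp is an exact function of rwlr and mat: standardized OLS equals
        # the sample-standardized truth
        f = table.frame
        b2 = table.betas["npp_rwlr"] * f["rwlr"].std(ddof=1) / f["npp"].std(ddof=1)
        b3 = table.betas["npp_mat"] * f["mat"].std(ddof=1) / f["npp"].std(ddof=1)
        assert by_path[("rwlr", "npp")] == pytest.approx(b2, abs=1e-3)
        assert by_path[("mat", "npp")] == pytest.approx(b3, abs=1e-3)
        assert fit.r2["npp"] == pytest.approx(1.0, abs=1e-6)

    def test_median_sign_pattern_recovery(self):
        signs = []
        for seed in range(100):
            table = gen_czu_table(n=23, noise_sd=1.0, seed=seed)
            fit = fit_path_model(table.frame, CHAIN)
            by_path = {(r["source"], r["target"]): r["estimate"]
                       for r in fit.coef.to_dict("records")}
            signs.append((np.sign(by_path[("br_ca", "rwlr")]),
                          np.sign(by_path[("rwlr", "npp")]),
                          np.sign(by_path[("mat", "npp")])))
        signs = np.array(signs)
        med = np.median(signs, axis=0)
        assert tuple(med) == (1.0, -1.0, 1.0)

    def test_joint_si_ca_model_refused(self):
        table = gen_czu_table(n=23, seed=3)
        bad = PathSpec.from_text("rwlr ~ br_ca + br_si\nnpp ~ rwlr")
        with pytest.raises(ParameterError, match="collinear"):
            fit_path_model(table.frame, bad)

    def test_missing_variable(self):
        table = gen_czu_table(n=23, seed=3)
        spec = PathSpec.from_text("rwlr ~ nope\nnpp ~ rwlr")
        with pytest.raises(GraphError):
            fit_path_model(table.frame, spec)

    def test_nan_data_rejected(self):
        table = gen_czu_table(n=23, seed=3).frame.copy()
        table.loc[0, "npp"] = np.nan
        with pytest.raises(IdentificationError):
            fit_path_model(table, CHAIN)

    def test_mirror_models_agree_on_npp_r2(self):
        # br_si is nearly -br_ca: the two single-element variants must
        # explain npp almost equally well
        table = gen_czu_table(n=23, noise_sd=0.5, seed=11)
        si = fit_path_model(table.frame,
                            PathSpec.from_text("rwlr ~ br_si\nnpp ~ rwlr + mat"))
        ca = fit_path_model(table.frame, CHAIN)
        assert abs(si.r2["npp"] - ca.r2["npp"]) < 0.05

    def test_rmsea_ci_ordering(self):
        table = gen_czu_table(n=23, noise_sd=1.0, seed=21)
        fit = fit_path_model(table.frame, CHAIN)
        lo, hi = fit.rmsea_ci90
        assert 0 <= lo <= hi
        assert lo <= fit.rmsea + 1e-12 <= hi + 1e-9 or fit.rmsea == 0.0


class TestTotalEffects:
    def make_fit(self, b, variables):
        return PathFit(spec=None, variables=variables,
                       coef=pd.DataFrame(), b_matrix=b, r2={}, n=0,
                       chisq=0.0, df=0, chisq_p=1.0, cfi=1.0,
                       rmsea=0.0, rmsea_ci90=(0.0, 0.0))

    def test_chain_product_rule(self):
        b = pd.DataFrame(0.0, index=["x", "m", "y"], columns=["x", "m", "y"])
        b.loc["m", "x"] = 0.8
        b.loc["y", "m"] = -0.5
        fit = self.make_fit(b, ["x", "m", "y"])
        eff = total_effects(fit, "y")
        assert eff["x"]["total"] == pytest.approx(-0.4)
        assert eff["x"]["direct"] == 0.0
        assert eff["x"]["indirect"] == pytest.approx(-0.4)

    def test_direct_only(self):
        b = pd.DataFrame(0.0, index=["x", "y"], columns=["x", "y"])
        b.loc["y", "x"] = 0.3
        eff = total_effects(self.make_fit(b, ["x", "y"]), "y")
        assert eff["x"] == {"direct": 0.3, "indirect": 0.0, "total": 0.3}

    def test_two_chains_plus_direct(self):
        names = ["x", "m1", "m2", "y"]
        b = pd.DataFrame(0.0, index=names, columns=names)
        b.loc["m1", "x"] = 0.4
        b.loc["y", "m1"] = 0.5    # chain 1: 0.2
        b.loc["m2", "x"] = 0.1
        b.loc["y", "m2"] = -0.5   # chain 2: -0.05
        b.loc["y", "x"] = 0.1     # direct
        eff = total_effects(self.make_fit(b, names), "y")
        assert eff["x"]["total"] == pytest.approx(0.25)
        assert eff["x"]["indirect"] == pytest.approx(0.15)

    def test_indirect_equals_chain_products_on_fitted_model(self):
        table = gen_czu_table(n=23, noise_sd=1.0, seed=31)
        fit = fit_path_model(table.frame, CHAIN)
        by_path = {(r["source"], r["target"]): r["estimate"]
                   for r in fit.coef.to_dict("records")}
        expected = by_path[("br_ca", "rwlr")] * by_path[("rwlr", "npp")]
        assert fit.total["br_ca"]["indirect"] == pytest.approx(expected, abs=1e-8)
        assert fit.total["br_ca"]["total"] == pytest.approx(
            fit.total["br_ca"]["direct"] + fit.total["br_ca"]["indirect"],
            abs=1e-12)

    def test_unknown_target(self):
        b = pd.DataFrame(0.0, index=["x", "y"], columns=["x", "y"])
        with pytest.raises(GraphError):
            total_effects(self.make_fit(b, ["x", "y"]), "zzz")


class TestMediationIdentity:
    def test_total_effect_equals_simple_slope_chain(self):
        # y is an exact function of m: the chain reproduces the simple slope
        rng = np.random.default_rng(41)
        x = rng.standard_normal(60)
        m = 0.7 * x + 0.4 * rng.standard_normal(60)
        y = -0.5 * m
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(data, PathSpec.from_text("m ~ x\ny ~ m"))
        assert fit.total["x"]["total"] == pytest.approx(
            std_slope(y, x), abs=1e-6)

    def test_total_effect_equals_simple_slope_saturated(self):
        # with the direct path included the identity holds for any data
        rng = np.random.default_rng(42)
        x = rng.standard_normal(40)
        m = 0.6 * x + rng.standard_normal(40)
        y = 0.5 * m - 0.2 * x + rng.standard_normal(40)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_path_model(data, PathSpec.from_text("m ~ x\ny ~ m + x"))
        assert fit.total["x"]["total"] == pytest.approx(
            std_slope(y, x), abs=1e-10)


class TestAcceptModel:
    def stub(self, chisq_p=0.30, cfi=0.97, rmsea_lo=0.0, df=2):
        return PathFit(spec=None, variables=[], coef=pd.DataFrame(),
                       b_matrix=pd.DataFrame(), r2={}, n=23, chisq=1.0,
                       df=df, chisq_p=chisq_p, cfi=cfi, rmsea=0.1,
                       rmsea_ci90=(rmsea_lo, 0.3))

    def test_all_criteria_met(self):
        ok, reasons = accept_model(self.stub())
        assert ok and reasons == []

    def test_cfi_failure_named(self):
        ok, reasons = accept_model(self.stub(cfi=0.85))
        assert not ok and reasons == ["CFI"]

    def test_multiple_failures(self):
        ok, reasons = accept_model(self.stub(chisq_p=0.01, cfi=0.5,
                                             rmsea_lo=0.2))
        assert not ok
        assert reasons == ["chisq_p", "CFI", "RMSEA_lower_CI"]

    def test_zero_df_accepted_with_warning(self):
        ok, reasons = accept_model(self.stub(df=0))
        assert ok and "zero df" in reasons[0]


class TestParameterRecovery:
    def test_bias_and_sign_recovery(self):
        # scaled-down version of the full acceptance sweep (50 seeds)
        truth = {"br_ca->rwlr": 0.90, "rwlr->npp": -0.6502, "mat->npp": 0.30}
        est = {k: [] for k in truth}
        for seed in range(50):
            table = gen_czu_table(n=23, noise_sd=1.0, seed=seed)
            fit = fit_path_model(table.frame, CHAIN)
            by_path = {f"{r['source']}->{r['target']}": r["estimate"]
                       for r in fit.coef.to_dict("records")}
            for k in truth:
                est[k].append(by_path[k])
        for k, target in truth.items():
            vals = np.array(est[k])
            assert abs(vals.mean() - target) < 0.06, k
            if abs(target) >= 0.4:
                assert np.mean(np.sign(vals) == np.sign(target)) >= 0.95, k
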