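"""Bootstrap mechanics, residual diagnostics and pcVPC calibration."""

import numpy as np
import pandas as pd
import pytest

from siropk import (
    CovariateEffect,
    ModelSpec,
    TDMDataset,
    bootstrap,
    bootstrap_bias,
    fit,
    gof_diagnostics,
    vpc,
)


@pytest.fixture(scope="module")
def fitted(small_cohort):
    spec = ModelSpec(covariates=(CovariateEffect("OXC"),))
    return fit(small_cohort, spec)


class TestBootstrap:
    def test_bias_formula(self):
        # the published bootstrap bias of the clearance fixed effect
        assert bootstrap_bias(8.58, 8.59) == pytest.approx(-0.1164, abs=1e-4)
        assert round(bootstrap_bias(8.58, 8.59), 2) == -0.12
        assert bootstrap_bias(10.0, 10.0) == 0.0

    def test_identity_resample_reproduces_fit(self, small_cohort, fitted):
        idx = np.arange(small_cohort.n_subjects)
        res = bootstrap(small_cohort, fitted.spec, fitted, seed=0, indices_list=[idx],
                        fit_kwargs={"polish_maxfev": 2500})
        assert res.n_converged == 1
        rep = res.replicates.iloc[0]
        for k, v in fitted.params.items():
            assert rep[k] == pytest.approx(v, rel=5e-3)

    def test_percentiles_ordered_and_reproducible(self, small_cohort, fitted):
        a = bootstrap(small_cohort, fitted.spec, fitted, n_reps=8, seed=3)
        b = bootstrap(small_cohort, fitted.spec, fitted, n_reps=8, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert (a.table["p2.5"] <= a.table["median"]).all()
        assert (a.table["median"] <= a.table["p97.5"]).all()


class TestGOF:
    def test_perfect_predictions_give_zero_residuals(self, small_cohort, fitted):
        # observations set to the typical predictions: the conditional
        # eta modes land on zero and every residual vanishes
        gof0 = gof_diagnostics(small_cohort, fitted)
        df = small_cohort.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = gof0["PRED"].to_numpy()
        gof = gof_diagnostics(TDMDataset(df), fitted)
        np.testing.assert_allclose(gof["IPRED"], gof["DV"], rtol=1e-6)
        np.testing.assert_allclose(gof["WRES"], 0.0, atol=1e-5)
        np.testing.assert_allclose(gof["IWRES"], 0.0, atol=1e-5)

    def test_constructed_outlier_flagged(self, small_cohort, fitted):
        gof0 = gof_diagnostics(small_cohort, fitted)
        df = small_cohort.df.copy()
        obs_idx = df.index[df["EVID"] == 0]
        sd = np.sqrt(fitted.params["sigma1"])
        clean = gof0["IPRED"].to_numpy()
        df.loc[obs_idx, "DV"] = clean
        df.loc[obs_idx[5], "DV"] = clean[5] + 10 * sd
        gof = gof_diagnostics(TDMDataset(df), fitted)
        big = gof["ABS_IWRES"] > 5
        assert big.sum() == 1
        assert gof.index[big][0] == 5

    def test_self_simulated_residuals_centered(self, small_cohort, fitted):
        # simulate from the fitted model at the observed design, refit the
        # diagnostics: weighted residuals should center on zero
        from siropk.estimation import _Compiled
        from siropk.pk_model import _ss_trough

        rng = np.random.default_rng(17)
        comp = _Compiled(small_cohort, fitted.spec)
        tvcl, tvv = comp.typical(fitted.params)
        sd = np.sqrt(fitted.params["sigma1"])
        om = np.sqrt(fitted.params["omega2_cl"])
        eta = rng.normal(0, om, size=comp.n_subjects)
        f = _ss_trough(comp.dose, comp.tau, (tvcl * np.exp(eta))[comp.subj_idx],
                       tvv[comp.subj_idx], comp.ka)
        dv = f + rng.normal(0, sd, size=f.shape)
        df = small_cohort.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = np.clip(dv, 0.05, None)
        gof = gof_diagnostics(TDMDataset(df), fitted)
        n = len(gof)
        assert abs(gof["WRES"].mean()) < 3 / np.sqrt(n) * gof["WRES"].std() + 0.15

    def test_zero_residual_variance_rejected(self, small_cohort, fitted):
        broken = fitted.__class__(**{**fitted.__dict__, "params": {**fitted.params, "sigma1": 0.0}})
        with pytest.raises(ValueError):
            gof_diagnostics(small_cohort, broken)


class TestVPC:
    def test_deterministic_under_seed(self, small_cohort, fitted):
        a = vpc(small_cohort, fitted, n_sim=100, seed=5)
        b = vpc(small_cohort, fitted, n_sim=100, seed=5)
        pd.testing.assert_frame_equal(a.bins, b.bins)
        assert a.coverage == b.coverage

    def test_self_simulated_coverage_near_nominal(self, small_cohort, fitted):
        res = vpc(small_cohort, fitted, n_sim=400, seed=9)
        # data were generated by the same model family the fit recovered:
        # the 95% band should cover 90-99% of observations (binomial slack)
        assert 0.90 <= res.coverage <= 0.995

    def test_degenerate_variance_collapses_band(self, small_cohort):
        spec = ModelSpec(covariates=(CovariateEffect("OXC"),))
        base = fit(small_cohort, spec)
        frozen = base.__class__(**{**base.__dict__,
                                   "params": {**base.params, "omega2_cl": 0.0, "sigma1": 1e-12}})
        res = vpc(small_cohort, frozen, n_sim=50, seed=2)
        np.testing.assert_allclose(res.bins["sim_p2.5"], res.bins["sim_p97.5"], rtol=1e-6)

    def test_percentile_ordering(self, small_cohort, fitted):
        res = vpc(small_cohort, fitted, n_sim=200, seed=13)
        assert (res.bins["sim_p2.5"] <= res.bins["sim_p50"]).all()
        assert (res.bins["sim_p50"] <= res.bins["sim_p97.5"]).all()
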