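"""Mixed-effects estimation: objective against brute-force quadrature,
fit behaviour, and the stepwise covariate screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from siropk import (
    CohortSpec,
    CovariateEffect,
    ModelSpec,
    TDMDataset,
    covariate_screen,
    fit,
    generate_cohort,
    objective_function,
)
from siropk.pk_model import FixedEffects, _ss_trough

TRUTH = {"theta_cl": 8.59, "theta_v": 294.0, "beta_OXC": 1.16,
         "omega2_cl": 0.175, "sigma1": 1.913}


def toy_dataset(obs_by_subject, weights=None, dose=2.0, tau=24.0):
    """Hand-built trough-only dataset: obs_by_subject is a list of DV lists."""
    rows = []
    for i, dvs in enumerate(obs_by_subject, start=1):
        w = (weights or {}).get(i, 20.0)
        rows.append({"ID": i, "TIME": 0.0, "EVID": 1, "AMT": dose, "II": tau,
                     "DV": np.nan, "MDV": 1, "WT": w, "OXC": 0})
        for k, dv in enumerate(dvs):
            rows.append({"ID": i, "TIME": 24.0 * (7 + k), "EVID": 0, "AMT": np.nan,
                         "II": np.nan, "DV": dv, "MDV": 0, "WT": w, "OXC": 0})
    return TDMDataset(pd.DataFrame(rows))


def quadrature_ofv(data, spec, params):
    """-2 log marginal likelihood by adaptive quadrature over eta (oracle).

    Independent of the Laplace implementation: direct numerical
    integration of the joint density subject by subject.
    """
    df = data.df
    fx = spec.fixed_template
    total = 0.0
    for sid, grp in df.groupby("ID"):
        doserow = grp[grp["EVID"] == 1].iloc[0]
        obs = grp[grp["EVID"] == 0]
        w = doserow["WT"]
        tvcl = params["theta_cl"] * (w / 70.0) ** 0.75 if spec.allometric_weight else params["theta_cl"]
        for c in spec.covariates:
            if c.kind == "categorical":
                tvcl *= params[f"beta_{c.name}"] ** doserow[c.name]
        tvv = params["theta_v"] * (w / 70.0) if spec.allometric_weight else params["theta_v"]
        om = np.sqrt(params["omega2_cl"])

        def integrand(eta):
            f = _ss_trough(doserow["AMT"], doserow["II"], tvcl * np.exp(eta), tvv, fx.ka_fixed)
            if spec.residual_kind == "additive":
                sd = np.sqrt(params["sigma1"])
            elif spec.residual_kind == "proportional":
                sd = np.sqrt(params["sigma1"]) * f
            else:
                sd = np.sqrt(params["sigma1"] * f**2 + params["sigma2"])
            lik = np.prod(stats.norm.pdf(obs["DV"], loc=f, scale=sd))
            return lik * stats.norm.pdf(eta, scale=om)

        val, _ = integrate.quad(integrand, -8 * om, 8 * om, limit=200, epsabs=1e-13, epsrel=1e-11)
        total += -2.0 * np.log(val)
    return total


class TestObjective:
    # small IIV keeps the model near-linear in eta, where the Laplace
    # approximation is essentially exact and any discrepancy against the
    # quadrature oracle is an implementation error
    TOY_PARAMS = {"theta_cl": 8.59, "theta_v": 294.0, "omega2_cl": 0.005, "sigma1": 1.0}

    @pytest.mark.parametrize("obs", [
        [[6.8]],                       # one subject, one trough
        [[6.8, 7.9]],                  # one subject, two troughs
        [[6.8], [5.1, 7.2], [8.8]],    # three subjects
    ])
    def test_matches_quadrature_oracle_additive(self, obs):
        data = toy_dataset(obs)
        spec = ModelSpec()
        ours = objective_function(data, spec, self.TOY_PARAMS)
        oracle = quadrature_ofv(data, spec, self.TOY_PARAMS)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_matches_quadrature_oracle_proportional(self):
        data = toy_dataset([[6.8, 7.9], [5.2]])
        spec = ModelSpec(residual_kind="proportional")
        params = {"theta_cl": 8.59, "theta_v": 294.0, "omega2_cl": 0.005, "sigma1": 0.01}
        assert objective_function(data, spec, params) == pytest.approx(
            quadrature_ofv(data, spec, params), rel=1e-4
        )

    def test_zero_omega_reduces_to_wls_deviance(self):
        data = toy_dataset([[6.8], [5.1, 7.2]])
        spec = ModelSpec()
        params = dict(self.TOY_PARAMS, omega2_cl=0.0)
        got = objective_function(data, spec, params)
        # fixed-effects weighted least-squares deviance, computed directly
        dev = 0.0
        for sid, grp in data.df.groupby("ID"):
            d = grp[grp["EVID"] == 1].iloc[0]
            w = d["WT"]
            f = _ss_trough(d["AMT"], d["II"], 8.59 * (w / 70) ** 0.75, 294.0 * w / 70, 0.485)
            for dv in grp.loc[grp["EVID"] == 0, "DV"]:
                dev += np.log(2 * np.pi * 1.0) + (dv - f) ** 2 / 1.0
        assert got == pytest.approx(dev, rel=1e-10)

    def test_duplicate_subject_doubles_ofv(self):
        one = toy_dataset([[6.8, 7.9]])
        two = toy_dataset([[6.8, 7.9], [6.8, 7.9]])
        spec = ModelSpec()
        assert objective_function(two, spec, self.TOY_PARAMS) == pytest.approx(
            2 * objective_function(one, spec, self.TOY_PARAMS), rel=1e-10
        )

    def test_invariant_to_subject_order(self):
        a = toy_dataset([[6.8], [5.1, 7.2], [8.8]], weights={1: 12.0, 2: 30.0, 3: 55.0})
        b = toy_dataset([[8.8], [5.1, 7.2], [6.8]], weights={1: 55.0, 2: 30.0, 3: 12.0})
        spec = ModelSpec()
        assert objective_function(a, spec, self.TOY_PARAMS) == pytest.approx(
            objective_function(b, spec, self.TOY_PARAMS), rel=1e-12
        )

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            objective_function(toy_dataset([[6.8]]), ModelSpec(), {"theta_cl": 8.59})


class TestFit:
    def test_descent_from_truth_init(self, recovery_cohort):
        spec = ModelSpec(covariates=(CovariateEffect("OXC"),))
        ofv_at_truth = objective_function(recovery_cohort, spec, TRUTH)
        res = fit(recovery_cohort, spec, init=TRUTH)
        assert res.ofv <= ofv_at_truth + 1e-6
        assert res.converged

    def test_recovers_truth_within_tolerance(self, recovery_cohort):
        spec = ModelSpec(covariates=(CovariateEffect("OXC"),))
        res = fit(recovery_cohort, spec)
        # single-replicate check; the multi-replicate median is tighter
        assert res.params["theta_cl"] == pytest.approx(8.59, rel=0.30)
        assert res.params["beta_OXC"] == pytest.approx(1.16, rel=0.15)
        assert res.params["sigma1"] == pytest.approx(1.913, rel=0.35)
        assert all(v >= 0 for v in res.se.values())

    def test_zero_generating_iiv_shrinks_omega(self):
        spec_cohort = CohortSpec(
            n_subjects=60, mean_samples_per_subject=3.0,
            truth_variability=__import__("siropk").VariabilityParams(omega_cl=0.0),
        )
        ds = generate_cohort(spec_cohort, seed=8)
        res = fit(ds, ModelSpec(covariates=(CovariateEffect("OXC"),)))
        # no between-subject signal: omega collapses toward the boundary
        assert res.params["omega2_cl"] < 0.1 * 0.175

    def test_empirical_bayes_etas_returned(self, recovery_cohort):
        res = fit(recovery_cohort, ModelSpec(covariates=(CovariateEffect("OXC"),)), init=TRUTH)
        assert len(res.eta) == recovery_cohort.n_subjects
        assert np.isfinite(res.eta["eta_cl"]).all()
        # EBEs center near zero under a well-specified model
        assert abs(res.eta["eta_cl"].mean()) < 0.15


class TestCovariateScreen:
    def test_empty_candidate_list_returns_base(self, small_cohort):
        base = ModelSpec()
        res = covariate_screen(small_cohort, base, [])
        assert res.spec == base
        assert len(res.log) == 0

    def test_strong_artificial_effect_selected_and_inert_rejected(self):
        # amplify the comedication effect so the screen's decision logic
        # (not its power at the study effect size) is what is tested
        truth = FixedEffects(theta_oxc=2.0)
        ds = generate_cohort(
            CohortSpec(n_subjects=100, mean_samples_per_subject=3.0,
                       oxc_prevalence=0.3, truth_fixed=truth), seed=21)
        res = covariate_screen(
            ds, ModelSpec(),
            [CovariateEffect("OXC"), CovariateEffect("SEX")],
        )
        names = [c.name for c in res.spec.covariates]
        assert names == ["OXC"]
        fwd = res.log[(res.log.stage == "forward") & (res.log.decision == "included")]
        assert list(fwd.candidate) == ["OXC"]

    def test_constant_candidate_skipped(self, small_cohort):
        df = small_cohort.df.copy()
        df["CONST"] = 1
        ds = TDMDataset(df)
        with pytest.warns(UserWarning, match="skipped"):
            res = covariate_screen(ds, ModelSpec(), [CovariateEffect("CONST")])
        assert "CONST" not in [c.name for c in res.spec.covariates]
        assert (res.log.decision == "skipped: constant or missing column").any()
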