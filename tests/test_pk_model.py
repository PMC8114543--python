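"""Structural/covariate model: covariate algebra, closed-form troughs vs
an independent ODE oracle, and the model's scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siropk import (
    DoseRegimen,
    FixedEffects,
    PatientCovariates,
    StructuralParams,
    concentration_time_profile,
    trough_at_steady_state,
    typical_clearance,
    typical_volume,
)
from siropk.pk_model import _ss_trough

from conftest import ode_multidose_conc

FX = FixedEffects()


class TestCovariateModel:
    @pytest.mark.parametrize(
        "weight,oxc,expected",
        [
            (70.0, 0, 8.59),  # reference weight, no comedication
            (70.0, 1, 8.59 * 1.16),  # = 9.9644
            (5.0, 0, 1.1868),  # 8.59 * (5/70)**0.75, log-arithmetic check
        ],
    )
    def test_typical_clearance(self, weight, oxc, expected):
        cov = PatientCovariates("s", weight=weight, oxc=oxc)
        assert typical_clearance(cov, FX) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("weight,expected", [(70.0, 294.0), (35.0, 147.0), (5.0, 21.0)])
    def test_typical_volume(self, weight, expected):
        assert typical_volume(PatientCovariates("s", weight=weight), FX) == pytest.approx(expected)

    def test_oxc_ratio_constant_in_weight(self):
        for w in (5, 11.5, 20.5, 43.2, 70):
            r = typical_clearance(PatientCovariates("s", w, 1), FX) / typical_clearance(
                PatientCovariates("s", w, 0), FX
            )
            assert r == pytest.approx(1.16, abs=1e-12)

    def test_clearance_monotone_but_sublinear_per_kg(self):
        w = np.linspace(5, 70, 40)
        cl = np.array([typical_clearance(PatientCovariates("s", wi), FX) for wi in w])
        assert np.all(np.diff(cl) > 0)  # increasing in weight
        assert np.all(np.diff(cl / w) < 0)  # mg/kg demand falls with weight

    @pytest.mark.parametrize("weight", [0.0, -3.0])
    def test_nonpositive_weight_rejected(self, weight):
        with pytest.raises(ValueError):
            PatientCovariates("s", weight=weight)


class TestSteadyStateTrough:
    def test_matches_ode_oracle_spot_values(self):
        p70 = StructuralParams(cl_f=8.59, v_f=294.0, ka=0.485)
        assert trough_at_steady_state(p70, 2.1, 24.0) == pytest.approx(
            ode_multidose_conc(8.59, 294.0, 0.485, 2.1, 24.0), rel=1e-6
        )
        assert trough_at_steady_state(p70, 2.1, 24.0) == pytest.approx(7.479, abs=5e-3)
        p5 = StructuralParams(cl_f=1.1868, v_f=21.0, ka=0.485)
        assert trough_at_steady_state(p5, 0.35, 24.0) == pytest.approx(6.55, abs=0.01)

    @pytest.mark.parametrize("tau", [12.0, 24.0])
    @pytest.mark.parametrize("weight", [5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
    def test_matches_ode_oracle_grid(self, weight, tau):
        cl = typical_clearance(PatientCovariates("s", weight), FX)
        v = typical_volume(PatientCovariates("s", weight), FX)
        dose = 0.05 * weight * tau / 24.0
        closed = trough_at_steady_state(StructuralParams(cl, v, FX.ka_fixed), dose, tau)
        oracle = ode_multidose_conc(cl, v, FX.ka_fixed, dose, tau)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_zero_dose(self):
        p = StructuralParams(8.59, 294.0, 0.485)
        assert trough_at_steady_state(p, 0.0, 24.0) == 0.0

    @given(dose=st.floats(0.05, 10.0), scale=st.floats(0.5, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_dose_linearity(self, dose, scale):
        p = StructuralParams(4.0, 150.0, 0.485)
        c1 = trough_at_steady_state(p, dose, 24.0)
        c2 = trough_at_steady_state(p, dose * scale, 24.0)
        assert c2 == pytest.approx(c1 * scale, rel=1e-12)

    def test_ka_ke_degenerate_limit_continuous(self):
        # approach the flip-flop point: values must converge to the limit form
        v, tau, dose = 100.0, 24.0, 1.0
        ka = 0.485
        exact_at = _ss_trough(dose, tau, ka * v, v, ka)  # cl/v == ka exactly
        near = _ss_trough(dose, tau, ka * v * (1 + 1e-7), v, ka)
        assert near == pytest.approx(exact_at, rel=1e-5)
        assert np.isfinite(exact_at) and exact_at > 0


class TestConcentrationProfile:
    P70 = StructuralParams(8.59, 294.0, 0.485)
    REG = DoseRegimen(dose_per_kg_per_day=0.03, interval=24.0, weight=70.0)

    def test_zero_at_dosing_instant(self):
        assert concentration_time_profile(self.P70, self.REG, [0.0])[0] == 0.0

    def test_converges_to_steady_state_trough(self):
        target = trough_at_steady_state(self.P70, self.REG.dose_mg, 24.0)
        c240 = concentration_time_profile(self.P70, self.REG, [240.0])[0]
        assert c240 == pytest.approx(target, rel=2e-3)
        c2400 = concentration_time_profile(self.P70, self.REG, [2400.0])[0]
        assert c2400 == pytest.approx(target, rel=1e-9)

    def test_profile_matches_ode_between_doses(self):
        t_off = [3.0, 8.0, 15.0]
        oracle = ode_multidose_conc(8.59, 294.0, 0.485, self.REG.dose_mg, 24.0,
                                    n_doses=10, t_offsets=t_off)
        # cap the profile at the 10 doses the oracle administered
        times = [24.0 * 10 + dt for dt in t_off]
        reg10 = DoseRegimen(0.03, 24.0, 70.0, n_doses=10)
        ours = concentration_time_profile(self.P70, reg10, times)
        np.testing.assert_allclose(ours, oracle, rtol=1e-6)

    def test_profile_linear_in_dose(self):
        t = [12.0, 36.0, 100.0]
        double = DoseRegimen(0.06, 24.0, 70.0)
        np.testing.assert_allclose(
            concentration_time_profile(self.P70, double, t),
            2 * concentration_time_profile(self.P70, self.REG, t), rtol=1e-12,
        )

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            concentration_time_profile(self.P70, self.REG, [10.0, 5.0])
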