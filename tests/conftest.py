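"""Shared fixtures and independent numerical oracles.

The ODE oracle integrates the two-state absorption/disposition system
dose interval by dose interval with tight tolerances; it shares no code
with the closed-form trough implementation it checks.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from siropk import CohortSpec, FixedEffects, ResidualErrorModel, VariabilityParams, generate_cohort


def ode_multidose_conc(cl, v, ka, dose_mg, tau, n_doses=60, t_offsets=None):
    """Concentration (ng/ml) just before each dose time via ODE integration.

    Returns the concentration at t = n_doses * tau (immediately before
    the next dose), or at arbitrary offsets after the last dose when
    ``t_offsets`` is given.
    """
    ke = cl / v

    def rhs(t, y):
        gut, central = y
        return [-ka * gut, ka * gut - ke * central]

    y = np.array([0.0, 0.0])
    for _ in range(n_doses):
        y[0] += dose_mg
        sol = solve_ivp(rhs, (0.0, tau), y, rtol=1e-11, atol=1e-14, dense_output=False)
        y = sol.y[:, -1]
    if t_offsets is None:
        return y[1] / v * 1000.0
    out = []
    for dt in t_offsets:
        sol = solve_ivp(rhs, (0.0, dt), y, rtol=1e-11, atol=1e-14) if dt > 0 else None
        out.append((sol.y[1, -1] if sol else y[1]) / v * 1000.0)
    return np.array(out)


@pytest.fixture(scope="session")
def final_fixed():
    return FixedEffects()


@pytest.fixture(scope="session")
def final_var():
    return VariabilityParams()


@pytest.fixture(scope="session")
def final_err():
    return ResidualErrorModel()


@pytest.fixture(scope="session")
def small_cohort():
    """80-subject study-sized cohort from the truth model."""
    return generate_cohort(CohortSpec(), seed=20210)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One 200-subject x ~4-trough cohort for estimation tests."""
    return generate_cohort(
        CohortSpec(n_subjects=200, mean_samples_per_subject=4.0, oxc_prevalence=0.29), seed=11
    )
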