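"""Structural and covariate pharmacokinetic model for sirolimus.

One-compartment disposition with first-order absorption and first-order
elimination, parameterized by apparent oral clearance CL/F (L/h), apparent
volume V/F (L) and a fixed absorption rate constant Ka (1/h).  Typical
parameters follow the final covariate model for pediatric tuberous
sclerosis complex patients:

    CL/F = theta_cl * (weight / 70)**0.75 * theta_oxc**OXC
    V/F  = theta_v  * (weight / 70)

where OXC is 1 for patients co-medicated with oxcarbazepine (a CYP3A4
inducer that accelerates sirolimus elimination) and 0 otherwise.

Units convention: dose mg, volume L, clearance L/h, time h, concentration
ng/ml (= ug/L).  The single mg/L -> ng/ml conversion lives in
:data:`MG_PER_L_TO_NG_PER_ML`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MG_PER_L_TO_NG_PER_ML",
    "PatientCovariates",
    "StructuralParams",
    "FixedEffects",
    "DoseRegimen",
    "typical_clearance",
    "typical_volume",
    "trough_at_steady_state",
    "concentration_time_profile",
]

#: Conversion factor from mg/L to ng/ml.  mg/L == ug/ml == 1000 ng/ml.
MG_PER_L_TO_NG_PER_ML = 1000.0

#: Relative |ka - ke| below which the flip-flop limiting form is used.
_KA_KE_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class PatientCovariates:
    """Covariate record for one subject.

    Only ``weight`` and ``oxc`` enter the final model; the remaining
    fields carry screening covariates (demographics, labs, comedication
    flags) for covariate selection.
    """

    subject_id: str | int
    weight: float
    oxc: int = 0
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight!r}")
        if self.oxc not in (0, 1):
            raise ValueError(f"oxc flag must be 0 or 1, got {self.oxc!r}")


@dataclass(frozen=True)
class StructuralParams:
    """Realized one-compartment parameters for a single individual."""

    cl_f: float  # L/h
    v_f: float  # L
    ka: float  # 1/h

    def __post_init__(self) -> None:
        for name in ("cl_f", "v_f", "ka"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl_f / self.v_f


@dataclass(frozen=True)
class FixedEffects:
    """Population fixed effects of the final covariate model.

    Defaults are the final-model point estimates: reference clearance
    8.59 L/h and volume 294 L at the 70 kg standard weight, an
    oxcarbazepine clearance multiplier of 1.16, allometric exponents
    0.75 (clearance) and 1 (volume), and Ka fixed at 0.485/h.
    """

    theta_cl: float = 8.59  # L/h at w_std
    theta_v: float = 294.0  # L at w_std
    theta_oxc: float = 1.16  # clearance multiplier under oxcarbazepine
    power_cl: float = 0.75
    power_v: float = 1.0
    w_std: float = 70.0  # kg
    ka_fixed: float = 0.485  # 1/h

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v", "theta_oxc", "w_std", "ka_fixed"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive, got {v!r}")

    def with_(self, **kwargs) -> "FixedEffects":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseRegimen:
    """Maintenance regimen expressed per kg of body weight.

    ``dose_per_kg_per_day`` is the total daily dose; a 12 h interval
    splits it evenly into two administrations.
    """

    dose_per_kg_per_day: float  # mg/kg/day
    interval: float  # h
    weight: float  # kg
    n_doses: int | None = None  # None => steady state

    def __post_init__(self) -> None:
        if self.dose_per_kg_per_day < 0:
            raise ValueError("dose must be non-negative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1 when given")

    @property
    def dose_mg(self) -> float:
        """Amount per administration (mg)."""
        n_per_day = 24.0 / self.interval
        return self.dose_per_kg_per_day * self.weight / n_per_day


def _tv_cl(weight, oxc, fx: FixedEffects):
    """Vector-friendly typical clearance (L/h)."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    return fx.theta_cl * (weight / fx.w_std) ** fx.power_cl * fx.theta_oxc ** np.asarray(oxc)


def _tv_v(weight, fx: FixedEffects):
    """Vector-friendly typical volume (L)."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    return fx.theta_v * (weight / fx.w_std) ** fx.power_v


def typical_clearance(cov: PatientCovariates, fx: FixedEffects = FixedEffects()) -> float:
    """Typical CL/F (L/h) for a subject under the covariate model."""
    return float(_tv_cl(cov.weight, cov.oxc, fx))


def typical_volume(cov: PatientCovariates, fx: FixedEffects = FixedEffects()) -> float:
    """Typical V/F (L) for a subject under the covariate model."""
    return float(_tv_v(cov.weight, fx))


def _ss_trough(dose_mg, tau, cl, v, ka):
    """Steady-state pre-dose concentration (ng/ml), vectorized.

    Closed form for repeated dosing every ``tau`` hours of a
    one-compartment model with first-order absorption, evaluated at
    t = tau after the last dose (i.e. immediately before the next):

        C_ss(tau) = (D ka) / (V (ka - ke)) *
                    [ e^{-ke tau}/(1-e^{-ke tau}) - e^{-ka tau}/(1-e^{-ka tau}) ]

    With the flip-flop degeneracy ka == ke the limit
    D k tau / V * r / (1-r)^2, r = e^{-k tau}, is used instead.
    """
    dose_mg, cl, v = np.broadcast_arrays(
        np.asarray(dose_mg, dtype=float), np.asarray(cl, dtype=float), np.asarray(v, dtype=float)
    )
    ke = cl / v

    def accum(k):
        r = np.exp(-k * tau)
        return r / (1.0 - r)

    with np.errstate(divide="ignore", invalid="ignore"):
        general = dose_mg * ka / (v * (ka - ke)) * (accum(ke) - accum(ka))
    degenerate = np.abs(ka - ke) < _KA_KE_DEGENERACY_RTOL * ka
    if np.any(degenerate):
        r = np.exp(-ke * tau)
        limit = dose_mg * ke * tau / v * r / (1.0 - r) ** 2
        general = np.where(degenerate, limit, general)
    return general * MG_PER_L_TO_NG_PER_ML


def trough_at_steady_state(p: StructuralParams, dose_mg: float, interval: float) -> float:
    """Steady-state trough concentration (ng/ml) for repeated oral dosing.

    Parameters
    ----------
    p
        Individual structural parameters.
    dose_mg
        Amount per administration (mg), >= 0.
    interval
        Dosing interval tau (h), > 0.
    """
    if dose_mg < 0:
        raise ValueError("dose_mg must be non-negative")
    if interval <= 0:
        raise ValueError("interval must be positive")
    return float(_ss_trough(dose_mg, interval, p.cl_f, p.v_f, p.ka))


def concentration_time_profile(
    p: StructuralParams, regimen: DoseRegimen, times: Sequence[float]
) -> np.ndarray:
    """Concentration (ng/ml) at ``times`` under repeated dosing from t = 0.

    Doses of ``regimen.dose_mg`` are administered at 0, tau, 2*tau, ...
    (capped at ``regimen.n_doses`` if finite).  The profile is the
    superposition of single-dose one-compartment curves, summed in closed
    form via partial geometric series; at t = k*tau for large k it
    converges to :func:`trough_at_steady_state`.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")

    tau = regimen.interval
    dose = regimen.dose_mg
    ka, ke, v = p.ka, p.ke, p.v_f
    if abs(ka - ke) < _KA_KE_DEGENERACY_RTOL * ka:
        raise NotImplementedError("flip-flop profile not implemented; perturb ka")

    # number of doses administered by time t (dose at t itself included:
    # it contributes exactly zero concentration at its own instant)
    n = np.floor(t / tau).astype(int) + 1
    if regimen.n_doses is not None:
        n = np.minimum(n, regimen.n_doses)
    s = t - (n - 1) * tau  # time since most recent administered dose

    def partial(k):
        r = np.exp(-k * tau)
        return np.exp(-k * s) * (1.0 - r**n) / (1.0 - r)

    conc = dose * ka / (v * (ka - ke)) * (partial(ke) - partial(ka))
    return conc * MG_PER_L_TO_NG_PER_ML
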