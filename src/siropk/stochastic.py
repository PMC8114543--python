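"""Random-effects and residual-error layer.

Inter-individual variability (IIV) is lognormal on clearance (and
optionally volume): CL_i = TV(CL) * exp(eta_i) with eta_i ~ N(0, omega^2).
Residual (within-subject) error on a predicted trough P comes in the
three usual flavours:

    additive      O = P + eps1
    proportional  O = P * (1 + eps1)
    combined      O = P * (1 + eps1) + eps2

with eps ~ N(0, sigma^2).  The final model carries a single eta on CL/F
and an additive residual error.

Scale convention
----------------
Reported variability magnitudes (omega, sigma) may be variances (the
NONMEM OMEGA/SIGMA reporting convention) or standard deviations.  Both
:class:`VariabilityParams` and :class:`ResidualErrorModel` carry an
explicit ``scale_convention`` declaring how their stored numbers are to
be read; all sampling goes through the ``*_sd`` accessors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .pk_model import FixedEffects, PatientCovariates, typical_clearance, typical_volume

__all__ = [
    "ScaleConvention",
    "VariabilityParams",
    "ResidualErrorModel",
    "IndividualParams",
    "sample_individual",
    "sample_etas",
    "apply_residual_error",
]

ScaleConvention = Literal["variance", "sd"]


def _to_sd(value: float, convention: str) -> float:
    if convention == "variance":
        return float(np.sqrt(value))
    if convention == "sd":
        return float(value)
    raise ValueError(f"unknown scale convention {convention!r}")


@dataclass(frozen=True)
class VariabilityParams:
    """IIV magnitudes.  ``omega_v`` is None in the final model (dropped
    because its estimate was indistinguishable from zero)."""

    omega_cl: float = 0.175
    omega_v: float | None = None
    scale_convention: ScaleConvention = "variance"

    def __post_init__(self) -> None:
        if self.omega_cl < 0:
            raise ValueError("omega_cl must be >= 0")
        if self.omega_v is not None and self.omega_v < 0:
            raise ValueError("omega_v must be >= 0 or None")
        _to_sd(0.0, self.scale_convention)  # validates the convention

    @property
    def sd_cl(self) -> float:
        return _to_sd(self.omega_cl, self.scale_convention)

    @property
    def sd_v(self) -> float:
        return 0.0 if self.omega_v is None else _to_sd(self.omega_v, self.scale_convention)


@dataclass(frozen=True)
class ResidualErrorModel:
    """Residual error specification (kind + magnitudes)."""

    kind: Literal["additive", "proportional", "combined"] = "additive"
    sigma1: float = 1.913
    sigma2: float | None = None
    scale_convention: ScaleConvention = "variance"

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual error kind {self.kind!r}")
        if self.sigma1 < 0:
            raise ValueError("sigma1 must be >= 0")
        if self.kind == "combined":
            if self.sigma2 is None or self.sigma2 < 0:
                raise ValueError("combined error requires sigma2 >= 0")
        elif self.sigma2 is not None:
            raise ValueError("sigma2 only applies to the combined error model")
        _to_sd(0.0, self.scale_convention)

    @property
    def sd1(self) -> float:
        return _to_sd(self.sigma1, self.scale_convention)

    @property
    def sd2(self) -> float:
        return 0.0 if self.sigma2 is None else _to_sd(self.sigma2, self.scale_convention)

    def observation_sd(self, pred) -> np.ndarray:
        """SD of an observation given its prediction, per the error law."""
        pred = np.asarray(pred, dtype=float)
        if self.kind == "additive":
            return np.broadcast_to(self.sd1, pred.shape).copy()
        if self.kind == "proportional":
            return self.sd1 * np.abs(pred)
        return np.sqrt(self.sd1**2 * pred**2 + self.sd2**2)


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realized parameters: typical values perturbed by eta."""

    eta_cl: float
    eta_v: float
    cl_f: float
    v_f: float


def sample_etas(n: int, var: VariabilityParams, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` eta_cl values ~ N(0, omega_cl^2) under the declared convention."""
    return rng.normal(0.0, var.sd_cl, size=n)


def sample_individual(
    cov: PatientCovariates,
    fx: FixedEffects,
    var: VariabilityParams,
    rng: np.random.Generator,
) -> IndividualParams:
    """Realize one individual's CL/F and V/F from the population model."""
    eta_cl = float(rng.normal(0.0, var.sd_cl))
    eta_v = float(rng.normal(0.0, var.sd_v)) if var.sd_v > 0 else 0.0
    return IndividualParams(
        eta_cl=eta_cl,
        eta_v=eta_v,
        cl_f=typical_clearance(cov, fx) * np.exp(eta_cl),
        v_f=typical_volume(cov, fx) * np.exp(eta_v),
    )


def apply_residual_error(pred, err: ResidualErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Turn predictions into observations by drawing residual error.

    Negative draws are *not* truncated here; callers decide their own
    policy (the cohort generator redraws, the PTA simulator counts them
    as out-of-window).
    """
    pred = np.asarray(pred, dtype=float)
    eps1 = rng.normal(0.0, 1.0, size=pred.shape)
    if err.kind == "additive":
        return pred + err.sd1 * eps1
    if err.kind == "proportional":
        return pred * (1.0 + err.sd1 * eps1)
    eps2 = rng.normal(0.0, 1.0, size=pred.shape)
    return pred * (1.0 + err.sd1 * eps1) + err.sd2 * eps2
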