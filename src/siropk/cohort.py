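"""Synthetic TDM cohort generation and NONMEM-style dataset I/O.

The generator emulates the published cohort's statistical structure: 80
pediatric tuberous-sclerosis patients, body weight right-skewed between
8 and 68 kg (mean 23.50, SD 11.71), 23/80 on oxcarbazepine, and on
average 2.35 trough samples per subject (188 in total).  Observed
troughs are steady-state trough concentrations under each subject's
realized clearance plus residual error, i.e. the cohort is drawn from
the final population model itself.

Demographics and laboratory covariates are generated with the published
summary statistics but are *inert* — they do not enter the truth model —
so covariate screening has true negatives to reject.

Datasets are carried as :class:`TDMDataset`, a thin validated wrapper
around a pandas DataFrame in NONMEM event-record dialect: one EVID=1
dose row per subject (AMT = amount per administration, II = interval)
followed by EVID=0 observation rows (DV = trough, MDV=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_model import FixedEffects, _ss_trough, _tv_cl, _tv_v
from .stochastic import ResidualErrorModel, VariabilityParams

__all__ = ["CohortSpec", "TDMDataset", "generate_cohort", "write_dataset", "read_dataset"]

#: Lower limit of the assay's linear response range (ng/ml); used for BLQ flagging.
ASSAY_LLOQ = 3.5

_REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "II", "DV", "MDV", "WT", "OXC"]

# (mean, sd, low, high) per Table-1-style laboratory covariate; all inert.
_LAB_COVARIATES = {
    "ALB": (43.00, 3.41, 36.0, 51.6),  # albumin g/L
    "ALT": (11.67, 9.13, 1.0, 50.0),  # alanine transaminase IU/L
    "AST": (28.35, 9.23, 9.0, 68.3),  # aspartate transaminase IU/L
    "SCR": (34.35, 10.81, 20.0, 89.0),  # creatinine umol/L
    "UREA": (4.53, 1.19, 2.0, 8.3),  # urea mmol/L
    "TP": (70.71, 5.81, 59.3, 80.5),  # total protein g/L
    "TBA": (4.03, 3.31, 0.05, 14.0),  # total bile acid umol/L
    "DBIL": (2.05, 0.78, 0.7, 4.0),  # direct bilirubin umol/L
    "TBIL": (5.54, 2.17, 2.1, 12.6),  # total bilirubin umol/L
    "HCT": (37.66, 3.75, 29.5, 49.4),  # hematocrit %
    "HGB": (125.96, 12.51, 96.0, 161.0),  # hemoglobin g/L
    "MCH": (27.20, 1.74, 23.1, 31.0),  # mean corpuscular hemoglobin pg
    "MCHC": (334.59, 11.44, 305.0, 370.0),  # MCH concentration g/L
}

# comedication prevalences (count / 80); OXC handled separately
_COMED_PREVALENCE = {
    "CBZ": 2 / 80,  # carbamazepine
    "LTG": 4 / 80,  # lamotrigine
    "LEV": 10 / 80,  # levetiracetam
    "TPM": 8 / 80,  # topiramate
    "VPA": 40 / 80,  # valproic acid
    "VGB": 12 / 80,  # vigabatrin
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the virtual cohort.

    Defaults match the published study population; ``truth_*`` hold the
    generating (true) population parameters, defaulting to the final
    model estimates.
    """

    n_subjects: int = 80
    weight_mean: float = 23.50  # kg
    weight_sd: float = 11.71  # kg
    weight_range: tuple[float, float] = (8.0, 68.0)
    oxc_prevalence: float = 23 / 80
    mean_samples_per_subject: float = 2.35  # 1 + Poisson(mean - 1)
    interval: float = 24.0  # h; study drug was taken once daily
    # per-subject daily dose chosen so the *typical* steady-state trough is
    # Uniform over this range (ng/ml) — administered doses are not published
    target_trough_range: tuple[float, float] = (4.0, 15.0)
    truth_fixed: FixedEffects = field(default_factory=FixedEffects)
    truth_variability: VariabilityParams = field(default_factory=VariabilityParams)
    truth_residual: ResidualErrorModel = field(default_factory=ResidualErrorModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.weight_range
        if not (0 < lo < hi):
            raise ValueError("weight_range must be 0 < low < high")
        if lo >= self.weight_mean + 4 * self.weight_sd or hi <= self.weight_mean - 4 * self.weight_sd:
            raise ValueError("weight truncation bounds infeasible for the stated moments")
        if not 0 <= self.oxc_prevalence <= 1:
            raise ValueError("oxc_prevalence must be in [0, 1]")
        if self.mean_samples_per_subject < 1:
            raise ValueError("mean_samples_per_subject must be >= 1")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


class TDMDataset:
    """Event-sorted dosing/observation records for one cohort.

    Wraps a DataFrame with NONMEM-style columns; invariants are enforced
    at construction:

    - times non-negative, sorted within subject (dose rows first at ties);
    - every observation row preceded by a dose row for that subject;
    - DV present (and positive) exactly on observation rows;
    - AMT present exactly on dose rows.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df.copy())

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) == 0:
            raise ValueError("empty dataset")
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if df["TIME"].lt(0).any():
            raise ValueError("negative TIME")
        if not df["EVID"].isin([0, 1]).all():
            raise ValueError("EVID must be 0 (observation) or 1 (dose)")
        dose = df["EVID"] == 1
        obs = ~dose
        bad_dv = dose & df["DV"].notna()
        if bad_dv.any():
            # +2: header line plus 1-based numbering, matching the CSV on disk
            rows = (df.index[bad_dv] + 2).tolist()
            raise ValueError(f"DV present on dose row(s) at line(s) {rows}")
        if df.loc[obs, "DV"].isna().any():
            raise ValueError("observation row without DV")
        if df.loc[obs, "DV"].le(0).any():
            raise ValueError("non-positive DV on observation row")
        if df.loc[dose, "AMT"].isna().any() or df.loc[dose, "AMT"].le(0).any():
            raise ValueError("dose row requires positive AMT")
        if not (df.loc[obs, "MDV"] == 0).all():
            raise ValueError("observation rows must have MDV=0")
        for sid, grp in df.groupby("ID", sort=False):
            if (np.diff(grp["TIME"].to_numpy()) < 0).any():
                raise ValueError(f"times not sorted within subject {sid}")
            first_dose = grp.index[grp["EVID"] == 1]
            first_obs = grp.index[grp["EVID"] == 0]
            if len(first_dose) == 0 and len(first_obs) > 0:
                raise ValueError(f"subject {sid} has observations but no dose history")
            if len(first_obs) > 0 and len(first_dose) > 0:
                t_dose = grp.loc[first_dose[0], "TIME"]
                if (grp.loc[first_obs, "TIME"] < t_dose).any():
                    raise ValueError(f"observation before first dose for subject {sid}")
        return df.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def subjects(self) -> pd.DataFrame:
        """One row per subject with its subject-level columns."""
        cols = [c for c in self.df.columns if c not in ("TIME", "EVID", "AMT", "II", "DV", "MDV", "BLQ")]
        return self.df.groupby("ID", sort=False)[cols].first().reset_index(drop=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TDMDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_exact=False, rtol=0, atol=1e-12)
            return True
        except AssertionError:
            return False

    def __repr__(self) -> str:
        return f"TDMDataset({self.n_subjects} subjects, {self.n_observations} observations)"


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _truncated_lognormal(rng, mean, sd, lo, hi, size):
    """Lognormal moment-matched to (mean, sd), rejection-truncated to [lo, hi]."""
    cv2 = (sd / mean) ** 2
    s2 = np.log1p(cv2)
    mu = np.log(mean) - s2 / 2
    out = rng.lognormal(mu, np.sqrt(s2), size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.lognormal(mu, np.sqrt(s2), size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int | np.random.Generator = 0) -> TDMDataset:
    """Draw one virtual cohort from the truth model.

    Reproducible bit-for-bit under a fixed integer seed.  Residual-error
    draws that would produce a non-positive trough are rejected and
    redrawn so every recorded concentration is positive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects
    fx, var, err = spec.truth_fixed, spec.truth_variability, spec.truth_residual

    weight = _truncated_lognormal(
        rng, spec.weight_mean, spec.weight_sd, *spec.weight_range, size=n
    )
    oxc = (rng.random(n) < spec.oxc_prevalence).astype(int)
    # age loosely tracks weight (both inert for the truth model)
    age = np.clip(weight / 3.6 + rng.normal(0, 1.5, n), 0.61, 16.61)
    sex = (rng.random(n) < 35 / 80).astype(int)  # 1 = boy
    form = (rng.random(n) < 0.5).astype(int)  # 0 = tablet, 1 = solution
    labs = {k: _truncated_normal(rng, *v, size=n) for k, v in _LAB_COVARIATES.items()}
    comeds = {k: (rng.random(n) < p).astype(int) for k, p in _COMED_PREVALENCE.items()}

    tvcl = _tv_cl(weight, oxc, fx)
    tvv = _tv_v(weight, fx)
    # dose policy: typical steady-state trough uniform over the target range
    trough_per_mg = _ss_trough(1.0, spec.interval, tvcl, tvv, fx.ka_fixed)
    target = rng.uniform(*spec.target_trough_range, size=n)
    dose_mg = target / trough_per_mg

    eta_cl = rng.normal(0.0, var.sd_cl, size=n)
    eta_v = rng.normal(0.0, var.sd_v, size=n) if var.sd_v > 0 else np.zeros(n)
    n_obs = 1 + rng.poisson(max(spec.mean_samples_per_subject - 1.0, 0.0), size=n)

    rows: list[dict] = []
    for i in range(n):
        ipred = float(
            _ss_trough(
                dose_mg[i], spec.interval, tvcl[i] * np.exp(eta_cl[i]), tvv[i] * np.exp(eta_v[i]), fx.ka_fixed
            )
        )
        base = {
            "ID": i + 1,
            "WT": round(float(weight[i]), 2),
            "OXC": int(oxc[i]),
            "AGE": round(float(age[i]), 2),
            "SEX": int(sex[i]),
            "FORM": int(form[i]),
            **{k: round(float(v[i]), 2) for k, v in labs.items()},
            **{k: int(v[i]) for k, v in comeds.items()},
        }
        rows.append(
            {**base, "TIME": 0.0, "EVID": 1, "AMT": float(dose_mg[i]), "II": spec.interval,
             "DV": np.nan, "MDV": 1, "BLQ": 0}
        )
        # steady-state troughs sampled on distinct later days
        days = np.sort(rng.choice(np.arange(7, 181), size=int(n_obs[i]), replace=False))
        for day in days:
            dv = -1.0
            while dv <= 0:
                dv = float(apply_err_scalar(ipred, err, rng))
            rows.append(
                {**base, "TIME": float(day) * 24.0, "EVID": 0, "AMT": np.nan, "II": np.nan,
                 "DV": dv, "MDV": 0, "BLQ": int(dv < ASSAY_LLOQ)}
            )

    order = ["ID", "TIME", "EVID", "AMT", "II", "DV", "MDV", "BLQ", "WT", "OXC", "AGE", "SEX",
             "FORM", *_LAB_COVARIATES, *_COMED_PREVALENCE]
    return TDMDataset(pd.DataFrame(rows)[order])


def apply_err_scalar(pred: float, err: ResidualErrorModel, rng: np.random.Generator) -> float:
    """One residual-error draw for a scalar prediction."""
    from .stochastic import apply_residual_error

    return float(apply_residual_error(np.array([pred]), err, rng)[0])


def write_dataset(ds: TDMDataset, path: str | Path) -> None:
    """Write a cohort as comma-separated NONMEM-dialect text with header."""
    ds.df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> TDMDataset:
    """Read and validate a cohort written by :func:`write_dataset`.

    Raises ``ValueError`` naming the offending line for malformed rows
    and for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty dataset file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty dataset file: {path}") from exc
    if len(df) == 0:
        raise ValueError(f"dataset file has a header but no rows: {path}")
    return TDMDataset(df)
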