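"""Model validation: nonparametric bootstrap, goodness-of-fit residual
diagnostics, and a prediction-corrected visual predictive check (pcVPC).

The bootstrap resamples *subjects* with replacement (the exchangeable
unit for longitudinal TDM data) and refits every replicate; reported
per parameter are the original estimate, the replicate median, the
2.5th/97.5th percentiles and the relative bias

    bias% = (median - estimate) / estimate * 100.

The pcVPC scales observed and simulated concentrations by the ratio of
the bin-median population prediction to each observation's own
population prediction, removing dose/covariate heterogeneity before
comparing percentiles.  Troughs carry no usable time axis (all are
steady-state pre-dose samples), so bins are weight quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TDMDataset
from .estimation import FitResult, ModelSpec, _Compiled, _inner_newton_1d, fit
from .pk_model import _ss_trough

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "bootstrap",
    "bootstrap_bias",
    "gof_diagnostics",
    "vpc",
]


def bootstrap_bias(median: float, estimate: float) -> float:
    """Relative bias (%) of a bootstrap median against the point estimate."""
    return (median - estimate) / estimate * 100.0


@dataclass
class BootstrapResult:
    table: pd.DataFrame  # parameter, estimate, median, p2.5, p97.5, bias_pct
    n_replicates: int
    n_converged: int
    replicates: pd.DataFrame  # one row per converged replicate
    failed: bool  # >50% non-convergence invalidates the exercise

    def __post_init__(self) -> None:
        bad = self.table["p2.5"] > self.table["p97.5"]
        if bad.any():
            raise ValueError("bootstrap percentiles out of order")


def _resample(data: TDMDataset, idx: np.ndarray) -> TDMDataset:
    """Dataset of the subjects in ``idx`` (with repetition), renumbered."""
    df = data.df
    blocks = {sid: grp for sid, grp in df.groupby("ID", sort=False)}
    ids = list(blocks)
    out = []
    for new_id, i in enumerate(idx, start=1):
        b = blocks[ids[i]].copy()
        b["ID"] = new_id
        out.append(b)
    return TDMDataset(pd.concat(out, ignore_index=True))


def bootstrap(
    data: TDMDataset,
    spec: ModelSpec,
    base_fit: FitResult,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    indices_list: list[np.ndarray] | None = None,
    fit_kwargs: dict | None = None,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the population fit.

    Replicates are refitted starting from the original estimates (the
    customary warm start).  ``indices_list`` overrides the random
    resampling with explicit subject index arrays, e.g. the identity
    permutation for a self-check.  Non-converged replicates are counted
    and excluded from the percentiles.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit_kwargs = {"maxiter": 100, "polish_maxfev": 800, **(fit_kwargs or {})}
    n_subj = data.n_subjects
    if indices_list is not None:
        n_reps = len(indices_list)
    rows = []
    n_converged = 0
    for r in range(n_reps):
        idx = (indices_list[r] if indices_list is not None
               else rng.integers(0, n_subj, size=n_subj))
        try:
            res = fit(_resample(data, np.asarray(idx)), spec, init=base_fit.params, **fit_kwargs)
        except Exception:
            continue
        if res.converged and np.isfinite(res.ofv):
            n_converged += 1
            rows.append({"replicate": r, **res.params})
    reps = pd.DataFrame(rows)
    failed = n_converged < n_reps / 2
    table_rows = []
    for name, est in base_fit.params.items():
        vals = reps[name].to_numpy() if name in reps else np.array([np.nan])
        table_rows.append({
            "parameter": name,
            "estimate": est,
            "median": float(np.nanmedian(vals)),
            "p2.5": float(np.nanpercentile(vals, 2.5)),
            "p97.5": float(np.nanpercentile(vals, 97.5)),
            "bias_pct": bootstrap_bias(float(np.nanmedian(vals)), est),
        })
    return BootstrapResult(
        table=pd.DataFrame(table_rows), n_replicates=n_reps,
        n_converged=n_converged, replicates=reps, failed=failed,
    )


def _predictions(data: TDMDataset, fitres: FitResult):
    """Per-observation population and individual predictions."""
    comp = _Compiled(data, fitres.spec)
    params = fitres.params
    tvcl, tvv = comp.typical(params)
    pred = _ss_trough(comp.dose, comp.tau, tvcl[comp.subj_idx], tvv[comp.subj_idx], comp.ka)
    # conditional (empirical-Bayes) modes on the supplied data
    if set(fitres.spec.eta_on) == {"cl"} and params.get("omega2_cl", 0) > 1e-12:
        eta, _, _ = _inner_newton_1d(comp, params, "cl", None)
    else:
        eta = np.zeros(comp.n_subjects)
    ipred = _ss_trough(
        comp.dose, comp.tau, (tvcl * np.exp(eta))[comp.subj_idx], tvv[comp.subj_idx], comp.ka
    )
    return comp, pred, ipred, eta


def gof_diagnostics(data: TDMDataset, fitres: FitResult) -> pd.DataFrame:
    """Residual table: PRED, IPRED, WRES, |iWRES| per observation.

    WRES uses the first-order approximation of the marginal variance
    (gradient of the prediction w.r.t. eta at zero, squared, times
    omega^2, plus the residual variance); iWRES standardizes by the
    residual error SD at the individual prediction.  Under a correct
    model both are approximately standard normal.
    """
    comp, pred, ipred, eta = _predictions(data, fitres)
    params = fitres.params
    res_var_pred = comp.residual_var(pred, params)
    res_var_ipred = comp.residual_var(ipred, params)
    if np.any(res_var_ipred <= 0) or np.any(res_var_pred <= 0):
        raise ValueError("zero residual variance; diagnostics undefined")
    omega2 = params.get("omega2_cl", 0.0)
    # conditional (FOCE-style) weighted residual: linearize around the
    # empirical-Bayes mode, which centers the residual despite the
    # curvature of the trough in eta
    h = 1e-5
    tvcl, tvv = comp.typical(params)
    eta_obs = eta[comp.subj_idx]
    f_plus = _ss_trough(comp.dose, comp.tau, (tvcl * np.exp(eta + h))[comp.subj_idx],
                        tvv[comp.subj_idx], comp.ka)
    dfde = (f_plus - ipred) / h
    marg_mean = ipred - dfde * eta_obs
    marg_var = dfde**2 * omega2 + res_var_ipred
    obs = data.df[data.df["EVID"] == 0]
    iwres = (comp.y - ipred) / np.sqrt(res_var_ipred)
    return pd.DataFrame({
        "ID": obs["ID"].to_numpy(),
        "TIME": obs["TIME"].to_numpy(),
        "DV": comp.y,
        "PRED": pred,
        "IPRED": ipred,
        "WRES": (comp.y - marg_mean) / np.sqrt(marg_var),
        "IWRES": iwres,
        "ABS_IWRES": np.abs(iwres),
    })


@dataclass
class VPCResult:
    bins: pd.DataFrame  # per bin: observed/simulated percentiles
    coverage: float  # fraction of observations inside the simulated band
    n_sim: int
    binning: str = "weight quartiles"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, row in self.bins.iterrows():
            if not (row["sim_p2.5"] <= row["sim_p97.5"]):
                raise ValueError("simulated percentile ordering violated")
            if not (row["obs_p2.5"] <= row["obs_p50"] <= row["obs_p97.5"]):
                raise ValueError("observed percentile ordering violated")


def vpc(
    data: TDMDataset,
    fitres: FitResult,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    n_bins: int = 4,
) -> VPCResult:
    """Prediction-corrected VPC at the observed design.

    ``n_sim`` replicate datasets are simulated under the fitted model
    (new eta per subject, new residual error per observation, same
    doses/weights/covariates); observed and simulated values are
    prediction-corrected within weight-quartile bins and the observed
    values are compared with the 2.5th-97.5th percentile band of the
    simulated distribution bin by bin.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp, pred, _, _ = _predictions(data, fitres)
    params = fitres.params
    notes: list[str] = []

    wt = comp.weight[comp.subj_idx]
    try:
        bins = pd.qcut(wt, q=n_bins, duplicates="drop")
    except ValueError:
        bins = pd.Series(pd.Categorical(["all"] * len(wt)))
        notes.append("binning collapsed: weight not binnable into quartiles")
    bin_codes = pd.Series(bins).cat.codes.to_numpy()
    n_used_bins = bin_codes.max() + 1
    if n_used_bins < n_bins:
        notes.append(f"bins merged: {n_used_bins} of {n_bins} requested")

    # prediction-correction factor per observation
    pc = np.empty_like(pred)
    for b in range(n_used_bins):
        m = bin_codes == b
        pc[m] = np.median(pred[m]) / pred[m]
    obs_pc = comp.y * pc

    # simulate at the observed design
    tvcl, tvv = comp.typical(params)
    omega_sd = np.sqrt(params.get("omega2_cl", 0.0))
    sd1 = np.sqrt(params["sigma1"])
    etas = rng.normal(0.0, omega_sd, size=(n_sim, comp.n_subjects))
    cl = tvcl[None, :] * np.exp(etas)
    f = _ss_trough(comp.dose[None, :], comp.tau[None, :], cl[:, comp.subj_idx],
                   tvv[None, comp.subj_idx], comp.ka)
    kind = fitres.spec.residual_kind
    eps1 = rng.normal(0.0, 1.0, size=f.shape)
    if kind == "additive":
        sim = f + sd1 * eps1
    elif kind == "proportional":
        sim = f * (1.0 + sd1 * eps1)
    else:
        sd2 = np.sqrt(params["sigma2"])
        sim = f * (1.0 + sd1 * eps1) + sd2 * rng.normal(0.0, 1.0, size=f.shape)
    sim_pc = sim * pc[None, :]

    rows = []
    inside = 0
    for b in range(n_used_bins):
        m = bin_codes == b
        pool = sim_pc[:, m].ravel()
        lo, hi = np.percentile(pool, [2.5, 97.5])
        o = obs_pc[m]
        inside += int(np.sum((o >= lo) & (o <= hi)))
        rows.append({
            "bin": b,
            "weight_lo": float(wt[m].min()),
            "weight_hi": float(wt[m].max()),
            "n_obs": int(m.sum()),
            "obs_p2.5": float(np.percentile(o, 2.5)),
            "obs_p50": float(np.percentile(o, 50)),
            "obs_p97.5": float(np.percentile(o, 97.5)),
            "sim_p2.5": float(lo),
            "sim_p50": float(np.percentile(pool, 50)),
            "sim_p97.5": float(hi),
        })
    return VPCResult(
        bins=pd.DataFrame(rows), coverage=inside / len(obs_pc), n_sim=n_sim, notes=notes
    )
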