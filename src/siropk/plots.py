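"""Publication-style diagnostic and simulation plots.

Matplotlib figures mirroring the usual popPK panels: goodness-of-fit
quartet, weighted-residual density and Q-Q, VPC bands, PTA-vs-dose
curves and concentration-time profiles.  All functions return the
Figure; callers decide whether to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .optimize import PTAGrid
from .pk_model import DoseRegimen, StructuralParams, concentration_time_profile
from .validation import VPCResult

__all__ = ["gof_quartet", "residual_distribution", "vpc_plot", "pta_plot", "profile_plot"]


def gof_quartet(gof: pd.DataFrame):
    """Observations vs PRED/IPRED, |iWRES| vs IPRED, WRES vs time."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = [0, max(gof["DV"].max(), gof["PRED"].max(), gof["IPRED"].max()) * 1.05]
    for ax, x, xlab in ((axes[0, 0], "PRED", "population prediction (ng/ml)"),
                        (axes[0, 1], "IPRED", "individual prediction (ng/ml)")):
        ax.plot(gof[x], gof["DV"], "o", ms=3, alpha=0.6)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("observation (ng/ml)")
    axes[1, 0].plot(gof["IPRED"], gof["ABS_IWRES"], "o", ms=3, alpha=0.6)
    axes[1, 0].set_xlabel("individual prediction (ng/ml)")
    axes[1, 0].set_ylabel("|iWRES|")
    axes[1, 1].plot(gof["TIME"], gof["WRES"], "o", ms=3, alpha=0.6)
    axes[1, 1].axhline(0, color="k", lw=1, ls="--")
    axes[1, 1].set_xlabel("time (h)")
    axes[1, 1].set_ylabel("weighted residual")
    fig.tight_layout()
    return fig


def residual_distribution(gof: pd.DataFrame):
    """Density and normal Q-Q of weighted residuals."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    w = gof["WRES"].to_numpy()
    axes[0].hist(w, bins=20, density=True, alpha=0.7)
    x = np.linspace(w.min() - 1, w.max() + 1, 200)
    axes[0].plot(x, stats.norm.pdf(x), "k-", lw=1)
    axes[0].set_xlabel("weighted residual")
    axes[0].set_ylabel("density")
    stats.probplot(w, dist="norm", plot=axes[1])
    axes[1].set_title("")
    fig.tight_layout()
    return fig


def vpc_plot(res: VPCResult):
    """Observed percentiles against the simulated 95% band per bin."""
    fig, ax = plt.subplots(figsize=(7, 5))
    mid = (res.bins["weight_lo"] + res.bins["weight_hi"]) / 2
    ax.fill_between(mid, res.bins["sim_p2.5"], res.bins["sim_p97.5"], alpha=0.25,
                    label="simulated 2.5-97.5%")
    ax.plot(mid, res.bins["sim_p50"], "-", label="simulated median")
    for q, style in (("obs_p2.5", ":"), ("obs_p50", "-"), ("obs_p97.5", ":")):
        ax.plot(mid, res.bins[q], "k" + style, lw=1.5)
    ax.set_xlabel("weight-bin midpoint (kg)")
    ax.set_ylabel("prediction-corrected concentration (ng/ml)")
    ax.legend()
    fig.tight_layout()
    return fig


def pta_plot(grid: PTAGrid):
    """PTA against dose, one curve per weight group."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for w in grid.pta.columns:
        ax.plot(grid.pta.index, grid.pta[w], "-o", ms=3, label=f"{w:g} kg")
    ax.set_xlabel("dose (mg/kg/day)")
    ax.set_ylabel("probability of 5-10 ng/ml trough")
    ax.legend(ncol=2, fontsize=8)
    fig.tight_layout()
    return fig


def profile_plot(p: StructuralParams, regimen: DoseRegimen, t_end: float = 240.0):
    """Concentration-time curve under repeated dosing with the window shaded."""
    t = np.linspace(0, t_end, 600)
    c = concentration_time_profile(p, regimen, t)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, c)
    ax.axhspan(5, 10, alpha=0.15, color="green", label="target 5-10 ng/ml")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/ml)")
    ax.legend()
    fig.tight_layout()
    return fig
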