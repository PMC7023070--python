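"""Diagnostic plots: goodness-of-fit panels, VPC, and validation bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def gof_panels(fit, path: str) -> None:
    """Four-panel goodness-of-fit figure: PRED and IPRED vs observations,
    CWRES vs time after dose, IWRES vs individual predictions."""
    from .diagnostics import _etas_matrix, _fit_objective, _tad, cwres, iwres

    model = fit.model
    pk = model._pk
    obj = _fit_objective(model, fit)
    etas = _etas_matrix(model, fit)
    ipred = obj.individual_pred(etas)[pk.mask]
    pred = obj.individual_pred(np.zeros((pk.n, 2)))[pk.mask]
    dv = np.exp(pk.logy)[pk.mask]
    iw = iwres(model, fit)
    cw = cwres(model, fit)
    tad = _tad(model)[pk.mask]

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x, title in ((axes[0, 0], pred, "PRED"), (axes[0, 1], ipred, "IPRED")):
        ax.plot(x, dv, "o", ms=3, alpha=0.6)
        lim = max(float(np.max(x)), float(np.max(dv)))
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(f"{title} (mg/L)")
        ax.set_ylabel("observed (mg/L)")
    axes[1, 0].plot(tad, cw["CWRES"], "o", ms=3, alpha=0.6)
    axes[1, 0].axhline(0, color="k", lw=0.8, ls="--")
    axes[1, 0].set_xlabel("time after dose (h)")
    axes[1, 0].set_ylabel("CWRES")
    axes[1, 1].plot(iw["IPRED"], iw["IWRES"], "o", ms=3, alpha=0.6)
    axes[1, 1].axhline(0, color="k", lw=0.8, ls="--")
    axes[1, 1].set_xlabel("IPRED (mg/L)")
    axes[1, 1].set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(vpc_result, path: str) -> None:
    """Observed percentiles against simulation-based 95% CIs per bin."""
    fig, ax = plt.subplots(figsize=(7, 5))
    b = vpc_result.bins
    shades = {2.5: "lightgray", 50.0: "darkgray", 97.5: "lightgray"}
    for p in (2.5, 50.0, 97.5):
        lo, hi = vpc_result.sim_ci[p]
        ax.fill_between(b, lo, hi, color=shades[p], alpha=0.7)
        ax.plot(b, vpc_result.observed[p], "-" if p == 50.0 else "--", color="C0")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def validation_plot(bands, path: str) -> None:
    """Median and 2.5/97.5 simulated trajectories per Clcr grid value, with
    observed points overlaid when present."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for gi, clcr in enumerate(bands.clcr_grid):
        ax.plot(bands.times, bands.percentiles[gi, 1], label=f"Clcr {clcr:g}")
        ax.plot(bands.times, bands.percentiles[gi, 0], ls="--", lw=0.7, color="gray")
        ax.plot(bands.times, bands.percentiles[gi, 2], ls="--", lw=0.7, color="gray")
    if bands.observed is not None and len(bands.observed):
        ax.plot(bands.observed["TIME"], bands.observed["DV"], "ko", ms=4)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
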