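"""PK/PD indices and target attainment.

Efficacy targets for linezolid: ``AUC24/MIC >= 80`` and ``100% T>MIC`` for
the intermittent regimen; ``Css >= MIC`` (equivalent to 100% T>MIC) for
continuous infusion.  Observed-profile indices use measured concentrations;
simulation-based PTA uses noise-free model profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pkmodel import concentration, steady_state_css, typical_clearance
from .types import (
    IndividualParameters,
    PopulationParameters,
    ValidationError,
    _require,
)
from .cohort import make_regimen

MIC_GRID = (1.0, 2.0, 4.0)
AUC_TARGET = 80.0


@dataclass(frozen=True)
class PKPDResult:
    """Per-subject indices and boolean attainment per MIC."""

    subject_id: int | str
    auc24: float
    pct_t_above_mic: dict[float, float]
    css: float | None
    attain_auc: dict[float, bool]
    attain_t: dict[float, bool]
    attain_css: dict[float, bool] | None


def nca_auc_tau(times, concentrations, tau: float = 12.0) -> float:
    """Noncompartmental AUC over one steady-state dosing interval (mg*h/L).

    Linear-up/log-down trapezoid; the profile must span the whole interval
    (no extrapolation).  ``auc24`` for a q12h regimen is twice this value.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    _require(t.ndim == 1 and t.size >= 3, "need >= 3 points")
    _require(c.shape == t.shape, "times/concentrations lengths differ")
    _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
    _require(bool(np.all(c >= 0)), "concentrations must be >= 0")
    if t[0] > 1e-9 or t[-1] < tau - 1e-9:
        raise ValidationError(f"profile must span [0, {tau}] h; got [{t[0]}, {t[-1]}]")
    if np.all(c == 0):
        warnings.warn("all-zero profile; AUC = 0", stacklevel=2)
        return 0.0
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)   # log-down
        else:
            auc += dt * (c1 + c2) / 2.0                 # linear up (or zero tail)
    return float(auc)


def auc24_from_tau(auc_tau: float) -> float:
    """AUC over 24 h for a q12h regimen: twice the interval AUC."""
    return 2.0 * auc_tau


def pct_time_above_mic(times, concentrations, mic: float, tau: float = 12.0) -> float:
    """Percent of the dosing interval with concentration above the MIC.

    Crossing times between bracketing samples are located by log-linear
    interpolation (mono-exponential decline between samples); falls back to
    linear when a bracketing concentration is zero.
    """
    if mic <= 0:
        raise ValidationError("mic must be > 0")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    _require(t.ndim == 1 and t.size >= 3, "need >= 3 points")
    _require(c.shape == t.shape, "times/concentrations lengths differ")
    _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
    if t[0] > 1e-9 or t[-1] < tau - 1e-9:
        raise ValidationError(f"profile must span [0, {tau}] h; got [{t[0]}, {t[-1]}]")
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        a1, a2 = c1 > mic, c2 > mic
        if a1 and a2:
            total += dt
        elif a1 != a2:
            # frac = crossing position within the segment, from the left
            if c1 > 0 and c2 > 0:
                frac = math.log(c1 / mic) / math.log(c1 / c2)
            else:
                frac = (mic - c1) / (c2 - c1)
            total += dt * frac if a1 else dt * (1.0 - frac)
    return float(100.0 * total / tau)


def subject_indices(
    subject_id,
    times,
    concentrations,
    mic_grid=MIC_GRID,
    css: float | None = None,
    tau: float = 12.0,
) -> PKPDResult:
    """All indices for one measured steady-state interval profile."""
    auc_tau = nca_auc_tau(times, concentrations, tau)
    auc24 = auc24_from_tau(auc_tau)
    pct = {m: pct_time_above_mic(times, concentrations, m, tau) for m in mic_grid}
    return PKPDResult(
        subject_id=subject_id,
        auc24=auc24,
        pct_t_above_mic=pct,
        css=css,
        attain_auc={m: auc24 / m >= AUC_TARGET for m in mic_grid},
        attain_t={m: pct[m] >= 100.0 - 1e-9 for m in mic_grid},
        attain_css=({m: css >= m for m in mic_grid} if css is not None else None),
    )


def attainment_table(
    results: dict[str, list],
    mic_grid=MIC_GRID,
) -> pd.DataFrame:
    """Attainment counts and percentages per group x MIC x target.

    ``results`` maps group labels to lists: for intermittent groups, lists of
    :class:`PKPDResult` scored per patient on ``attain_auc``/``attain_t``;
    for a continuous-infusion group (label containing 'continuous'), lists of
    per-sample Css values scored on ``Css >= MIC``.  Percentages are rounded
    only here, at the reporting layer.
    """
    rows = []
    for group, items in results.items():
        if not items:
            warnings.warn(f"empty group {group!r} omitted", stacklevel=2)
            continue
        continuous = "continuous" in str(group).lower()
        for mic in mic_grid:
            if continuous:
                n = len(items)
                k = sum(1 for css in items if css >= mic)
                rows.append({"group": group, "mic": mic, "target": "Css>=MIC",
                             "n": n, "attained": k,
                             "display": f"{k} ({round(100 * k / n)}%)"})
            else:
                n = len(items)
                for target, key in (("AUC24/MIC>=80", "attain_auc"),
                                    ("100%T>MIC", "attain_t")):
                    k = sum(1 for r in items if getattr(r, key)[mic])
                    rows.append({"group": group, "mic": mic, "target": target,
                                 "n": n, "attained": k,
                                 "display": f"{k} ({round(100 * k / n)}%)"})
    return pd.DataFrame(rows)


def compare_proportions(x1: int, n1: int, x2: int, n2: int,
                        method: str = "auto") -> float:
    """Two-sided p-value comparing two attainment proportions.

    ``method='pearson'`` forces Pearson's chi-square without continuity
    correction; ``'fisher'`` forces Fisher's exact test; ``'auto'`` uses
    Pearson unless any expected cell count is below 5, in which case it
    switches to Fisher (the switch is logged via warnings).
    """
    for x, n in ((x1, n1), (x2, n2)):
        _require(n >= 1, "n must be >= 1")
        _require(0 <= x <= n, "need 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if method == "auto":
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if np.any(expected < 5):
            warnings.warn("expected cell < 5; using Fisher's exact test", stacklevel=2)
            method = "fisher"
        else:
            method = "pearson"
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "pearson":
        if table[:, 0].sum() in (0, table.sum()) :
            return 1.0  # degenerate margin: identical proportions of 0 or 1
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p)
    raise ValidationError(f"unknown method {method!r}")


def pta_simulation(
    params: PopulationParameters,
    regimen_kind: str,
    covariate_sampler,
    mic_grid=MIC_GRID,
    n: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo probability of target attainment.

    Draws ``n`` subjects (covariates from ``covariate_sampler(rng, size)``,
    etas from the population model), computes noise-free model profiles over
    one steady-state interval (intermittent) or the steady-state
    concentration (continuous), and scores the efficacy targets per MIC.
    Returns PTA percentages per (MIC, target).
    """
    _require(n >= 100, "n must be >= 100")
    rng = np.random.default_rng(seed)
    covs = covariate_sampler(rng, n)
    doses = make_regimen(regimen_kind)
    sds = np.sqrt([params.omega_cl, params.omega_v1])
    etas = rng.standard_normal((n, 2)) * sds[None, :]
    rows = []
    if regimen_kind == "continuous":
        rate = doses[-1].rate
        css = np.array([
            steady_state_css(rate, typical_clearance(params, c) * math.exp(etas[i, 0]))
            for i, c in enumerate(covs)
        ])
        for mic in mic_grid:
            rows.append({"mic": mic, "target": "Css>=MIC",
                         "pta": float(100.0 * np.mean(css >= mic))})
        return pd.DataFrame(rows)
    t_grid = np.linspace(0.0, 12.0, 49)
    last = doses[-1].start_time
    attain_auc = {m: 0 for m in mic_grid}
    attain_t = {m: 0 for m in mic_grid}
    for i, cov in enumerate(covs):
        ind = IndividualParameters.from_population(params, cov, etas[i, 0], etas[i, 1])
        prof = concentration(ind, doses, last + t_grid)
        auc24 = 2.0 * nca_auc_tau(t_grid, prof)
        for m in mic_grid:
            if auc24 / m >= AUC_TARGET:
                attain_auc[m] += 1
            if np.all(prof > m):
                attain_t[m] += 1
    for m in mic_grid:
        rows.append({"mic": m, "target": "AUC24/MIC>=80",
                     "pta": 100.0 * attain_auc[m] / n})
        rows.append({"mic": m, "target": "100%T>MIC",
                     "pta": 100.0 * attain_t[m] / n})
    return pd.DataFrame(rows)
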