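"""Structural two-compartment IV-infusion model and residual-error model.

Closed-form bi-exponential solution with micro-constants ``k10 = CL/V1``,
``k12 = Q/V1``, ``k21 = Q/V2`` and eigenvalues ``alpha``, ``beta`` from the
standard quadratic.  Multiple doses are handled by superposition; an infusion
is evaluated piecewise (during / after) in a single vectorised expression.

The residual model generates observations on the natural scale,
``y = f * (1 + eps_prop) + eps_add``, and fits log-transformed data with the
log-transform-both-sides variance ``sigma_prop**2 + (sigma_add / f)**2``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import (
    CLCR_REF,
    DosingEvent,
    IndividualParameters,
    PopulationParameters,
    SubjectCovariates,
    ValidationError,
)


def typical_clearance(params: PopulationParameters, cov: SubjectCovariates) -> float:
    """Typical (eta = 0) total clearance in L/h.

    ``CL = cl_nr + cl_r_slope * (clcr / 44) + sc * qef`` with the
    extracorporeal term present only on CRRT.  Strictly increasing in Clcr
    and never below the non-renal component.
    """
    return params.cl_nr + params.cl_r_slope * (cov.clcr / CLCR_REF) + cov.cl_ec


def _two_cmt_conc(cl, v1, q, v2, start, rate, duration, t):
    """Broadcasted closed-form concentration for one infusion event.

    All arguments broadcast against each other; returns the plasma
    concentration (mg/L), zero before the infusion starts.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # unit-bolus coefficients, A + B = 1
    coef_a = (k21 - alpha) / (beta - alpha)
    coef_b = (k21 - beta) / (alpha - beta)
    tau = t - start
    te = np.clip(tau, 0.0, duration)            # elapsed infusion time
    tp = np.maximum(tau - duration, 0.0)        # time since infusion end
    term_a = (coef_a / alpha) * (-np.expm1(-alpha * te)) * np.exp(-alpha * tp)
    term_b = (coef_b / beta) * (-np.expm1(-beta * te)) * np.exp(-beta * tp)
    return (rate / v1) * (term_a + term_b)


def _check_individual(params: IndividualParameters) -> None:
    vals = (params.cl, params.v1, params.q, params.v2)
    if not all(np.isfinite(v) and v > 0 for v in vals):
        raise ValidationError(f"non-finite or non-positive PK parameters: {vals}")


def concentration(
    params: IndividualParameters,
    doses: Sequence[DosingEvent],
    t,
):
    """Plasma concentration (mg/L) at time(s) ``t`` under superposed doses.

    Times before every dose start return 0 (nothing administered yet).
    For a never-ending infusion at rate R the limit is ``R / cl``.
    """
    _check_individual(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    out = np.zeros_like(t_arr)
    for d in doses:
        out = out + _two_cmt_conc(
            params.cl, params.v1, params.q, params.v2, d.start_time, d.rate, d.duration, t_arr
        )
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def _cumulative_single(cl, v1, q, v2, rate, duration, tau):
    """Integral of one infusion's concentration from its start to ``tau``."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    coef_a = (k21 - alpha) / (beta - alpha)
    coef_b = (k21 - beta) / (alpha - beta)
    tau = np.maximum(np.asarray(tau, dtype=float), 0.0)
    te = np.clip(tau, 0.0, duration)
    tp = np.maximum(tau - duration, 0.0)

    def _one(coef, lam):
        during = (coef / lam) * (te + np.expm1(-lam * te) / lam)
        after = (coef / lam**2) * (-np.expm1(-lam * te)) * (-np.expm1(-lam * tp))
        return during + after

    return (rate / v1) * (_one(coef_a, alpha) + _one(coef_b, beta))


def auc_interval(
    params: IndividualParameters,
    doses: Sequence[DosingEvent],
    t0: float,
    t1: float,
) -> float:
    """Analytic AUC (mg*h/L) of the model concentration over ``[t0, t1]``."""
    _check_individual(params)
    if not (0 <= t0 <= t1):
        raise ValidationError(f"need 0 <= t0 <= t1, got [{t0}, {t1}]")
    total = 0.0
    for d in doses:
        total += _cumulative_single(
            params.cl, params.v1, params.q, params.v2, d.rate, d.duration, t1 - d.start_time
        ) - _cumulative_single(
            params.cl, params.v1, params.q, params.v2, d.rate, d.duration, t0 - d.start_time
        )
    return float(total)


def log_variance(f, sigma_add: float, sigma_prop: float):
    """Residual variance of log-concentration at true concentration ``f``.

    Log-transform-both-sides (delta-method) form of the combined error model:
    ``sigma_prop**2 + (sigma_add / f)**2``.  Requires ``f > 0``.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValidationError("log_variance requires f > 0")
    out = sigma_prop**2 + (sigma_add / f_arr) ** 2
    return out if out.ndim else float(out)


def observe(f, sigma_add: float, sigma_prop: float, rng: np.random.Generator):
    """Draw natural-scale observations ``y = f*(1 + eps_prop) + eps_add``."""
    f_arr = np.asarray(f, dtype=float)
    y = (
        f_arr * (1.0 + sigma_prop * rng.standard_normal(f_arr.shape))
        + sigma_add * rng.standard_normal(f_arr.shape)
    )
    return y if y.ndim else float(y)


def steady_state_css(rate: float, cl: float) -> float:
    """Steady-state concentration (mg/L) of a continuous infusion: rate/CL."""
    if cl <= 0:
        raise ValidationError("cl must be > 0")
    return rate / cl


def intermittent_regimen(
    n_doses: int = 8,
    amount: float = 600.0,
    interval: float = 12.0,
    duration: float = 0.5,
) -> list[DosingEvent]:
    """Standard intermittent regimen: ``n_doses`` infusions ``interval`` apart."""
    return [DosingEvent(i * interval, amount, duration) for i in range(n_doses)]


def continuous_regimen(
    loading: float = 600.0,
    loading_duration: float = 0.5,
    rate: float = 50.0,
    maintenance_hours: float = 96.0,
) -> list[DosingEvent]:
    """Loading infusion followed by a long constant-rate maintenance infusion."""
    return [
        DosingEvent(0.0, loading, loading_duration),
        DosingEvent(loading_duration, rate * maintenance_hours, maintenance_hours),
    ]
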