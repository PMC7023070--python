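"""Independent oracles used by the test suite.

These deliberately avoid the package's own closed forms: ODE integration for
the structural model, Gauss-Hermite quadrature for the marginal likelihood,
and the textbook steady-state superposition formula.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp

from lzpk.estimation import _conditional_modes


def ode_concentration(ind, doses, times, rtol=1e-10, atol=1e-12):
    """Two-compartment concentrations by piecewise adaptive ODE integration."""
    times = np.asarray(times, dtype=float)
    k10 = ind.cl / ind.v1
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2
    breaks = sorted({0.0, *(d.start_time for d in doses),
                     *(d.start_time + d.duration for d in doses),
                     float(times.max())})
    breaks = [b for b in breaks if b <= times.max() + 1e-12]

    def rate_in(t):
        return sum(d.rate for d in doses if d.start_time <= t < d.start_time + d.duration)

    out = np.empty_like(times)
    state = np.zeros(2)
    for a, b in zip(breaks[:-1], breaks[1:]):
        r = rate_in(0.5 * (a + b))

        def rhs(t, y, r=r):
            return [r - (k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

        t_eval = times[(times > a + 1e-12) & (times <= b + 1e-12)]
        grid = np.unique(np.concatenate([np.sort(t_eval), [b]]))
        sol = solve_ivp(rhs, (a, b), state, t_eval=grid, rtol=rtol, atol=atol)
        lookup = dict(zip(grid, sol.y[0]))
        for i, t in enumerate(times):
            if t in lookup:
                out[i] = lookup[t]
        state = sol.y[:, -1]   # state at the segment end b
    out[times <= breaks[0] + 1e-12] = 0.0
    return out / ind.v1


def gauss_hermite_ofv(model, params, n_nodes: int = 21) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature,
    centred and scaled at each subject's conditional mode."""
    obj = model._objective_for(model._theta_from_params(params))
    etas, m0, H = _conditional_modes(obj)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    zz = np.array([[zi, zj] for zi in z for zj in z])          # (K, 2)
    ww = np.array([wi * wj for wi in w for wj in w])
    total = 0.0
    n = obj.pk.n
    for i in range(n):
        R = np.linalg.cholesky(H[i]).T                          # H = R'R
        B = 2.0 * np.linalg.inv(R)
        pts = np.tile(etas[None, :, :], (len(zz), 1, 1))
        pts[:, i, :] = etas[i][None, :] + zz @ B.T
        m_i = obj.m(pts)[:, i]
        log_terms = -0.5 * m_i + np.sum(zz**2, axis=1) + np.log(ww)
        lse = np.logaddexp.reduce(log_terms)
        total += -2.0 * (lse + np.log(abs(np.linalg.det(B))))
    return total


def ss_intermittent_conc(ind, amount, tau, dur, t_after_dose):
    """Analytic steady-state concentration for repeated infusions, valid for
    times at or after the end of the infusion within the interval."""
    rate = amount / dur
    k10 = ind.cl / ind.v1
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    lam = np.array([(s + disc) / 2, (s - disc) / 2])
    coef = np.array([(k21 - lam[0]) / (lam[1] - lam[0]),
                     (k21 - lam[1]) / (lam[0] - lam[1])])
    t = np.asarray(t_after_dose, dtype=float)
    out = np.zeros_like(t)
    for c, L in zip(coef, lam):
        out = out + (c / L) * (1 - np.exp(-L * dur)) * np.exp(-L * (t - dur)) \
            / (1 - np.exp(-L * tau))
    return (rate / ind.v1) * out


def piecewise_linear_auc_ratio(times, plasma, effluent):
    """AUC ratio by adaptive quadrature of the piecewise-linear interpolants."""
    def make(f):
        return lambda x: np.interp(x, times, f)
    pts = list(times[1:-1])
    auc_p = quad(make(plasma), times[0], times[-1], points=pts, limit=500)[0]
    auc_e = quad(make(effluent), times[0], times[-1], points=pts, limit=500)[0]
    return auc_e / auc_p
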