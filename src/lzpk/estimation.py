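"""Mixed-effects estimation of the population PK model.

The marginal likelihood over the subject-level random effects
``(eta_cl, eta_v1)`` is approximated by a conditional-mode Laplace expansion
with interaction (residual variance evaluated at the individual prediction),
on log-transformed concentrations.  This is the same family of approximation
as NONMEM's FOCE-I; exact agreement with NONMEM's linearisation is not
attempted, and recovery of generating parameters — not OFV equality — is the
supported contract.

The inner problem (two etas per subject) is solved by damped Newton
iterations, vectorised across subjects with finite-difference derivatives;
the outer problem optimises fixed effects and (log-transformed) variance
parameters with Nelder-Mead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariates import build_hepatic_flags
from .data import DatasetTable, PLASMA_CMT
from .pkmodel import _two_cmt_conc
from .types import CLCR_REF, ModelSpec, PopulationParameters, ValidationError

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data packing

@dataclass
class _Packed:
    """Per-subject arrays padded to a common width for vectorised likelihoods."""

    ids: list
    times: np.ndarray      # (n, m) h
    logy: np.ndarray       # (n, m) log observed plasma concentration
    mask: np.ndarray       # (n, m) bool, True where a real observation sits
    dose_start: np.ndarray  # (n, d)
    dose_rate: np.ndarray   # (n, d) padded doses have rate 0
    dose_dur: np.ndarray    # (n, d)
    cl_ec: np.ndarray       # (n,)
    clcr44: np.ndarray      # (n,) Clcr / 44
    hep: np.ndarray         # (n, 3) hepatic flags [>=1, >=2, ==3] as 0/1

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def _pack(dataset: DatasetTable) -> _Packed:
    subjects = dataset.subjects()
    keep, dropped = [], []
    for rec in subjects:
        obs = rec.observations
        ok = obs[(obs["CMT"] == PLASMA_CMT) & (obs["BLQ"] == 0) & obs["DV"].notna()]
        if len(ok) == 0:
            dropped.append(rec.covariates.subject_id)
            continue
        if np.any(ok["DV"].to_numpy() <= 0):
            raise ValidationError(
                f"subject {rec.covariates.subject_id}: non-positive DV in likelihood"
            )
        keep.append((rec, ok))
    if dropped:
        warnings.warn(f"subjects without quantifiable plasma observations dropped: {dropped}",
                      stacklevel=2)
    if not keep:
        raise ValidationError("no usable plasma observations in dataset")
    n = len(keep)
    m = max(len(ok) for _, ok in keep)
    d = max(len(rec.doses) for rec, _ in keep)
    times = np.zeros((n, m))
    logy = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    dose_start = np.zeros((n, d))
    dose_rate = np.zeros((n, d))
    dose_dur = np.ones((n, d))
    cl_ec = np.zeros(n)
    clcr44 = np.zeros(n)
    hep = np.zeros((n, 3))
    ids = []
    for i, (rec, ok) in enumerate(keep):
        k = len(ok)
        times[i, :k] = ok["TIME"].to_numpy()
        logy[i, :k] = np.log(ok["DV"].to_numpy(dtype=float))
        mask[i, :k] = True
        for j, dose in enumerate(rec.doses):
            dose_start[i, j] = dose.start_time
            dose_rate[i, j] = dose.rate
            dose_dur[i, j] = dose.duration
        cov = rec.covariates
        cl_ec[i] = cov.cl_ec
        clcr44[i] = cov.clcr / CLCR_REF
        if cov.bilirubin is not None and cov.got is not None and cov.gpt is not None:
            hep[i] = np.asarray(
                build_hepatic_flags(cov.bilirubin, cov.got, cov.gpt, cov.sex), dtype=float
            )
        ids.append(cov.subject_id)
    return _Packed(ids, times, logy, mask, dose_start, dose_rate, dose_dur,
                   cl_ec, clcr44, hep)


def _conc_packed(cl, v1, q, v2, pk: _Packed):
    """Concentration at all packed observation slots; cl/v1 shaped (..., n)."""
    cl = cl[..., None]
    v1 = v1[..., None]
    out = 0.0
    for j in range(pk.dose_start.shape[1]):
        out = out + _two_cmt_conc(
            cl, v1, q, v2,
            pk.dose_start[:, j, None], pk.dose_rate[:, j, None], pk.dose_dur[:, j, None],
            pk.times,
        )
    return out


# ---------------------------------------------------------------------------
# inner (eta) problem

class _InnerObjective:
    """Per-subject penalised -2 log joint density, batched over eta points."""

    def __init__(self, pk: _Packed, tvcl: np.ndarray, tvv1: float, q: float, v2: float,
                 sigma_add: float, sigma_prop: float, omega: np.ndarray):
        self.pk = pk
        self.tvcl = tvcl
        self.tvv1 = tvv1
        self.q = q
        self.v2 = v2
        self.sa2 = sigma_add**2
        self.sp2 = sigma_prop**2
        self.sa = sigma_add
        self.omega = omega                      # (2,) variances
        self.active = omega > 0.0
        self.pen_const = float(np.sum(np.log(2.0 * np.pi * omega[self.active])))

    def individual_pred(self, etas: np.ndarray) -> np.ndarray:
        cl = self.tvcl * np.exp(etas[..., 0])
        v1 = self.tvv1 * np.exp(etas[..., 1])
        return _conc_packed(cl, v1, self.q, self.v2, self.pk)

    def m(self, etas: np.ndarray, strict: bool = False) -> np.ndarray:
        """-2 log [p(y|eta) p(eta)] for eta arrays shaped (..., n, 2).

        With ``strict`` a non-positive prediction at an observation raises
        (subject/time context included); otherwise such points evaluate to
        +inf so line searches simply reject them.
        """
        pk = self.pk
        with np.errstate(all="ignore"):
            f = self.individual_pred(etas)
            f = np.where(pk.mask, f, 1.0)
            bad = (f <= 0.0) | ~np.isfinite(f)
            if strict and np.any(bad):
                idx = np.argwhere(bad)[0]
                i, j = int(idx[-2]), int(idx[-1])
                raise ValidationError(
                    f"non-positive predicted concentration for subject {pk.ids[i]} "
                    f"at t={pk.times[i, j]:.4g} h"
                )
            f = np.where(bad, 1.0, f)
            r = pk.logy - np.log(f)
            v = self.sp2 + self.sa2 / (f * f)
            lik = np.sum(np.where(pk.mask, r * r / v + np.log(v) + LOG2PI, 0.0), axis=-1)
            lik = np.where(np.any(bad, axis=-1), np.inf, lik)
            pen = self.pen_const
            for k in range(2):
                if self.active[k]:
                    pen = pen + etas[..., k] ** 2 / self.omega[k]
        return lik + pen


def _conditional_modes(obj: _InnerObjective, eta0: np.ndarray | None = None,
                       grad_tol: float = 1e-8, max_iter: int = 100, h: float = 1e-4):
    """Damped Newton search for per-subject conditional modes, vectorised.

    Returns (etas, m0, H) with the objective value and finite-difference
    Hessian at the modes.
    """
    n = obj.pk.n
    a1, a2 = bool(obj.active[0]), bool(obj.active[1])
    etas = np.zeros((n, 2)) if eta0 is None else np.array(eta0, dtype=float)
    if not a1:
        etas[:, 0] = 0.0
    if not a2:
        etas[:, 1] = 0.0
    off = np.array([
        [0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1],
    ], dtype=float) * h
    if not a1:
        off[:, 0] = 0.0
    if not a2:
        off[:, 1] = 0.0
    done = np.zeros(n, dtype=bool)
    obj.m(np.zeros((1, n, 2)), strict=True)  # validate design/params at the start
    if not (a1 or a2):
        m0 = obj.m(etas)
        return etas, m0, np.tile(np.eye(2), (n, 1, 1))

    # the conditional objective can be multimodal in eta (sparse individual
    # information); pick the starting basin from a coarse omega-scaled grid
    sd = np.sqrt(np.where(obj.active, obj.omega, 0.0))
    g1d = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    cand = [np.zeros((n, 2))]
    grid_pts = []
    for u in (g1d if a1 else [0.0]):
        for w in (g1d if a2 else [0.0]):
            grid_pts.append(np.broadcast_to(np.array([u * sd[0], w * sd[1]]), (n, 2)))
    cand.extend(grid_pts)
    if eta0 is not None:
        cand.append(np.array(eta0, dtype=float))
    cand_arr = np.stack(cand)                        # (C, n, 2)
    mc = obj.m(cand_arr)                             # (C, n)
    best = np.argmin(mc, axis=0)
    etas = cand_arr[best, np.arange(n), :].copy()

    def derivs(e):
        ms = obj.m(e[None, :, :] + off[:, None, :])   # (9, n)
        m0 = ms[0]
        g1 = (ms[1] - ms[2]) / (2 * h) if a1 else np.zeros(n)
        g2 = (ms[3] - ms[4]) / (2 * h) if a2 else np.zeros(n)
        h11 = (ms[1] + ms[2] - 2 * m0) / h**2 if a1 else np.ones(n)
        h22 = (ms[3] + ms[4] - 2 * m0) / h**2 if a2 else np.ones(n)
        h12 = (ms[5] - ms[6] - ms[7] + ms[8]) / (4 * h**2) if (a1 and a2) else np.zeros(n)
        return m0, g1, g2, h11, h22, h12

    m0, g1, g2, h11, h22, h12 = derivs(etas)
    for _ in range(max_iter):
        gmax = np.maximum(np.abs(g1), np.abs(g2))
        done |= gmax < grad_tol
        if done.all():
            break
        # damp to positive definite (2x2 eigenvalue floor)
        eig_min = 0.5 * ((h11 + h22) - np.sqrt((h11 - h22) ** 2 + 4 * h12**2))
        lam = np.where(eig_min < 1e-6, 1e-6 - eig_min, 0.0)
        d11, d22 = h11 + lam, h22 + lam
        det = d11 * d22 - h12**2
        s1 = np.clip(-(d22 * g1 - h12 * g2) / det, -4.0, 4.0)
        s2 = np.clip(-(d11 * g2 - h12 * g1) / det, -4.0, 4.0)
        scale = np.ones(n)
        accepted = done.copy()
        cand = etas.copy()
        m_new = m0.copy()
        for _bt in range(15):
            trial = etas.copy()
            trial[:, 0] = etas[:, 0] + scale * s1
            trial[:, 1] = etas[:, 1] + scale * s2
            mt = obj.m(trial[None, :, :])[0]
            better = (~accepted) & (mt <= m0 + 1e-12)
            cand[better] = trial[better]
            m_new[better] = mt[better]
            accepted |= better
            if accepted.all():
                break
            scale = np.where(accepted, scale, scale * 0.5)
        stalled = (~accepted) | (
            (np.abs(scale * s1) < 1e-9) & (np.abs(scale * s2) < 1e-9) & (gmax < 1e-5)
        )
        done |= stalled
        etas = np.where(accepted[:, None], cand, etas)
        m0, g1, g2, h11, h22, h12 = derivs(etas)
    H = np.empty((n, 2, 2))
    H[:, 0, 0] = h11
    H[:, 1, 1] = h22
    H[:, 0, 1] = H[:, 1, 0] = h12
    return etas, m0, H


def _laplace_ofv(m0: np.ndarray, H: np.ndarray, active: np.ndarray) -> float:
    """Assemble the Laplace -2 log marginal likelihood from per-subject parts."""
    d = int(active.sum())
    if d == 0:
        return float(np.sum(m0))
    if d == 2:
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
    else:
        k = 0 if active[0] else 1
        det = H[:, k, k]
    if np.any(det <= 1e-10) or not np.all(np.isfinite(det)):
        # a non-PD curvature at the "mode" means the Laplace expansion is
        # invalid there; report +inf so optimisers reject the region
        return float("inf")
    logdet = np.log(det / (4.0 if d == 2 else 2.0))
    return float(np.sum(m0 + logdet - d * LOG2PI))


# ---------------------------------------------------------------------------
# model / results objects

@dataclass(frozen=True)
class CovariateStep:
    """One candidate evaluation in stepwise covariate model building."""

    name: str
    phase: str            # "forward" | "backward"
    delta_ofv: float      # OFV(larger model) - OFV(smaller model); <= 0 favours inclusion
    df: int
    p_value: float
    included: bool


class PopPKModel:
    """Population PK model bound to a dataset and a structural spec.

    Parameters
    ----------
    dataset : DatasetTable or pandas.DataFrame
        Longitudinal dataset in the NONMEM-dialect layout.  Only quantifiable
        plasma observations enter the likelihood (below-LOQ records are
        excluded, the M1 convention).
    spec : ModelSpec
        Structural covariate choices (renal term, hepatic flags).
    """

    def __init__(self, dataset: DatasetTable | pd.DataFrame, spec: ModelSpec = ModelSpec()):
        if isinstance(dataset, pd.DataFrame):
            dataset = DatasetTable(dataset)
        self.dataset = dataset
        self.spec = spec
        self._pk = _pack(dataset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> "PopPKModel":
        return cls(DatasetTable(df), spec)

    # -- parameter vector bookkeeping ------------------------------------
    @property
    def param_names(self) -> list[str]:
        names = ["cl_nr"]
        if self.spec.clcr_on_cl:
            names.append("cl_r_slope")
        names += ["v1", "q", "v2"]
        names += [f"beta_{h}" for h in self.spec.hepatic_on_cl]
        names += ["omega_sd_cl", "omega_sd_v1", "sigma_add", "sigma_prop"]
        return names

    def _default_start(self) -> dict[str, float]:
        start = {"cl_nr": 3.0 if self.spec.clcr_on_cl else 5.0, "cl_r_slope": 3.0,
                 "v1": 20.0, "q": 50.0, "v2": 25.0,
                 "omega_sd_cl": 0.5, "omega_sd_v1": 0.5,
                 "sigma_add": 0.3, "sigma_prop": 0.2}
        for h in self.spec.hepatic_on_cl:
            start[f"beta_{h}"] = 0.0
        return {k: start[k] for k in self.param_names}

    @staticmethod
    def _is_log(name: str) -> bool:
        return not name.startswith("beta_")

    def _objective_for(self, theta: dict[str, float]) -> _InnerObjective:
        pk = self._pk
        tvcl = np.full(pk.n, theta["cl_nr"])
        if self.spec.clcr_on_cl:
            tvcl = tvcl + theta["cl_r_slope"] * pk.clcr44
        tvcl = tvcl + pk.cl_ec
        if self.spec.hepatic_on_cl:
            hep_idx = {"hep_ge1": 0, "hep_ge2": 1, "hep_eq3": 2}
            expo = np.zeros(pk.n)
            for h in self.spec.hepatic_on_cl:
                expo = expo + theta[f"beta_{h}"] * pk.hep[:, hep_idx[h]]
            tvcl = tvcl * np.exp(expo)
        if np.any(tvcl <= 0):
            raise ValidationError("non-positive typical clearance")
        omega = np.array([theta["omega_sd_cl"] ** 2, theta["omega_sd_v1"] ** 2])
        return _InnerObjective(pk, tvcl, theta["v1"], theta["q"], theta["v2"],
                               theta["sigma_add"], theta["sigma_prop"], omega)

    def _theta_from_params(self, params: PopulationParameters,
                           hepatic_betas: dict[str, float] | None = None) -> dict[str, float]:
        theta = {
            "cl_nr": params.cl_nr, "cl_r_slope": params.cl_r_slope,
            "v1": params.v1, "q": params.q, "v2": params.v2,
            "omega_sd_cl": math.sqrt(params.omega_cl),
            "omega_sd_v1": math.sqrt(params.omega_v1),
            "sigma_add": params.sigma_add, "sigma_prop": params.sigma_prop,
        }
        for h in self.spec.hepatic_on_cl:
            theta[f"beta_{h}"] = (hepatic_betas or {}).get(h, 0.0)
        return theta

    # -- likelihood ------------------------------------------------------
    def ofv(self, params: PopulationParameters,
            hepatic_betas: dict[str, float] | None = None) -> float:
        """Laplace -2 log marginal likelihood at the given parameters."""
        obj = self._objective_for(self._theta_from_params(params, hepatic_betas))
        etas, m0, H = _conditional_modes(obj)
        return _laplace_ofv(m0, H, obj.active)

    def conditional_etas(self, params: PopulationParameters,
                         hepatic_betas: dict[str, float] | None = None) -> np.ndarray:
        """Empirical-Bayes (conditional mode) etas at fixed parameters."""
        obj = self._objective_for(self._theta_from_params(params, hepatic_betas))
        etas, _, _ = _conditional_modes(obj)
        return etas

    # -- fitting ---------------------------------------------------------
    def fit(self, start: PopulationParameters | dict[str, float] | None = None,
            maxfev: int = 6000, compute_rse: bool = True,
            fix: dict[str, float] | None = None, restarts: int = 2) -> "PopPKResults":
        """Minimise the Laplace OFV; returns a :class:`PopPKResults`.

        Positivity-constrained parameters are optimised on the log scale with
        Nelder-Mead, restarted from its own solution up to ``restarts`` times
        (the simplex can collapse prematurely on this 8-9 dimensional
        surface; a restart from the solution is the standard remedy).
        Non-convergence is flagged on the result, never raised.  ``fix`` pins
        named parameters at given values (excluded from optimisation and RSE).
        """
        names = self.param_names
        if start is None:
            theta0 = self._default_start()
        elif isinstance(start, PopulationParameters):
            theta0 = self._theta_from_params(start)
        else:
            theta0 = dict(start)
            missing = [k for k in names if k not in theta0]
            if missing:
                defaults = self._default_start()
                theta0.update({k: defaults[k] for k in missing})
        fix = dict(fix or {})
        free = [k for k in names if k not in fix]

        def encode(theta):
            return np.array([math.log(theta[k]) if self._is_log(k) else theta[k] for k in free])

        def decode(x):
            theta = dict(fix)
            for k, xv in zip(free, x):
                theta[k] = math.exp(xv) if self._is_log(k) else xv
            return theta

        warm = {"etas": None}

        def objective(x):
            if np.any(np.abs(x) > 12.0):
                return 1e10 + float(np.sum(np.abs(x)))
            try:
                obj = self._objective_for(decode(x))
                etas, m0, H = _conditional_modes(obj, eta0=warm["etas"])
                warm["etas"] = etas
                val = _laplace_ofv(m0, H, obj.active)
            except (ValidationError, FloatingPointError, ValueError):
                return 1e10
            if not np.isfinite(val):
                return 1e10
            return val

        x0 = encode(theta0)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore", under="ignore"):
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxfev": maxfev, "fatol": 1e-4, "xatol": 1e-4, "adaptive": True},
            )
            for _ in range(max(restarts, 0)):
                prev = res.fun
                res2 = optimize.minimize(
                    objective, res.x, method="Nelder-Mead",
                    options={"maxfev": maxfev, "fatol": 1e-4, "xatol": 1e-4,
                             "adaptive": True},
                )
                if res2.fun <= res.fun:
                    res2.nfev += res.nfev
                    res = res2
                if prev - res.fun < 0.1:
                    break
        theta_hat = decode(res.x)
        obj = self._objective_for(theta_hat)
        etas, m0, H = _conditional_modes(obj, eta0=warm["etas"])
        ofv = _laplace_ofv(m0, H, obj.active)
        if not np.isfinite(ofv):
            etas, m0, H = _conditional_modes(obj)
            ofv = _laplace_ofv(m0, H, obj.active)
        boundary = any(
            theta_hat[k] < 1e-3 for k in ("omega_sd_cl", "omega_sd_v1") if k in free
        )
        converged = bool(res.success and np.isfinite(ofv))

        se = {k: float("nan") for k in names}
        if compute_rse and converged:
            se_free = self._standard_errors(theta_hat, free, fix)
            se.update(se_free)
        rse = {
            k: (100.0 * se[k] / abs(theta_hat[k])
                if np.isfinite(se[k]) and theta_hat[k] != 0 else float("nan"))
            for k in names
        }

        params = PopulationParameters(
            cl_nr=theta_hat["cl_nr"],
            # without the renal covariate the slope is structurally absent;
            # an epsilon keeps the container's positivity invariant
            cl_r_slope=theta_hat.get("cl_r_slope", 1e-12),
            v1=theta_hat["v1"], q=theta_hat["q"], v2=theta_hat["v2"],
            omega_cl=theta_hat["omega_sd_cl"] ** 2,
            omega_v1=theta_hat["omega_sd_v1"] ** 2,
            sigma_add=theta_hat["sigma_add"], sigma_prop=theta_hat["sigma_prop"],
        )
        hepatic_betas = {h: theta_hat[f"beta_{h}"] for h in self.spec.hepatic_on_cl}

        eta_df = pd.DataFrame(
            {"ID": self._pk.ids, "eta_cl": etas[:, 0], "eta_v1": etas[:, 1]}
        )
        shrinkage = self._shrinkage(theta_hat, obj, etas)
        return PopPKResults(
            model=self, spec=self.spec, params=params, hepatic_betas=hepatic_betas,
            estimates=dict(theta_hat), ofv=float(ofv), se=se, rse=rse, etas=eta_df,
            shrinkage=shrinkage, converged=converged, boundary=boundary,
            nfev=int(res.nfev), message=str(res.message),
        )

    def _standard_errors(self, theta: dict[str, float], free: list[str],
                         fix: dict[str, float]) -> dict[str, float]:
        """SEs from the inverse central-difference Hessian of the OFV."""
        p = len(free)
        x = np.array([theta[k] for k in free])
        # steps sized against OFV curvature, not machine noise: the inner
        # optimisation leaves ~1e-8 jitter on the OFV, so tiny steps make
        # the off-diagonal differences pure noise
        hs = np.maximum(1e-2 * np.abs(x), 1e-4)

        def f(xv):
            th = dict(fix)
            th.update({k: v for k, v in zip(free, xv)})
            try:
                obj = self._objective_for(th)
                etas, m0, H = _conditional_modes(obj)
                return _laplace_ofv(m0, H, obj.active)
            except (ValidationError, FloatingPointError, ValueError):
                return float("nan")

        f0 = f(x)
        hess = np.empty((p, p))
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            xi = x.copy(); xi[i] += hs[i]; fp[i] = f(xi)
            xi = x.copy(); xi[i] -= hs[i]; fm[i] = f(xi)
            hess[i, i] = (fp[i] + fm[i] - 2 * f0) / hs[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                xpp = x.copy(); xpp[[i, j]] += hs[[i, j]]
                xmm = x.copy(); xmm[[i, j]] -= hs[[i, j]]
                xpm = x.copy(); xpm[i] += hs[i]; xpm[j] -= hs[j]
                xmp = x.copy(); xmp[i] -= hs[i]; xmp[j] += hs[j]
                hess[i, j] = hess[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * hs[i] * hs[j])
        out = {}
        try:
            cov = 2.0 * np.linalg.inv(hess)
            diag = np.diag(cov)
            for k, v in zip(free, diag):
                out[k] = math.sqrt(v) if v > 0 else float("nan")
        except np.linalg.LinAlgError:
            out = {k: float("nan") for k in free}
        return out

    def _shrinkage(self, theta: dict[str, float], obj: _InnerObjective,
                   etas: np.ndarray) -> dict[str, float]:
        out = {}
        for k, key in enumerate(("omega_sd_cl", "omega_sd_v1")):
            w = theta[key]
            label = f"eta_{'cl' if k == 0 else 'v1'}"
            if w <= 0:
                out[label] = float("nan")
                continue
            sd = float(np.std(etas[:, k], ddof=1))
            out[label] = float(np.clip((1.0 - sd / w) * 100.0, 0.0, 100.0))
        f = obj.individual_pred(etas)
        f = np.where(obj.pk.mask, f, 1.0)
        v = theta["sigma_prop"] ** 2 + (theta["sigma_add"] / f) ** 2
        iw = (obj.pk.logy - np.log(f)) / np.sqrt(v)
        iw = iw[obj.pk.mask]
        out["epsilon"] = float(np.clip((1.0 - np.std(iw, ddof=1)) * 100.0, 0.0, 100.0))
        return out


@dataclass
class PopPKResults:
    """Estimation results: estimates, uncertainties, EB etas, diagnostics."""

    model: PopPKModel
    spec: ModelSpec
    params: PopulationParameters
    hepatic_betas: dict[str, float]
    estimates: dict[str, float]
    ofv: float
    se: dict[str, float]
    rse: dict[str, float]
    etas: pd.DataFrame
    shrinkage: dict[str, float]
    converged: bool
    boundary: bool
    nfev: int
    message: str = ""

    _ROW_LABELS = {
        "cl_nr": ("CL_NR (L/h)", 1.0),
        "cl_r_slope": ("CL_R slope (L/h per Clcr/44)", 1.0),
        "v1": ("V1 (L)", 1.0),
        "q": ("Q (L/h)", 1.0),
        "v2": ("V2 (L)", 1.0),
        "omega_sd_cl": ("IIV_CL (%CV)", 100.0),
        "omega_sd_v1": ("IIV_V1 (%CV)", 100.0),
        "sigma_add": ("Residual additive (mg/L)", 1.0),
        "sigma_prop": ("Residual proportional (fraction)", 1.0),
    }

    def summary(self) -> str:
        """Human-readable estimate table (estimate, RSE%, shrinkage)."""
        lines = [
            "Population PK model fit",
            f"  covariates on CL: {', '.join(self.spec.covariates) or 'none'}"
            " (+ fixed per-subject CL_EC)",
            f"  subjects: {self.model._pk.n}   observations: {self.model._pk.n_obs}",
            f"  OFV: {self.ofv:.3f}   converged: {self.converged}"
            + ("   [boundary]" if self.boundary else ""),
            "",
            f"  {'Parameter':<34}{'Estimate':>12}{'RSE (%)':>10}",
        ]
        for key in self.model.param_names:
            label, scale = self._ROW_LABELS.get(key, (key, 1.0))
            est = self.estimates[key] * scale
            rse = self.rse.get(key, float("nan"))
            rse_s = f"{rse:.0f}" if np.isfinite(rse) else "-"
            lines.append(f"  {label:<34}{est:>12.4g}{rse_s:>10}")
        lines.append("")
        lines.append(
            "  shrinkage (%): "
            + ", ".join(f"{k}={v:.1f}" for k, v in self.shrinkage.items())
        )
        return "\n".join(lines)

    # convenience delegations ------------------------------------------
    def iwres(self) -> pd.DataFrame:
        from .diagnostics import iwres
        return iwres(self.model, self)

    def cwres(self) -> pd.DataFrame:
        from .diagnostics import cwres
        return cwres(self.model, self)

    def vpc(self, n_sim: int = 1000, seed: int = 0, **kw):
        from .diagnostics import vpc
        return vpc(self.model, self, n_sim=n_sim, seed=seed, **kw)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, np.bool_):
                return bool(x)
            return x

        return clean({
            "ofv": self.ofv,
            "converged": self.converged,
            "boundary": self.boundary,
            "estimates": self.estimates,
            "rse": self.rse,
            "shrinkage": self.shrinkage,
            "hepatic_betas": self.hepatic_betas,
            "etas": self.etas.to_dict(orient="list"),
        })


# ---------------------------------------------------------------------------
# module-level conveniences mirroring the pipeline surface

def fit(dataset, spec: ModelSpec = ModelSpec(), start=None, **kwargs) -> PopPKResults:
    """Fit the population model to a dataset (see :meth:`PopPKModel.fit`)."""
    return PopPKModel(dataset, spec).fit(start=start, **kwargs)


def ofv(dataset, params: PopulationParameters, spec: ModelSpec = ModelSpec(),
        hepatic_betas: dict[str, float] | None = None) -> float:
    """Laplace OFV of a dataset at fixed population parameters."""
    return PopPKModel(dataset, spec).ofv(params, hepatic_betas)


def compare_models(fit_reduced: PopPKResults | float, fit_full: PopPKResults | float,
                   df: int) -> float:
    """Likelihood-ratio p-value for nested fits (chi-square on the OFV drop)."""
    if df < 1:
        raise ValidationError("df must be >= 1")
    red = fit_reduced.ofv if isinstance(fit_reduced, PopPKResults) else float(fit_reduced)
    full = fit_full.ofv if isinstance(fit_full, PopPKResults) else float(fit_full)
    drop = red - full
    if drop < 0:
        warnings.warn("full model has higher OFV than reduced; returning p = 1", stacklevel=2)
        return 1.0
    return float(stats.chi2.sf(drop, df))


@dataclass
class SCMResult:
    steps: list[CovariateStep]
    final: PopPKResults

    @property
    def selected(self) -> tuple[str, ...]:
        return self.final.spec.covariates


def _candidate_identifiable(model: PopPKModel, name: str) -> bool:
    pk = model._pk
    col = pk.clcr44 if name == "clcr" else pk.hep[:, {"hep_ge1": 0, "hep_ge2": 1, "hep_eq3": 2}[name]]
    return float(np.std(col)) > 1e-12


def scm(dataset, base_spec: ModelSpec = ModelSpec(clcr_on_cl=False),
        candidates: tuple[str, ...] = ("clcr", "hep_ge1", "hep_ge2", "hep_eq3"),
        forward_alpha: float = 0.05, backward_alpha: float = 0.01,
        start=None, final_rse: bool = True, **fit_kwargs) -> SCMResult:
    """Stepwise covariate model building: forward inclusion then backward
    deletion with likelihood-ratio tests (df = 1 per covariate).

    Forward keeps the best candidate while the OFV drop exceeds the
    ``forward_alpha`` chi-square cutoff (3.84 at 0.05); backward removes any
    retained covariate whose removal worsens the OFV by less than the
    ``backward_alpha`` cutoff (6.63 at 0.01).  Ties break on larger OFV drop,
    then lexicographic name.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = DatasetTable(dataset)
    fwd_cut = float(stats.chi2.isf(forward_alpha, 1))
    bwd_cut = float(stats.chi2.isf(backward_alpha, 1))
    steps: list[CovariateStep] = []

    current_spec = base_spec
    current = PopPKModel(dataset, current_spec).fit(start=start, compute_rse=False,
                                                    **fit_kwargs)
    remaining = list(candidates)
    for name in list(remaining):
        if name == "clcr" and base_spec.clcr_on_cl:
            remaining.remove(name)
        elif not _candidate_identifiable(current.model, name):
            warnings.warn(f"candidate {name!r} is constant across subjects; skipped",
                          stacklevel=2)
            remaining.remove(name)

    while remaining:
        trials = []
        for name in sorted(remaining):
            spec_try = current_spec.with_covariate(name)
            res_try = PopPKModel(dataset, spec_try).fit(
                start={**current.estimates}, compute_rse=False,
                **{"restarts": 0, **{k: v for k, v in fit_kwargs.items()
                                     if k != "restarts"}})
            delta = res_try.ofv - current.ofv
            trials.append((name, res_try, delta))
        # best = largest OFV drop; ties by name (sorted order is stable)
        name, res_best, delta = min(trials, key=lambda t: (t[2], t[0]))
        for nm, _, dl in trials:
            steps.append(CovariateStep(nm, "forward", dl, 1,
                                       float(stats.chi2.sf(max(-dl, 0.0), 1)),
                                       included=(nm == name and -dl > fwd_cut)))
        if -delta > fwd_cut:
            current_spec = current_spec.with_covariate(name)
            current = res_best
            remaining.remove(name)
        else:
            break

    # backward deletion: repeatedly drop the least-supported covariate unless
    # its removal worsens the OFV beyond the stricter cutoff
    only_forward_included = [n for n in current_spec.covariates
                             if n in candidates or (n == "clcr" and "clcr" in candidates)]
    while only_forward_included:
        drops = []
        for name in sorted(only_forward_included):
            spec_try = current_spec.without_covariate(name)
            res_try = PopPKModel(dataset, spec_try).fit(
                start={**current.estimates}, compute_rse=False,
                **{"restarts": 0, **{k: v for k, v in fit_kwargs.items()
                                     if k != "restarts"}})
            worsening = res_try.ofv - current.ofv   # >= 0 where the covariate helps
            drops.append((worsening, name, res_try))
        worsening, name, res_try = min(drops, key=lambda t: (t[0], t[1]))
        if worsening <= bwd_cut:
            steps.append(CovariateStep(name, "backward", worsening, 1,
                                       float(stats.chi2.sf(max(worsening, 0.0), 1)),
                                       included=False))
            current_spec = current_spec.without_covariate(name)
            current = res_try
            only_forward_included.remove(name)
        else:
            for w, nm, _ in sorted(drops):
                steps.append(CovariateStep(nm, "backward", w, 1,
                                           float(stats.chi2.sf(w, 1)), included=True))
            break

    if final_rse:
        # refit the surviving model once with standard errors
        current = PopPKModel(dataset, current_spec).fit(
            start={**current.estimates}, **fit_kwargs)
    return SCMResult(steps, current)


@dataclass
class BootstrapResult:
    """Nonparametric (subject-resampling) bootstrap summaries."""

    estimates: pd.DataFrame       # one row per replicate
    summary: pd.DataFrame         # median and 5th/95th percentiles per parameter
    n_failed: int
    b: int
    reliable: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"BootstrapResult(b={self.b}, n_failed={self.n_failed}, "
                f"reliable={self.reliable})\n{self.summary}")


def bootstrap(dataset, spec: ModelSpec = ModelSpec(), b: int = 2000, seed: int = 0,
              fit_result: PopPKResults | None = None, **fit_kwargs) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the model fit.

    Resamples subjects with replacement (preserving n), refits each replicate
    starting from the original estimates, and reports per-parameter median and
    5th-95th percentiles.  Flagged unreliable if > 20% of replicates fail.
    """
    if b < 1:
        raise ValidationError("b must be >= 1")
    if isinstance(dataset, pd.DataFrame):
        dataset = DatasetTable(dataset)
    model = PopPKModel(dataset, spec)
    if fit_result is None:
        fit_result = model.fit(compute_rse=False, **fit_kwargs)
    rng = np.random.default_rng(seed)
    ids = sorted(dataset.df["ID"].unique())
    rows = []
    n_failed = 0
    for _ in range(b):
        draw = rng.choice(ids, size=len(ids), replace=True)
        sub = dataset.resample_subjects(draw)
        try:
            res = PopPKModel(sub, spec).fit(start={**fit_result.estimates},
                                            compute_rse=False, **fit_kwargs)
            ok = res.converged
        except ValidationError:
            ok = False
        if not ok:
            n_failed += 1
            continue
        rows.append(dict(res.estimates))
    est = pd.DataFrame(rows)
    if len(est):
        summ = pd.DataFrame({
            "median": est.median(),
            "p5": est.quantile(0.05),
            "p95": est.quantile(0.95),
        })
    else:
        summ = pd.DataFrame(columns=["median", "p5", "p95"])
    reliable = n_failed <= 0.2 * b
    if not reliable:
        warnings.warn(f"bootstrap unreliable: {n_failed}/{b} replicates failed", stacklevel=2)
    return BootstrapResult(est, summ, n_failed, b, reliable)
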