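"""Synthetic-cohort generator emulating the clinical study design.

Two presets are provided: the model-building cohort (40 ICU subjects, 23 on
CRRT, 600 mg q12h 30-min infusions sampled densely at steady state, with
paired effluent samples for CRRT subjects) and the continuous-infusion
validation cohort (11 subjects, 600 mg loading + 50 mg/h, one sample per day
over four days).  Covariate laws are parametric stand-ins matched to the
published medians and ranges — the study reports no full distributions — so
the generator is an emulation of the design, not an inference about it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DatasetTable, EFFLUENT_CMT, PLASMA_CMT, SubjectRecord
from .pkmodel import concentration, continuous_regimen, intermittent_regimen, observe
from .types import (
    DosingEvent,
    IndividualParameters,
    PopulationParameters,
    REFERENCE_PARAMS,
    SubjectCovariates,
    ValidationError,
    _require,
)

#: Protocol sampling times (h after the monitored dose): pre-dose, end of
#: 30-min infusion, then 1, 2, 3, 6, a draw in the 8-10 h window, and 12 h.
STUDY_SCHEDULE: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 6.0, (8.0, 10.0), 12.0)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``clcr_no_crrt`` / ``clcr_crrt`` are (median, low, high) triplets for the
    creatinine-clearance laws of the two arms; ``sc_law`` is
    (mean, sd, low, high) for the truncated-normal sieving coefficient and
    ``qef_range`` the uniform effluent-flow support in L/h.  ``schedule``
    holds within-interval sampling times (a (lo, hi) tuple marks a windowed
    sample); for the continuous regimen the schedule is absolute hours.
    """

    n_subjects: int = 40
    crrt_fraction: float = 23.0 / 40.0
    clcr_no_crrt: tuple[float, float, float] = (71.2, 11.0, 179.5)
    clcr_crrt: tuple[float, float, float] = (6.0, 0.0, 45.6)
    sc_law: tuple[float, float, float, float] = (0.8, 0.1, 0.5, 1.1)
    qef_range: tuple[float, float] = (1.1, 3.3)
    regimen: str = "intermittent"
    schedule: tuple = STUDY_SCHEDULE
    seed: int = 0
    loq_plasma: float = 0.5
    loq_effluent: float = 0.2
    male_fraction: float = 29.0 / 40.0
    infusion_duration_overrides: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 1, "n_subjects must be >= 1")
        _require(0.0 <= self.crrt_fraction <= 1.0, "crrt_fraction must be in [0, 1]")
        _require(self.regimen in ("intermittent", "continuous"),
                 f"unknown regimen {self.regimen!r}")
        for t in self.schedule:
            tv = t if not isinstance(t, tuple) else t[0]
            _require(tv >= 0, "schedule times must be >= 0")
        lo, hi = self.sc_law[2], self.sc_law[3]
        _require(lo < hi, "empty sieving-coefficient support")
        _require(self.clcr_no_crrt[1] < self.clcr_no_crrt[2], "empty Clcr support")
        _require(self.clcr_crrt[1] < self.clcr_crrt[2], "empty Clcr support")

    @classmethod
    def study(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """The 40-subject intermittent-infusion model-building design."""
        return replace(cls(seed=seed), **overrides)

    @classmethod
    def validation(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """The 11-subject continuous-infusion external-validation design."""
        base = cls(
            n_subjects=11, crrt_fraction=0.0,
            clcr_no_crrt=(111.0, 45.0, 240.0),
            regimen="continuous", schedule=(24.0, 48.0, 72.0, 96.0),
            seed=seed,
        )
        return replace(base, **overrides)


def _trunc_lognormal(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float, size: int) -> np.ndarray:
    """Log-normal with the given median, rejection-truncated to [lo, hi]."""
    mu = math.log(median)
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.lognormal(mu, sigma, size=4 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
        if filled == size:
            return out
    raise ValidationError("truncated sampling failed; support too narrow")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=4 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
        if filled == size:
            return out
    raise ValidationError("truncated sampling failed; support too narrow")


def _trunc_exponential(rng: np.random.Generator, median: float, lo: float,
                       hi: float, size: int) -> np.ndarray:
    scale = median / math.log(2.0)
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.exponential(scale, size=4 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
        if filled == size:
            return out
    raise ValidationError("truncated sampling failed; support too narrow")


def sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectCovariates]:
    """Draw subject covariates under the cohort design.

    The CRRT arm size is exact (``round(crrt_fraction * n)``).  Non-CRRT Clcr
    is log-normal matched to the published median; CRRT Clcr is exponential
    (mostly oligo/anuric patients) matched to its median; both truncated to
    the published ranges.  Sc is truncated normal, Qef uniform.
    """
    n = spec.n_subjects
    n_crrt = int(round(spec.crrt_fraction * n))
    crrt_flags = np.array([True] * n_crrt + [False] * (n - n_crrt))

    med, lo, hi = spec.clcr_no_crrt
    clcr_no = _trunc_lognormal(rng, med, 0.55, lo, hi, n - n_crrt)
    med_c, lo_c, hi_c = spec.clcr_crrt
    clcr_c = _trunc_exponential(rng, med_c, lo_c, hi_c, n_crrt)
    sc = _trunc_normal(rng, spec.sc_law[0], spec.sc_law[1], spec.sc_law[2],
                       spec.sc_law[3], n_crrt)
    qef = rng.uniform(spec.qef_range[0], spec.qef_range[1], size=n_crrt)

    sexes = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    weight = _trunc_normal(rng, 73.0, 12.0, 50.0, 115.0, n)
    bili = _trunc_lognormal(rng, 0.7, 0.5, 0.1, 2.6, n)
    got = _trunc_lognormal(rng, 38.0, 0.8, 5.0, 700.0, n)
    gpt = _trunc_lognormal(rng, 35.0, 0.9, 5.0, 600.0, n)

    out = []
    i_c = i_n = 0
    for i in range(n):
        if crrt_flags[i]:
            cov = SubjectCovariates(
                subject_id=i + 1, clcr=float(clcr_c[i_c]), crrt=True,
                sc=float(sc[i_c]), qef=float(qef[i_c]), sex=str(sexes[i]),
                body_weight=float(weight[i]), bilirubin=float(bili[i]),
                got=float(got[i]), gpt=float(gpt[i]),
            )
            i_c += 1
        else:
            cov = SubjectCovariates(
                subject_id=i + 1, clcr=float(clcr_no[i_n]), crrt=False,
                sex=str(sexes[i]), body_weight=float(weight[i]),
                bilirubin=float(bili[i]), got=float(got[i]), gpt=float(gpt[i]),
            )
            i_n += 1
        out.append(cov)
    return out


def make_regimen(kind: str, infusion_duration: float = 0.5) -> list[DosingEvent]:
    """Dosing events for a named regimen.

    ``intermittent``: eight 600 mg infusions (default 30 min) 12 h apart, so
    sampling after the last dose is effectively at steady state.
    ``continuous``: 600 mg loading over 30 min then 50 mg/h for 96 h
    (1200 mg/day).
    """
    if kind == "intermittent":
        return intermittent_regimen(n_doses=8, amount=600.0, interval=12.0,
                                    duration=infusion_duration)
    if kind == "continuous":
        return continuous_regimen(loading=600.0, loading_duration=infusion_duration,
                                  rate=50.0, maintenance_hours=96.0)
    raise ValidationError(f"unknown regimen kind {kind!r}")


def _draw_schedule(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    times = []
    for t in spec.schedule:
        if isinstance(t, tuple):
            times.append(rng.uniform(t[0], t[1]))
        else:
            times.append(float(t))
    return np.array(times)


def simulate_dataset(
    cohort: list[SubjectCovariates],
    regimen_kind: str,
    params: PopulationParameters = REFERENCE_PARAMS,
    rng: np.random.Generator | None = None,
    spec: CohortSpec | None = None,
) -> DatasetTable:
    """Simulate a longitudinal dataset for a cohort under a regimen.

    Per subject: draw (eta_cl, eta_v1), evaluate the structural model at the
    schedule times, apply the combined residual-error model, and flag records
    below the assay quantification limit (plasma 0.5, effluent 0.2 mg/L) as
    BLQ with a censored DV.  CRRT subjects on the intermittent design get
    paired effluent records (Sc times the plasma truth, same error model).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    spec = spec if spec is not None else (
        CohortSpec.study() if regimen_kind == "intermittent" else CohortSpec.validation()
    )
    overrides = dict(spec.infusion_duration_overrides)
    records = []
    for cov in cohort:
        dur = overrides.get(cov.subject_id, 0.5)
        doses = make_regimen(regimen_kind, infusion_duration=dur)
        eta_cl = rng.normal(0.0, math.sqrt(params.omega_cl)) if params.omega_cl > 0 else 0.0
        eta_v1 = rng.normal(0.0, math.sqrt(params.omega_v1)) if params.omega_v1 > 0 else 0.0
        ind = IndividualParameters.from_population(params, cov, eta_cl, eta_v1)
        rel_times = _draw_schedule(spec, rng)
        if regimen_kind == "intermittent":
            t_obs = doses[-1].start_time + rel_times
        else:
            t_obs = rel_times
        f = concentration(ind, doses, t_obs)
        y = observe(f, params.sigma_add, params.sigma_prop, rng)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        blq = (y < spec.loq_plasma) | (y <= 0)
        obs_rows = [{"TIME": float(t), "DV": (np.nan if b else float(v)),
                     "CMT": PLASMA_CMT, "BLQ": int(b)}
                    for t, v, b in zip(t_obs, y, blq)]
        if cov.crrt and regimen_kind == "intermittent":
            f_ef = cov.sc * np.asarray(f)
            y_ef = np.atleast_1d(np.asarray(
                observe(f_ef, params.sigma_add, params.sigma_prop, rng), dtype=float))
            blq_ef = (y_ef < spec.loq_effluent) | (y_ef <= 0)
            obs_rows += [{"TIME": float(t), "DV": (np.nan if b else float(v)),
                          "CMT": EFFLUENT_CMT, "BLQ": int(b)}
                         for t, v, b in zip(t_obs, y_ef, blq_ef)]
        obs = pd.DataFrame(obs_rows).sort_values(["TIME", "CMT"], kind="stable")
        records.append(SubjectRecord(cov, doses, obs.reset_index(drop=True)))
    return DatasetTable.from_subjects(records)


def generate(spec: CohortSpec, params: PopulationParameters = REFERENCE_PARAMS,
             seed: int | None = None) -> DatasetTable:
    """Covariates + simulation in one call, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cohort = sample_covariates(spec, rng)
    return simulate_dataset(cohort, spec.regimen, params, rng, spec)
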