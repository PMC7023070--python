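"""Bedside-derived clearance covariates.

Urine-based creatinine clearance, the CRRT sieving coefficient from paired
plasma/effluent AUCs over a dosing interval, extracorporeal clearance, and the
dichotomous hepatic-dysfunction flags used in covariate screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ValidationError, _require

#: Sex-specific normal ranges for the hepatic markers (low, high).
BILIRUBIN_RANGE = (0.3, 1.9)              # mg/dL, both sexes
GOT_RANGE = {"M": (8.0, 30.0), "F": (6.0, 25.0)}   # U/L
GPT_RANGE = {"M": (8.0, 35.0), "F": (6.0, 25.0)}   # U/L


def estimate_clcr(cru: float, vu: float, crp: float) -> float:
    """Creatinine clearance (mL/min) from a 10-h timed urine collection.

    ``Clcr = (Cru * Vu) / (Crp * 600 min)`` with urine creatinine ``cru``
    (mg/dL), urine volume ``vu`` (mL) and plasma creatinine ``crp`` (mg/dL).
    """
    _require(crp > 0, f"plasma creatinine must be > 0, got {crp}")
    _require(cru >= 0, f"urine creatinine must be >= 0, got {cru}")
    _require(vu >= 0, f"urine volume must be >= 0, got {vu}")
    return (cru * vu) / (crp * 600.0)


@dataclass(frozen=True)
class PairedProfiles:
    """Paired plasma/effluent concentrations on a shared time grid (one
    dosing interval), used to estimate the sieving coefficient."""

    times: np.ndarray
    plasma: np.ndarray
    effluent: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.plasma, dtype=float)
        e = np.asarray(self.effluent, dtype=float)
        _require(t.ndim == 1 and t.size >= 2, "need >= 2 time points")
        _require(p.shape == t.shape and e.shape == t.shape, "times/plasma/effluent lengths differ")
        _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
        _require(bool(np.all(p >= 0)) and bool(np.all(e >= 0)), "concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "plasma", p)
        object.__setattr__(self, "effluent", e)


def sieving_coefficient(profiles: PairedProfiles) -> float:
    """Sieving coefficient Sc = AUC_effluent / AUC_plasma.

    Both AUCs use the linear trapezoid on the shared grid (interpolation bias
    largely cancels in the ratio).  Values above 1.2 — physically implausible
    but possible under measurement noise — trigger a warning.
    """
    auc_p = float(np.trapezoid(profiles.plasma, profiles.times))
    auc_e = float(np.trapezoid(profiles.effluent, profiles.times))
    if auc_p <= 0:
        raise ValidationError("plasma AUC must be > 0")
    sc = auc_e / auc_p
    if sc > 1.2:
        warnings.warn(f"sieving coefficient {sc:.3g} > 1.2 (check assay)", stacklevel=2)
    return sc


def extracorporeal_clearance(sc: float, qef: float) -> float:
    """Extracorporeal clearance (L/h): sieving coefficient times effluent flow."""
    _require(sc >= 0, f"sc must be >= 0, got {sc}")
    _require(qef >= 0, f"qef must be >= 0, got {qef}")
    return sc * qef


def build_hepatic_flags(
    bilirubin: float, got: float, gpt: float, sex: str
) -> tuple[bool, bool, bool]:
    """Dichotomous hepatic-dysfunction covariates.

    Counts how many of bilirubin, GOT and GPT fall outside their sex-specific
    normal ranges; returns flags for (>= 1, >= 2, == 3) abnormal markers.
    """
    _require(sex in ("M", "F"), f"sex must be 'M' or 'F', got {sex!r}")
    for name, val in (("bilirubin", bilirubin), ("got", got), ("gpt", gpt)):
        _require(val >= 0, f"{name} must be >= 0, got {val}")
    n_abn = 0
    for val, (lo, hi) in (
        (bilirubin, BILIRUBIN_RANGE),
        (got, GOT_RANGE[sex]),
        (gpt, GPT_RANGE[sex]),
    ):
        if not (lo <= val <= hi):
            n_abn += 1
    return (n_abn >= 1, n_abn >= 2, n_abn == 3)
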