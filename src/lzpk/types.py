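"""Domain types for the linezolid population-PK pipeline.

Units follow ICU bedside convention throughout the package: concentrations in
mg/L (identical to ug/mL), volumes in L, clearances in L/h, times in hours,
creatinine clearance (Clcr) in mL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: Clcr value (mL/min) that normalises the renal-clearance covariate term.
#: Fixed by the final covariate model, not recentred to any sample median.
CLCR_REF = 44.0


class ValidationError(ValueError):
    """Raised when a domain object or operation input violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, inter-individual variances and residual error terms.

    Total typical clearance is ``cl_nr + cl_r_slope * (clcr / 44) + cl_ec``
    where ``cl_ec = sc * qef`` is the per-subject extracorporeal clearance
    (zero without CRRT).  Random effects act multiplicatively:
    ``CL_i = TVCL * exp(eta_cl)``, ``V1_i = v1 * exp(eta_v1)``.

    Parameters
    ----------
    cl_nr : float
        Non-renal clearance (L/h).
    cl_r_slope : float
        Renal clearance at the reference Clcr of 44 mL/min (L/h); the renal
        component is ``cl_r_slope * clcr / 44``.
    v1, v2 : float
        Central and peripheral volumes of distribution (L).
    q : float
        Inter-compartmental clearance (L/h).
    omega_cl, omega_v1 : float
        Variances of the log-scale random effects on CL and V1.
    sigma_add : float
        Additive residual SD on the natural concentration scale (mg/L).
    sigma_prop : float
        Proportional residual SD (fraction of the prediction).
    """

    cl_nr: float
    cl_r_slope: float
    v1: float
    q: float
    v2: float
    omega_cl: float = 0.0
    omega_v1: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_nr", "cl_r_slope", "v1", "q", "v2"):
            val = getattr(self, name)
            _require(math.isfinite(val) and val > 0, f"{name} must be finite and > 0, got {val}")
        for name in ("omega_cl", "omega_v1", "sigma_add", "sigma_prop"):
            val = getattr(self, name)
            _require(math.isfinite(val) and val >= 0, f"{name} must be finite and >= 0, got {val}")
        _require(
            self.sigma_add > 0 or self.sigma_prop > 0,
            "at least one residual error component must be positive",
        )

    @property
    def iiv_cl_cv(self) -> float:
        """IIV of CL as %CV, ``sqrt(omega_cl) * 100``."""
        return math.sqrt(self.omega_cl) * 100.0

    @property
    def iiv_v1_cv(self) -> float:
        """IIV of V1 as %CV, ``sqrt(omega_v1) * 100``."""
        return math.sqrt(self.omega_v1) * 100.0


#: Published population estimates for linezolid in critically ill adults
#: (600 mg q12h, 30-min IV infusion; cohort including CRRT patients).  Used as
#: the default generating truth for synthetic cohorts.
REFERENCE_PARAMS = PopulationParameters(
    cl_nr=2.62,
    cl_r_slope=4.35,
    v1=16.2,
    q=71.7,
    v2=29.0,
    omega_cl=0.615**2,
    omega_v1=0.659**2,
    sigma_add=0.266,
    sigma_prop=0.159,
)


@dataclass(frozen=True)
class SubjectCovariates:
    """Bedside covariates for one subject.

    ``sc`` (sieving coefficient) and ``qef`` (effluent flow, L/h) must be set
    iff the subject is on CRRT; extracorporeal clearance is ``sc * qef``.
    """

    subject_id: int | str
    clcr: float
    crrt: bool = False
    sc: float | None = None
    qef: float | None = None
    sex: str = "M"
    body_weight: float | None = None
    bilirubin: float | None = None
    got: float | None = None
    gpt: float | None = None

    def __post_init__(self) -> None:
        _require(math.isfinite(self.clcr) and self.clcr >= 0, f"clcr must be >= 0, got {self.clcr}")
        _require(self.sex in ("M", "F"), f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.crrt:
            _require(self.sc is not None and self.qef is not None, "CRRT subjects need sc and qef")
            _require(self.sc >= 0, f"sc must be >= 0, got {self.sc}")
            _require(self.qef >= 0, f"qef must be >= 0, got {self.qef}")
        else:
            _require(
                self.sc is None and self.qef is None,
                "sc/qef only apply to CRRT subjects",
            )

    @property
    def cl_ec(self) -> float:
        """Extracorporeal clearance (L/h): ``sc * qef`` on CRRT, else 0."""
        if not self.crrt:
            return 0.0
        return self.sc * self.qef  # type: ignore[operator]


@dataclass(frozen=True)
class DosingEvent:
    """A constant-rate IV infusion: ``amount`` mg over ``duration`` h.

    A 30-min infusion has ``duration=0.5``; continuous infusion is a single
    long-duration event.  Overlapping events are allowed (superposition).
    """

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.start_time) and self.start_time >= 0,
                 f"start_time must be >= 0, got {self.start_time}")
        _require(math.isfinite(self.amount) and self.amount > 0,
                 f"amount must be > 0, got {self.amount}")
        _require(math.isfinite(self.duration) and self.duration > 0,
                 f"duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate (mg/h)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class IndividualParameters:
    """Realised subject-level PK parameters.

    ``cl = TVCL * exp(eta_cl)`` and ``v1 = TVV1 * exp(eta_v1)``; ``q`` and
    ``v2`` are population values (no IIV).  ``eta = 0`` reproduces the
    typical-value parameters exactly.
    """

    cl: float
    v1: float
    q: float
    v2: float
    eta_cl: float = 0.0
    eta_v1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            val = getattr(self, name)
            _require(math.isfinite(val) and val > 0, f"{name} must be finite and > 0, got {val}")
        for name in ("eta_cl", "eta_v1"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")

    @classmethod
    def from_population(
        cls,
        params: PopulationParameters,
        cov: SubjectCovariates,
        eta_cl: float = 0.0,
        eta_v1: float = 0.0,
    ) -> "IndividualParameters":
        """Realise individual parameters from population values + covariates."""
        from .pkmodel import typical_clearance  # local import avoids a cycle

        tvcl = typical_clearance(params, cov)
        return cls(
            cl=tvcl * math.exp(eta_cl),
            v1=params.v1 * math.exp(eta_v1),
            q=params.q,
            v2=params.v2,
            eta_cl=eta_cl,
            eta_v1=eta_v1,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices for estimation.

    ``clcr_on_cl`` switches the renal covariate term on CL (the final model
    has it; the base model does not).  ``hepatic_on_cl`` lists dichotomous
    hepatic-dysfunction flags entering CL multiplicatively as
    ``exp(beta * flag)``; names from {'hep_ge1', 'hep_ge2', 'hep_eq3'}.
    Extracorporeal clearance always enters as a fixed per-subject offset.
    """

    clcr_on_cl: bool = True
    hepatic_on_cl: tuple[str, ...] = ()

    _HEPATIC = ("hep_ge1", "hep_ge2", "hep_eq3")

    def __post_init__(self) -> None:
        for name in self.hepatic_on_cl:
            _require(name in self._HEPATIC, f"unknown hepatic flag {name!r}")
        _require(len(set(self.hepatic_on_cl)) == len(self.hepatic_on_cl),
                 "duplicate hepatic flags")

    def with_covariate(self, name: str) -> "ModelSpec":
        if name == "clcr":
            _require(not self.clcr_on_cl, "clcr already included")
            return replace(self, clcr_on_cl=True)
        _require(name in self._HEPATIC, f"unknown covariate {name!r}")
        _require(name not in self.hepatic_on_cl, f"{name} already included")
        return replace(self, hepatic_on_cl=tuple(sorted(self.hepatic_on_cl + (name,))))

    def without_covariate(self, name: str) -> "ModelSpec":
        if name == "clcr":
            _require(self.clcr_on_cl, "clcr not included")
            return replace(self, clcr_on_cl=False)
        _require(name in self.hepatic_on_cl, f"{name} not included")
        return replace(self, hepatic_on_cl=tuple(n for n in self.hepatic_on_cl if n != name))

    @property
    def covariates(self) -> tuple[str, ...]:
        out = ("clcr",) if self.clcr_on_cl else ()
        return out + self.hepatic_on_cl
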