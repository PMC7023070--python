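"""NONMEM-dialect dataset table: reader, writer and validation.

One row per event.  ``EVID=1`` rows are infusion doses (``AMT`` mg at ``RATE``
mg/h, so duration = AMT/RATE); ``EVID=0`` rows are observations with ``DV`` in
mg/L.  ``CMT`` is 1 for plasma and 10 for CRRT effluent (kept visibly distinct
from the PK compartments).  ``BLQ=1`` marks observations censored below the
assay quantification limit.  Covariates are carried on every row of a subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import DosingEvent, SubjectCovariates, ValidationError

PLASMA_CMT = 1
EFFLUENT_CMT = 10

REQUIRED_COLUMNS = [
    "ID", "TIME", "EVID", "MDV", "CMT", "AMT", "RATE", "DV", "BLQ",
    "CLCR", "CRRT", "SC", "QEF", "SEX", "WT", "BILI", "GOT", "GPT",
]


@dataclass
class SubjectRecord:
    """Covariates, dosing events and observations for one subject."""

    covariates: SubjectCovariates
    doses: list[DosingEvent]
    observations: pd.DataFrame  # columns TIME, DV, CMT, BLQ


class DatasetTable:
    """Validated longitudinal PK dataset."""

    def __init__(self, df: pd.DataFrame):
        self.df = _validate(df.copy())

    @classmethod
    def read(cls, path: str | Path) -> "DatasetTable":
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_subjects(cls, subjects: Iterable[SubjectRecord]) -> "DatasetTable":
        rows = []
        for rec in subjects:
            cov = rec.covariates
            base = {
                "ID": cov.subject_id,
                "CLCR": cov.clcr,
                "CRRT": int(cov.crrt),
                "SC": cov.sc if cov.crrt else np.nan,
                "QEF": cov.qef if cov.crrt else np.nan,
                "SEX": cov.sex,
                "WT": cov.body_weight if cov.body_weight is not None else np.nan,
                "BILI": cov.bilirubin if cov.bilirubin is not None else np.nan,
                "GOT": cov.got if cov.got is not None else np.nan,
                "GPT": cov.gpt if cov.gpt is not None else np.nan,
            }
            for d in rec.doses:
                rows.append({**base, "TIME": d.start_time, "EVID": 1, "MDV": 1,
                             "CMT": PLASMA_CMT, "AMT": d.amount, "RATE": d.rate,
                             "DV": np.nan, "BLQ": 0})
            for _, o in rec.observations.iterrows():
                rows.append({**base, "TIME": o["TIME"], "EVID": 0,
                             "MDV": int(o["BLQ"]), "CMT": int(o["CMT"]),
                             "AMT": np.nan, "RATE": np.nan,
                             "DV": o["DV"], "BLQ": int(o["BLQ"])})
        df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
        return cls(df)

    def subjects(self) -> list[SubjectRecord]:
        out = []
        for sid, g in self.df.groupby("ID", sort=True):
            first = g.iloc[0]
            crrt = bool(first["CRRT"])
            cov = SubjectCovariates(
                subject_id=sid,
                clcr=float(first["CLCR"]),
                crrt=crrt,
                sc=float(first["SC"]) if crrt else None,
                qef=float(first["QEF"]) if crrt else None,
                sex=str(first["SEX"]),
                body_weight=_opt(first["WT"]),
                bilirubin=_opt(first["BILI"]),
                got=_opt(first["GOT"]),
                gpt=_opt(first["GPT"]),
            )
            dose_rows = g[g["EVID"] == 1]
            doses = [
                DosingEvent(float(r["TIME"]), float(r["AMT"]), float(r["AMT"]) / float(r["RATE"]))
                for _, r in dose_rows.iterrows()
            ]
            obs = g[g["EVID"] == 0][["TIME", "DV", "CMT", "BLQ"]].reset_index(drop=True)
            out.append(SubjectRecord(cov, doses, obs))
        return out

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def resample_subjects(self, ids: Iterable, relabel: bool = True) -> "DatasetTable":
        """New table from the given subject IDs (with repetition allowed).

        Repeated draws get fresh integer IDs so the result is a valid
        dataset of the same size — the bootstrap resampling unit.
        """
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            g = self.df[self.df["ID"] == sid]
            if g.empty:
                raise ValidationError(f"unknown subject id {sid!r}")
            g = g.copy()
            if relabel:
                g["ID"] = new_id
            parts.append(g)
        return DatasetTable(pd.concat(parts, ignore_index=True))


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df[REQUIRED_COLUMNS].reset_index(drop=True)
    for i, row in df.iterrows():
        where = f"row {i} (ID {row['ID']})"
        if not np.isfinite(row["TIME"]) or row["TIME"] < 0:
            raise ValidationError(f"{where}: TIME must be finite and >= 0")
        evid = row["EVID"]
        if evid == 1:
            if not (row["AMT"] > 0):
                raise ValidationError(f"{where}: dose row needs AMT > 0")
            if not (row["RATE"] > 0):
                raise ValidationError(f"{where}: dose row needs RATE > 0")
            if not pd.isna(row["DV"]):
                raise ValidationError(f"{where}: dose row must not carry DV")
        elif evid == 0:
            if pd.isna(row["DV"]) and not row["BLQ"]:
                raise ValidationError(f"{where}: observation needs DV or BLQ flag")
            if row["CMT"] not in (PLASMA_CMT, EFFLUENT_CMT):
                raise ValidationError(f"{where}: CMT must be {PLASMA_CMT} or {EFFLUENT_CMT}")
        else:
            raise ValidationError(f"{where}: EVID must be 0 or 1")
    for sid, g in df.groupby("ID"):
        t = g["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"subject {sid!r}: times not sorted")
    return df
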