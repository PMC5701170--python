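"""Domain types and event-record dataset I/O for continuous-infusion PK studies.

The study design emulated here is a sparse-sampling population PK study of a
drug given by open-ended continuous intravenous infusion (remifentanil during
venoarterial ECMO).  Data are exchanged as NONMEM-style event-record CSV
tables: one row per dose event or observation, identified by ``EVID``/``MDV``,
with subject-level covariates repeated on every row.

Units contract (fixed package-wide): time in hours since each subject's first
dose, infusion rates in mg/h, concentrations in ng/mL, volumes in L,
clearances in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LLOQ",
    "CovariateRecord",
    "InfusionEvent",
    "Observation",
    "SubjectRecord",
    "StudyDataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
]

#: Lower limit of quantification of the remifentanil assay, ng/mL.
LLOQ = 0.05

#: Column order of the event-record CSV dialect.
CSV_COLUMNS = [
    "ID", "TIME", "DV", "RATE", "EVID", "MDV",
    "SEX", "AGE", "WT", "BMI", "TP", "PUMP", "FLOW", "CRRT", "SCR", "TEMP",
]

_MANDATORY_COLUMNS = ["ID", "TIME", "DV", "RATE", "EVID", "MDV"]

#: CSV column name -> CovariateRecord field.
COVARIATE_COLUMNS = {
    "SEX": "sex",
    "AGE": "age",
    "WT": "weight",
    "BMI": "bmi",
    "TP": "total_protein",
    "PUMP": "pump_speed",
    "FLOW": "ecmo_flow",
    "CRRT": "crrt",
    "SCR": "scr",
    "TEMP": "temperature",
}


class DatasetFormatError(ValueError):
    """A file does not conform to the event-record CSV dialect."""


class DatasetValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass(frozen=True)
class CovariateRecord:
    """Subject-level covariates.

    ``sex`` is coded female = 0, male = 1; ``crrt`` (continuous renal
    replacement therapy) absent = 0, present = 1.  ``pump_speed`` is the ECMO
    centrifugal pump speed in RPM.  Every field other than ``sex`` and
    ``pump_speed`` may be missing (``None``).
    """

    sex: int
    pump_speed: float
    age: Optional[float] = None            # years
    weight: Optional[float] = None         # kg
    bmi: Optional[float] = None            # kg/m^2
    total_protein: Optional[float] = None  # g/dL
    ecmo_flow: Optional[float] = None      # L/min
    crrt: Optional[int] = None             # 0/1
    scr: Optional[float] = None            # mg/dL
    temperature: Optional[float] = None    # deg C

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise DatasetValidationError(f"sex must be 0 or 1, got {self.sex!r}")
        if self.crrt is not None and self.crrt not in (0, 1):
            raise DatasetValidationError(f"crrt must be 0 or 1, got {self.crrt!r}")
        if not self.pump_speed > 0:
            raise DatasetValidationError(
                f"pump_speed must be positive, got {self.pump_speed!r}")
        if self.weight is not None and not self.weight > 0:
            raise DatasetValidationError(f"weight must be positive, got {self.weight!r}")

    def get(self, name: str):
        """Return a covariate by its canonical field name."""
        return getattr(self, name)


@dataclass(frozen=True)
class InfusionEvent:
    """One constant-rate infusion segment.

    ``start_time`` hours since first dose, ``rate`` mg/h, ``duration`` hours.
    """

    start_time: float
    rate: float
    duration: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise DatasetValidationError(f"rate must be >= 0, got {self.rate}")
        if not self.duration > 0:
            raise DatasetValidationError(f"duration must be > 0, got {self.duration}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Observation:
    """A measured plasma concentration.

    ``blq_flag`` marks values below the assay LLOQ (0.05 ng/mL).  If not given
    it is derived from the concentration.
    """

    time: float
    concentration: float
    blq_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetValidationError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise DatasetValidationError(
                f"concentration must be >= 0, got {self.concentration}")
        if self.blq_flag is None:
            object.__setattr__(self, "blq_flag", bool(self.concentration < LLOQ))
        elif self.blq_flag and not self.concentration < LLOQ:
            raise DatasetValidationError(
                f"blq_flag set but concentration {self.concentration} >= {LLOQ}")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariates, ordered dose events, ordered observations."""

    id: str
    covariates: CovariateRecord
    doses: tuple[InfusionEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.doses:
            raise DatasetValidationError(f"subject {self.id}: at least one dose event required")
        for a, b in zip(self.doses, self.doses[1:]):
            if b.start_time < a.end_time - 1e-12:
                raise DatasetValidationError(
                    f"subject {self.id}: overlapping or unordered infusion events")
        tmax = self.infusion_end + 2.0
        times = [o.time for o in self.observations]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise DatasetValidationError(
                f"subject {self.id}: observation times are not non-decreasing")
        if any(t > tmax + 1e-9 for t in times):
            raise DatasetValidationError(
                f"subject {self.id}: observation beyond infusion end + 2 h")

    @property
    def infusion_end(self) -> float:
        return max(d.end_time for d in self.doses)


@dataclass(frozen=True)
class StudyDataset:
    """A collection of subjects plus free-text provenance metadata."""

    subjects: tuple[SubjectRecord, ...]
    metadata: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not self.subjects:
            raise DatasetValidationError("dataset must contain at least one subject")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetValidationError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def covariate_frame(self) -> pd.DataFrame:
        """One row per subject with all covariate fields."""
        rows = []
        for s in self.subjects:
            row = {"id": s.id}
            for f in CovariateRecord.__dataclass_fields__:
                row[f] = s.covariates.get(f)
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Event-record CSV reading / writing
# ---------------------------------------------------------------------------

def _covariates_from_row(row: pd.Series, subject: str) -> CovariateRecord:
    kwargs = {}
    for col, fieldname in COVARIATE_COLUMNS.items():
        val = row.get(col, np.nan)
        if pd.isna(val):
            kwargs[fieldname] = None
        elif fieldname in ("sex", "crrt"):
            kwargs[fieldname] = int(val)
        else:
            kwargs[fieldname] = float(val)
    if kwargs.get("sex") is None or kwargs.get("pump_speed") is None:
        raise DatasetFormatError(f"subject {subject}: SEX and PUMP are mandatory covariates")
    return CovariateRecord(**kwargs)


def _doses_from_events(times: Sequence[float], rates: Sequence[float],
                       t_last: float, subject: str) -> list[InfusionEvent]:
    """Reconstruct infusion segments from rate-change rows.

    An EVID=1 row with RATE > 0 starts a segment that runs until the next
    EVID=1 row (of any rate); RATE = 0 terminates the running infusion.  A
    segment still open at the end of the record runs until the last time in
    the record.
    """
    doses: list[InfusionEvent] = []
    for i, (t0, r) in enumerate(zip(times, rates)):
        if r == 0:
            continue
        t1 = times[i + 1] if i + 1 < len(times) else max(t_last, t0)
        if t1 <= t0:
            raise DatasetValidationError(
                f"subject {subject}: zero-duration infusion segment at t={t0}")
        doses.append(InfusionEvent(start_time=t0, rate=r, duration=t1 - t0))
    return doses


def read_dataset(path, lloq: float = LLOQ) -> StudyDataset:
    """Read an event-record CSV file into a validated :class:`StudyDataset`.

    Dose events are reconstructed from EVID=1 rate-change rows (a RATE of 0
    ends an infusion); rows with EVID=0 and MDV=0 become observations, with
    DV below ``lloq`` flagged as BLQ.
    """
    df = pd.read_csv(path, na_values=["."], float_precision="round_trip")
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing mandatory column {col!r}")
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(float)
        if np.any(np.diff(times) < 0):
            raise DatasetValidationError(
                f"subject {sid}: TIME must be non-decreasing within a subject")
        cov = _covariates_from_row(grp.iloc[0], str(sid))
        dose_rows = grp[grp["EVID"] == 1]
        rates = dose_rows["RATE"].to_numpy(float)
        if np.any(np.isnan(rates)):
            raise DatasetFormatError(f"subject {sid}: EVID=1 row without RATE")
        doses = _doses_from_events(
            dose_rows["TIME"].to_numpy(float).tolist(), rates.tolist(),
            t_last=float(times[-1]), subject=str(sid))
        obs_rows = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
        observations = [
            Observation(time=float(t), concentration=float(dv),
                        blq_flag=bool(dv < lloq))
            for t, dv in zip(obs_rows["TIME"], obs_rows["DV"])
        ]
        subjects.append(SubjectRecord(id=str(sid), covariates=cov,
                                      doses=doses, observations=observations))
    return StudyDataset(subjects=tuple(subjects), metadata=f"read from {path}")


def _subject_rows(s: SubjectRecord) -> Iterable[dict]:
    cov = {col: s.covariates.get(fieldname)
           for col, fieldname in COVARIATE_COLUMNS.items()}
    events: list[tuple[float, int, float, float]] = []  # (time, evid, rate, dv)
    prev_end = None
    for d in s.doses:
        if prev_end is not None and d.start_time > prev_end + 1e-12:
            events.append((prev_end, 1, 0.0, np.nan))  # explicit stop before a gap
        events.append((d.start_time, 1, d.rate, np.nan))
        prev_end = d.end_time
    events.append((prev_end, 1, 0.0, np.nan))  # terminate the final segment
    for o in s.observations:
        events.append((o.time, 0, np.nan, o.concentration))
    # stable sort by time, dose events before observations at equal times
    events.sort(key=lambda e: (e[0], -e[1]))
    for t, evid, rate, dv in events:
        yield {"ID": s.id, "TIME": t, "DV": dv, "RATE": rate,
               "EVID": evid, "MDV": 1 if evid == 1 else 0, **cov}


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset as event-record CSV; inverse of :func:`read_dataset`.

    Each infusion segment is written as a rate-change row plus an explicit
    RATE=0 terminator, so segment durations round-trip exactly.
    """
    if not isinstance(dataset, StudyDataset):
        raise DatasetValidationError("write_dataset requires a StudyDataset")
    rows = [row for s in dataset.subjects for row in _subject_rows(s)]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    # shortest round-trip repr keeps the numeric round trip exact
    df.to_csv(path, index=False, na_rep=".",
              float_format=lambda v: repr(float(v)))
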