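"""Domain types for minute-resolution motor-state series and medication logs.

The severity scale is a single axis on [-4, +4]: -4..-1 is increasing
bradykinesia (OFF), the open interval (-1, +1) is the ON state, and +1..+4 is
increasing dyskinesia (DYS).  Every downstream stage — cycle extraction,
stratification, response summaries — is defined in terms of the types here.

Time is handled as integer minutes since the Unix epoch (UTC-naive): the
scale is minute-native, so all clock times are floored to the minute on
ingestion and sub-minute precision never enters the pipeline.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotorState",
    "Pd9Series",
    "MedicationEvent",
    "Formulation",
    "ValidationError",
    "classify_motor_state",
    "classify_values",
    "validate_series",
    "minutes_from_timestamps",
    "timestamps_from_minutes",
    "read_series_csv",
    "write_series_csv",
    "read_medication_csv",
    "write_medication_csv",
]

#: lower bound of the severity scale (maximal bradykinesia)
SCALE_MIN = -4.0
#: upper bound of the severity scale (maximal dyskinesia)
SCALE_MAX = 4.0

_EPOCH = pd.Timestamp("1970-01-01")


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant.

    Carries *all* detected violations (not only the first) in
    :attr:`violations`, each a human-readable string naming the offending
    value and its location.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        msg = "; ".join(self.violations) if self.violations else "validation failed"
        super().__init__(msg)


class MotorState(enum.IntEnum):
    """Motor state of a person with Parkinson's, ordered OFF < ON < DYS."""

    OFF = 0
    ON = 1
    DYS = 2

    def __str__(self) -> str:  # "OFF" rather than "MotorState.OFF" in tables
        return self.name


class Formulation(str, enum.Enum):
    """Oral levodopa formulation of one administration."""

    IMMEDIATE_RELEASE = "immediate_release"
    CONTROLLED_RELEASE = "controlled_release"

    def __str__(self) -> str:
        return self.value


def classify_motor_state(value: float) -> MotorState:
    """Classify one severity value into OFF / ON / DYS.

    The rule partitions the scale: OFF for values <= -1, DYS for values >= +1,
    ON on the open interval in between.  The boundaries belong to OFF and DYS
    respectively, so -1.0 is OFF and +1.0 is DYS.

    Raises
    ------
    ValidationError
        If ``value`` is non-finite or outside [-4, +4].
    """
    v = float(value)
    if not math.isfinite(v) or v < SCALE_MIN or v > SCALE_MAX:
        raise ValidationError([f"severity value {value!r} is not a finite number in [-4, +4]"])
    if v <= -1.0:
        return MotorState.OFF
    if v >= 1.0:
        return MotorState.DYS
    return MotorState.ON


def classify_values(values: np.ndarray) -> np.ndarray:
    """Vectorized classification; returns an array of :class:`MotorState`."""
    v = np.asarray(values, dtype=float)
    bad = ~np.isfinite(v) | (v < SCALE_MIN) | (v > SCALE_MAX)
    if bad.any():
        idx = np.flatnonzero(bad)[:10]
        raise ValidationError(
            [f"severity value {v[i]!r} at position {i} is not a finite number in [-4, +4]" for i in idx]
        )
    out = np.full(v.shape, MotorState.ON, dtype=object)
    out[v <= -1.0] = MotorState.OFF
    out[v >= 1.0] = MotorState.DYS
    return out


@dataclass(frozen=True)
class Pd9Series:
    """Minute-indexed severity series for one patient recording.

    ``values`` is a float Series whose int64 index is minutes since the Unix
    epoch.  Absent minutes are genuine gaps (sensor not worn, data dropped);
    nothing in the pipeline imputes them.
    """

    patient_id: str
    session_id: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = self.values
        if not isinstance(s, pd.Series):
            s = pd.Series(dict(s), dtype=float)
        s = s.astype(float)
        s.index = s.index.astype(np.int64)
        s = s.sort_index()
        object.__setattr__(self, "values", s)

    @property
    def minutes(self) -> np.ndarray:
        """Integer minute stamps, sorted ascending."""
        return self.values.index.to_numpy()

    def __len__(self) -> int:
        return len(self.values)

    def restrict(self, minutes: Iterable[int]) -> "Pd9Series":
        """Return a copy keeping only the given minute stamps (set intersection)."""
        keep = self.values.index.intersection(pd.Index(list(minutes)))
        return replace(self, values=self.values.loc[keep])


@dataclass(frozen=True, order=True)
class MedicationEvent:
    """One timestamped oral levodopa administration.

    ``time`` is the ingestion minute (clock time floored to the minute),
    in minutes since the Unix epoch; it defines t = 0 of the dose's cycle.
    """

    time: int
    patient_id: str = field(compare=False)
    dose_mg: float = field(compare=False)
    formulation: Formulation = field(default=Formulation.IMMEDIATE_RELEASE, compare=False)

    def __post_init__(self) -> None:
        if not (self.dose_mg > 0):
            raise ValidationError([f"dose must be positive, got {self.dose_mg!r}"])
        object.__setattr__(self, "time", int(self.time))
        object.__setattr__(self, "formulation", Formulation(self.formulation))


def validate_series(series: Pd9Series) -> Pd9Series:
    """Check all series invariants, returning the series unchanged if valid.

    Violations checked: values outside [-4, +4] or non-finite, duplicate
    minute stamps.  (Off-grid stamps cannot survive construction, since the
    index is integer minutes, but duplicates can.)  All violations are
    reported together.
    """
    violations: list[str] = []
    s = series.values
    dup = s.index[s.index.duplicated()]
    for m in dup.unique()[:20]:
        violations.append(f"duplicate minute {int(m)} ({timestamps_from_minutes([int(m)])[0]}) in series {series.patient_id}/{series.session_id}")
    v = s.to_numpy()
    bad = ~np.isfinite(v) | (v < SCALE_MIN) | (v > SCALE_MAX)
    for i in np.flatnonzero(bad)[:20]:
        m = int(s.index[i])
        violations.append(
            f"value {v[i]!r} at minute {m} ({timestamps_from_minutes([m])[0]}) "
            f"of series {series.patient_id}/{series.session_id} is outside [-4, +4]"
        )
    if violations:
        raise ValidationError(violations)
    return series


# ---------------------------------------------------------------------------
# Time conversion helpers
# ---------------------------------------------------------------------------

def minutes_from_timestamps(timestamps) -> np.ndarray:
    """Floor ISO-8601 / datetime-like stamps to the minute grid (int64 minutes)."""
    ts = pd.to_datetime(timestamps)
    if isinstance(ts, pd.Timestamp):
        ts = pd.DatetimeIndex([ts])
    ts = pd.DatetimeIndex(ts).floor("min")
    return ((ts - _EPOCH) // pd.Timedelta(minutes=1)).to_numpy(dtype=np.int64)


def timestamps_from_minutes(minutes) -> pd.DatetimeIndex:
    """Inverse of :func:`minutes_from_timestamps` (exact on the grid)."""
    m = np.asarray(list(minutes) if not isinstance(minutes, np.ndarray) else minutes, dtype=np.int64)
    return _EPOCH + pd.to_timedelta(m, unit="min")


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------
# Series file: patient_id, session_id, timestamp (ISO-8601 to the minute),
# pd9 (decimal).  Medication file: patient_id, timestamp, dose_mg,
# formulation.  UTF-8, header row required, row order irrelevant.

_SERIES_COLS = ["patient_id", "session_id", "timestamp", "pd9"]
_MED_COLS = ["patient_id", "timestamp", "dose_mg", "formulation"]


def read_series_csv(path) -> list[Pd9Series]:
    """Read a severity-series table, one :class:`Pd9Series` per (patient, session).

    Every series is validated on ingestion; out-of-range values are rejected,
    never clamped — real scale output is bounded by construction, so an
    out-of-range value indicates a corrupt file.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "session_id": str})
    missing = [c for c in _SERIES_COLS if c not in df.columns]
    if missing:
        raise ValidationError([f"series file {path} lacks required column(s) {missing}"])
    df["minute"] = minutes_from_timestamps(df["timestamp"])
    out: list[Pd9Series] = []
    for (pid, sid), g in df.groupby(["patient_id", "session_id"], sort=True):
        s = pd.Series(g["pd9"].to_numpy(dtype=float), index=g["minute"].to_numpy())
        series = Pd9Series(patient_id=pid, session_id=sid, values=s)
        validate_series(series)
        out.append(series)
    return out


def write_series_csv(series_list: Sequence[Pd9Series], path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "session_id": s.session_id,
                    "timestamp": timestamps_from_minutes(s.minutes).strftime("%Y-%m-%dT%H:%M"),
                    "pd9": s.values.to_numpy(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_SERIES_COLS)
    df.to_csv(path, index=False)


def read_medication_csv(path) -> list[MedicationEvent]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _MED_COLS if c not in df.columns]
    if missing:
        raise ValidationError([f"medication file {path} lacks required column(s) {missing}"])
    minutes = minutes_from_timestamps(df["timestamp"])
    events = [
        MedicationEvent(
            time=int(m),
            patient_id=row.patient_id,
            dose_mg=float(row.dose_mg),
            formulation=Formulation(row.formulation),
        )
        for m, row in zip(minutes, df.itertuples())
    ]
    return sorted(events)


def write_medication_csv(events: Sequence[MedicationEvent], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "timestamp": timestamps_from_minutes([e.time for e in events]).strftime("%Y-%m-%dT%H:%M")
            if events
            else [],
            "dose_mg": [e.dose_mg for e in events],
            "formulation": [str(e.formulation) for e in events],
        }
    )
    df.to_csv(path, index=False)
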