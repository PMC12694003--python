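"""Levodopa-cycle extraction: medication-locked severity windows.

A complete levodopa cycle is the severity window from ``pre_minutes`` before
to ``post_minutes`` after one medication intake (defaults 20 and 90, i.e.
111 minute samples).  Only complete windows count: an event whose window is
missing any minute — a non-wear gap, a recording edge — yields no cycle, and
patients without at least one complete cycle are excluded from analysis.
The intake-minute value (offset 0) classifies the motor state at intake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Formulation,
    MedicationEvent,
    MotorState,
    Pd9Series,
    ValidationError,
    classify_motor_state,
    timestamps_from_minutes,
)

__all__ = [
    "CycleWindowConfig",
    "LevodopaCycle",
    "extract_cycles",
    "state_at_intake",
    "filter_included_patients",
    "write_cycle_table",
    "read_cycle_table",
]


@dataclass(frozen=True)
class CycleWindowConfig:
    """Extraction window around each intake, in minutes."""

    pre_minutes: int = 20
    post_minutes: int = 90

    def __post_init__(self) -> None:
        if self.pre_minutes < 0:
            raise ValidationError([f"pre_minutes must be >= 0, got {self.pre_minutes}"])
        if self.post_minutes < 1:
            raise ValidationError([f"post_minutes must be >= 1, got {self.post_minutes}"])

    @property
    def offsets(self) -> np.ndarray:
        """Integer minute offsets -pre .. +post inclusive."""
        return np.arange(-self.pre_minutes, self.post_minutes + 1)

    @property
    def n_samples(self) -> int:
        return self.pre_minutes + self.post_minutes + 1


@dataclass(frozen=True)
class LevodopaCycle:
    """One complete medication-locked severity window.

    ``values`` holds one severity value per minute offset in
    [-pre, +post] (offsets ascending, no gaps — completeness is a type
    invariant).  ``state_at_intake`` is the classification of the offset-0
    value.  ``normalized`` marks baseline-subtracted windows, whose values
    may leave [-4, +4].
    """

    patient_id: str
    event: MedicationEvent
    offsets: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    normalized: bool = False
    # computed from the offset-0 value unless supplied (baseline-normalized
    # cycles carry the state classified before subtraction)
    state_at_intake: MotorState | None = None

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        if offsets.shape != values.shape or offsets.ndim != 1:
            raise ValidationError(["cycle offsets and values must be 1-D and equally long"])
        if len(offsets) == 0 or not np.array_equal(offsets, np.arange(offsets[0], offsets[-1] + 1)):
            raise ValidationError(["cycle window is incomplete: offsets must be consecutive minutes"])
        if 0 not in offsets:
            raise ValidationError(["cycle window must contain the intake minute (offset 0)"])
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "values", values)
        if self.state_at_intake is None:
            object.__setattr__(self, "state_at_intake", classify_motor_state(values[offsets == 0][0]))

    def value_at(self, offset: int) -> float:
        return float(self.values[self.offsets == offset][0])

    def __len__(self) -> int:
        return len(self.offsets)


def extract_cycles(
    series: Pd9Series,
    events: Sequence[MedicationEvent],
    config: CycleWindowConfig = CycleWindowConfig(),
) -> list[LevodopaCycle]:
    """Extract one complete cycle per event whose full window is recorded.

    Events with any missing minute in [-pre, +post] around the intake yield
    no cycle.  Windows from closely spaced doses may overlap in absolute
    time; each still counts independently.  Output is ordered by event time.
    """
    mismatched = sorted({e.patient_id for e in events if e.patient_id != series.patient_id})
    if mismatched:
        raise ValidationError(
            [f"events for patient(s) {mismatched} do not belong to series patient {series.patient_id!r}"]
        )
    offsets = config.offsets
    s = series.values
    cycles: list[LevodopaCycle] = []
    for ev in sorted(events):
        window = s.reindex(ev.time + offsets)
        if window.isna().any():
            continue
        cycles.append(
            LevodopaCycle(
                patient_id=series.patient_id,
                event=ev,
                offsets=offsets,
                values=window.to_numpy(),
            )
        )
    return cycles


def state_at_intake(cycle: LevodopaCycle) -> MotorState:
    """Motor state at medication intake: classification of the offset-0 value."""
    return cycle.state_at_intake


def filter_included_patients(
    cohort: Sequence[tuple[Pd9Series, Sequence[MedicationEvent]]],
    config: CycleWindowConfig = CycleWindowConfig(),
) -> tuple[list[tuple[Pd9Series, list[LevodopaCycle]]], pd.DataFrame]:
    """Apply the patient-level inclusion rule: at least one complete cycle.

    Returns the retained (series, cycles) pairs plus an accounting table with
    one row per input patient: events seen, complete cycles, analyzed minutes,
    and whether the patient was included.
    """
    included: list[tuple[Pd9Series, list[LevodopaCycle]]] = []
    rows = []
    for series, events in cohort:
        cycles = extract_cycles(series, list(events), config)
        keep = len(cycles) >= 1
        rows.append(
            {
                "patient_id": series.patient_id,
                "n_events": len(events),
                "n_cycles": len(cycles),
                "analyzed_minutes": len(series) if keep else 0,
                "included": keep,
            }
        )
        if keep:
            included.append((series, cycles))
    table = pd.DataFrame(rows, columns=["patient_id", "n_events", "n_cycles", "analyzed_minutes", "included"])
    return included, table


# ---------------------------------------------------------------------------
# Cycle table (delimited text)
# ---------------------------------------------------------------------------

def _offset_label(o: int) -> str:
    return f"m{o:+d}"


def write_cycle_table(cycles: Sequence[LevodopaCycle], path) -> None:
    """Write cycles as one row each: metadata then one column per minute offset.

    Columns: patient_id, event_time, dose_mg, formulation, state_at_intake,
    then value columns labeled m-20 ... m+90 (at the default window).
    """
    rows = []
    for c in cycles:
        row = {
            "patient_id": c.patient_id,
            "event_time": timestamps_from_minutes([c.event.time]).strftime("%Y-%m-%dT%H:%M")[0],
            "dose_mg": c.event.dose_mg,
            "formulation": str(c.event.formulation),
            "state_at_intake": str(c.state_at_intake),
        }
        row.update({_offset_label(int(o)): v for o, v in zip(c.offsets, c.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cycle_table(path) -> list[LevodopaCycle]:
    """Re-parse a cycle table written by :func:`write_cycle_table`."""
    from .core import minutes_from_timestamps

    df = pd.read_csv(path, dtype={"patient_id": str})
    value_cols = [c for c in df.columns if c.startswith("m+") or c.startswith("m-")]
    offsets = np.array(sorted(int(c[1:]) for c in value_cols), dtype=np.int64)
    ordered = [f"m{o:+d}" for o in offsets]
    cycles = []
    for _, row in df.iterrows():
        ev = MedicationEvent(
            time=int(minutes_from_timestamps([row["event_time"]])[0]),
            patient_id=row["patient_id"],
            dose_mg=float(row["dose_mg"]),
            formulation=Formulation(row["formulation"]),
        )
        cycles.append(
            LevodopaCycle(
                patient_id=row["patient_id"],
                event=ev,
                offsets=offsets,
                values=row[ordered].to_numpy(dtype=float),
                state_at_intake=MotorState[row["state_at_intake"]],
            )
        )
    return cycles
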