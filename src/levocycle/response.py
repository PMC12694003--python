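"""Stratified, event-locked response statistics over levodopa cycles.

Cycles are grouped by the motor state at intake (OFF / ON / DYS, plus the
pooled ALL stratum) and summarized per 5-minute offset on the extraction
window: count, mean, standard error of the mean, median and quartiles —
optionally after baseline normalization, i.e. subtracting each cycle's
intake-minute value so curves show change from baseline.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MotorState, ValidationError
from .cycles import LevodopaCycle

__all__ = [
    "ResponseSummary",
    "StateCountTable",
    "sample_grid",
    "normalize_baseline",
    "stratify",
    "summarize",
    "state_count_table",
    "write_summary_table",
    "read_summary_table",
    "write_state_count_table",
]

#: stratum labels: the three intake states plus the pooled stratum
STRATA = ("ALL", "OFF", "ON", "DYS")


@dataclass(frozen=True)
class ResponseSummary:
    """Distribution statistics per minute offset for one stratum.

    ``rows`` has one row per offset on the sampling grid with columns
    n, mean, sem, median, q1, q3.  SEM uses the n-1 sample standard
    deviation over sqrt(n) and is NaN for n = 1; quartiles use linear
    interpolation.  ``normalized`` marks baseline-subtracted input.
    """

    stratum: str
    rows: pd.DataFrame
    normalized: bool
    step: int

    @property
    def offsets(self) -> np.ndarray:
        return self.rows.index.to_numpy()

    @property
    def n(self) -> int:
        return 0 if self.rows.empty else int(self.rows["n"].iloc[0])


@dataclass(frozen=True)
class StateCountTable:
    """Counts and percentages of cycles by motor state at intake."""

    counts: Mapping[MotorState, int]
    percentages: Mapping[MotorState, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motor_state": [str(s) for s in (MotorState.OFF, MotorState.ON, MotorState.DYS)],
                "count": [self.counts[s] for s in (MotorState.OFF, MotorState.ON, MotorState.DYS)],
                "percent": [
                    self.percentages[s] for s in (MotorState.OFF, MotorState.ON, MotorState.DYS)
                ],
            }
        )


def sample_grid(cycle: LevodopaCycle, step: int = 5) -> dict[int, float]:
    """Point samples of one cycle at multiples of ``step`` minutes.

    No within-bin averaging: the value at each grid offset is the single
    minute sample there.  ``step`` must divide both window bounds.
    """
    lo, hi = int(cycle.offsets[0]), int(cycle.offsets[-1])
    if step < 1 or lo % step or hi % step:
        raise ValidationError(
            [f"step {step} does not divide the window bounds [{lo}, {hi}]"]
        )
    grid = np.arange(lo, hi + 1, step)
    idx = np.searchsorted(cycle.offsets, grid)
    return {int(o): float(v) for o, v in zip(grid, cycle.values[idx])}


def normalize_baseline(cycle: LevodopaCycle) -> LevodopaCycle:
    """Subtract the intake-minute value from every offset (change from baseline).

    The offset-0 value of the result is exactly 0; values may leave [-4, +4]
    (range [-8, +8]) and are not clamped.  The intake state classified on the
    raw values is preserved.  Idempotent on already-normalized cycles.
    """
    baseline = cycle.value_at(0)
    return replace(
        cycle,
        values=cycle.values - baseline,
        normalized=True,
        state_at_intake=cycle.state_at_intake,
    )


def stratify(cycles: Sequence[LevodopaCycle]) -> dict[MotorState, list[LevodopaCycle]]:
    """Partition cycles by motor state at intake (disjoint, union = input)."""
    out: dict[MotorState, list[LevodopaCycle]] = {s: [] for s in MotorState}
    for c in cycles:
        out[c.state_at_intake].append(c)
    return out


def summarize(
    cycles: Sequence[LevodopaCycle],
    stratum: str = "ALL",
    normalized: bool = False,
    step: int = 5,
) -> ResponseSummary:
    """Per-offset distribution statistics for one stratum of cycles.

    Each cycle contributes its point sample at every multiple of ``step``
    minutes in the window.  With ``normalized`` the cycles are baseline-
    subtracted first.  An empty stratum yields an empty summary.
    """
    if normalized:
        cycles = [c if c.normalized else normalize_baseline(c) for c in cycles]
    if not cycles:
        rows = pd.DataFrame(columns=["n", "mean", "sem", "median", "q1", "q3"])
        rows.index.name = "offset_min"
        return ResponseSummary(stratum=stratum, rows=rows, normalized=normalized, step=step)
    sampled = [sample_grid(c, step) for c in cycles]
    offsets = np.array(sorted(sampled[0]))
    mat = np.array([[s[o] for o in offsets] for s in sampled])  # cycles x offsets
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else np.full(mat.shape[1], np.nan)
    q1, median, q3 = np.percentile(mat, [25, 50, 75], axis=0)
    rows = pd.DataFrame(
        {"n": n, "mean": mean, "sem": sem, "median": median, "q1": q1, "q3": q3},
        index=pd.Index(offsets, name="offset_min"),
    )
    return ResponseSummary(stratum=stratum, rows=rows, normalized=normalized, step=step)


def _round_half_up(x: float, digits: int = 1) -> float:
    # half-away-from-zero, matching the printed-table style (banker's
    # rounding would turn 23.45 into 23.4)
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def state_count_table(cycles_or_counts) -> StateCountTable:
    """Counts and percentages of cycles per motor state at intake.

    Accepts either a sequence of cycles or a mapping {MotorState: count}.
    Percentages are 100 * count / total rounded half-away-from-zero to one
    decimal.  An empty input is an error (no denominator).
    """
    if isinstance(cycles_or_counts, Mapping):
        counts = {s: int(cycles_or_counts.get(s, 0)) for s in MotorState}
    else:
        counts = {s: 0 for s in MotorState}
        for c in cycles_or_counts:
            counts[c.state_at_intake] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(["cannot tabulate motor states of an empty cycle set"])
    pct = {s: _round_half_up(100.0 * counts[s] / total) for s in MotorState}
    return StateCountTable(counts=counts, percentages=pct, total=total)


# ---------------------------------------------------------------------------
# Delimited-text writers / readers
# ---------------------------------------------------------------------------

def write_summary_table(summaries: Sequence[ResponseSummary], path) -> None:
    """Write stacked summaries: stratum, offset_min, n, mean, sem, median, q1, q3, normalized."""
    frames = []
    for s in summaries:
        if s.rows.empty:  # empty strata carry no rows
            continue
        df = s.rows.reset_index()
        df.insert(0, "stratum", s.stratum)
        df["normalized"] = s.normalized
        frames.append(df)
    cols = ["stratum", "offset_min", "n", "mean", "sem", "median", "q1", "q3", "normalized"]
    out = pd.concat(frames, ignore_index=True)[cols] if frames else pd.DataFrame(columns=cols)
    out.to_csv(path, index=False)


def read_summary_table(path) -> list[ResponseSummary]:
    df = pd.read_csv(path)
    out = []
    for (stratum, normalized), g in df.groupby(["stratum", "normalized"], sort=False):
        rows = g.set_index("offset_min")[["n", "mean", "sem", "median", "q1", "q3"]]
        offs = rows.index.to_numpy()
        step = int(np.diff(offs)[0]) if len(offs) > 1 else 5
        out.append(ResponseSummary(stratum=stratum, rows=rows, normalized=bool(normalized), step=step))
    return out


def write_state_count_table(table: StateCountTable, path) -> None:
    df = table.to_frame()
    df.loc[len(df)] = ["TOTAL", table.total, 100.0]
    df.to_csv(path, index=False)
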