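"""End-to-end runs: configuration, logging, output tables and figures.

Ties the stages together the way the published analysis is laid out:
simulate (or load) minute-resolution severity series and a medication log,
extract complete levodopa cycles, stratify by motor state at intake, and
write the cycle table, the state-count table, raw and baseline-normalized
response summaries, and the standard figures (daily severity graph with the
ON band shaded, a single-cycle view, per-stratum boxplot panels on the
5-minute grid, and per-stratum mean ± SEM panels).

Runs are driven by a single YAML config (flags may override individual
fields) so that one artifact captures every analysis choice.  INFO logging
records counts at every filter — events seen, cycles kept, patients
excluded — the attrition trail a real-data user needs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .core import (
    MedicationEvent,
    MotorState,
    Pd9Series,
    ValidationError,
    read_medication_csv,
    read_series_csv,
    timestamps_from_minutes,
    write_medication_csv,
    write_series_csv,
)
from .cycles import (
    CycleWindowConfig,
    LevodopaCycle,
    filter_included_patients,
    write_cycle_table,
)
from .response import (
    ResponseSummary,
    STRATA,
    state_count_table,
    stratify,
    summarize,
    write_state_count_table,
    write_summary_table,
)
from . import synthetic
from .synthetic import CohortConfig, DoseSpec, NoiseSpec, WearGapSpec

__all__ = [
    "RunConfig",
    "NoCyclesError",
    "load_config",
    "run_simulate",
    "run_analyze",
    "plot_daily_series",
    "plot_single_cycle",
    "plot_stratum_boxplots",
    "plot_mean_sem_panels",
]

logger = logging.getLogger("levocycle")

MINUTES_PER_DAY = 1440


class NoCyclesError(RuntimeError):
    """No complete cycle anywhere in the input: nothing to analyze."""


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class InputPaths(BaseModel):
    series: Path
    medication: Path


class SimulateBlock(BaseModel):
    n_patients: int = 10
    phenotype_mix: dict[str, float] = {"stable": 0.3, "wearing_off": 0.45, "brittle_fluctuator": 0.25}
    dose_schedule: Optional[list[dict]] = None  # [{clock, dose_mg, formulation}]
    n_days: int = 3
    noise: dict = {}
    wear_gaps: dict = {}

    def to_cohort_config(self, seed: int) -> CohortConfig:
        schedule = (
            tuple(DoseSpec(**d) for d in self.dose_schedule)
            if self.dose_schedule
            else synthetic.DEFAULT_SCHEDULE
        )
        return CohortConfig(
            n_patients=self.n_patients,
            phenotype_mix=self.phenotype_mix,
            dose_schedule=schedule,
            n_days=self.n_days,
            noise=NoiseSpec(**self.noise),
            wear_gaps=WearGapSpec(**self.wear_gaps),
            seed=seed,
        )


class WindowBlock(BaseModel):
    pre_minutes: int = 20
    post_minutes: int = 90


class AnalysisBlock(BaseModel):
    step: int = 5
    normalized: bool = True  # also write baseline-normalized summaries


class RunConfig(BaseModel):
    """One reproducible run: exactly one of ``input`` or ``simulate``."""

    input: Optional[InputPaths] = None
    simulate: Optional[SimulateBlock] = None
    window: WindowBlock = Field(default_factory=WindowBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    out_dir: Path = Path("levocycle_out")
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.input is None) == (self.simulate is None):
            raise ValueError("config must contain exactly one of 'input' or 'simulate'")
        return self

    def window_config(self) -> CycleWindowConfig:
        return CycleWindowConfig(self.window.pre_minutes, self.window.post_minutes)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _setup_logging(level: str) -> None:
    logging.basicConfig(level=getattr(logging, level), format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(getattr(logging, level))


# ---------------------------------------------------------------------------
# Pipeline entry points
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic cohort and write series, medication log and manifest."""
    _setup_logging(config.log_level)
    if config.simulate is None:
        raise ValidationError(["config field 'simulate' is required for the simulate command"])
    cc = config.simulate.to_cohort_config(config.seed)
    cohort = synthetic.generate_cohort(cc)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": out / "series.csv",
        "medication": out / "medication.csv",
        "manifest": out / "manifest.csv",
    }
    write_series_csv([s for s, _, _ in cohort], paths["series"])
    all_events = [e for _, evs, _ in cohort for e in evs]
    write_medication_csv(all_events, paths["medication"])
    synthetic.write_manifest(cohort, paths["manifest"], seed=cc.seed)
    logger.info(
        "simulated cohort: %d patients, %d medication events, %d recorded minutes",
        len(cohort),
        len(all_events),
        sum(len(s) for s, _, _ in cohort),
    )
    return paths


def _load_cohort(config: RunConfig) -> list[tuple[Pd9Series, list[MedicationEvent]]]:
    if config.input is not None:
        series_list = read_series_csv(config.input.series)
        events = read_medication_csv(config.input.medication)
        by_patient: dict[str, list[MedicationEvent]] = {}
        for e in events:
            by_patient.setdefault(e.patient_id, []).append(e)
        # cycle windows may span session boundaries: merge a patient's
        # sessions into one minute-indexed view
        merged: dict[str, Pd9Series] = {}
        for s in series_list:
            if s.patient_id in merged:
                prev = merged[s.patient_id]
                combined = prev.values.combine_first(s.values)
                merged[s.patient_id] = Pd9Series(s.patient_id, prev.session_id, combined)
            else:
                merged[s.patient_id] = s
        return [(merged[pid], by_patient.get(pid, [])) for pid in sorted(merged)]
    cc = config.simulate.to_cohort_config(config.seed)
    return [(s, evs) for s, evs, _ in synthetic.generate_cohort(cc)]


def run_analyze(config: RunConfig, figures: bool = True) -> dict[str, Path]:
    """Run extract -> stratify -> summarize -> count table, write tables and figures.

    Raises :class:`NoCyclesError` if no complete cycle exists in the whole
    input.  All tables are bit-reproducible for fixed inputs.
    """
    _setup_logging(config.log_level)
    cohort = _load_cohort(config)
    n_events = sum(len(evs) for _, evs in cohort)
    total_minutes = sum(len(s) for s, _ in cohort)
    logger.info("loaded %d patients, %d events, %d minutes", len(cohort), n_events, total_minutes)

    included, accounting = filter_included_patients(cohort, config.window_config())
    cycles = [c for _, cyc in included for c in cyc]
    logger.info(
        "inclusion: %d of %d patients retained (%d excluded), %d complete cycles, %d analyzed minutes",
        len(included),
        len(cohort),
        len(cohort) - len(included),
        len(cycles),
        int(accounting.loc[accounting["included"], "analyzed_minutes"].sum()),
    )
    if not cycles:
        raise NoCyclesError("no complete levodopa cycle in the input")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["inclusion"] = out / "inclusion.csv"
    accounting.to_csv(paths["inclusion"], index=False)

    paths["cycles"] = out / "cycle_table.csv"
    write_cycle_table(cycles, paths["cycles"])

    counts = state_count_table(cycles)
    paths["state_counts"] = out / "state_counts.csv"
    write_state_count_table(counts, paths["state_counts"])
    logger.info(
        "state at intake: OFF %d (%.1f%%), ON %d (%.1f%%), DYS %d (%.1f%%) of %d cycles",
        counts.counts[MotorState.OFF], counts.percentages[MotorState.OFF],
        counts.counts[MotorState.ON], counts.percentages[MotorState.ON],
        counts.counts[MotorState.DYS], counts.percentages[MotorState.DYS],
        counts.total,
    )

    strata = stratify(cycles)
    by_label = {"ALL": cycles, "OFF": strata[MotorState.OFF], "ON": strata[MotorState.ON], "DYS": strata[MotorState.DYS]}
    step = config.analysis.step
    summaries = [summarize(by_label[lab], stratum=lab, normalized=False, step=step) for lab in STRATA]
    if config.analysis.normalized:
        summaries += [summarize(by_label[lab], stratum=lab, normalized=True, step=step) for lab in STRATA]
    paths["summaries"] = out / "response_summaries.csv"
    write_summary_table(summaries, paths["summaries"])

    if figures:
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        series0, _ = cohort[0]
        events0 = next(evs for s, evs in cohort if s.patient_id == series0.patient_id)
        paths["fig_daily"] = fig_dir / "daily_series.png"
        plot_daily_series(series0, events0, paths["fig_daily"])
        paths["fig_cycle"] = fig_dir / "single_cycle.png"
        plot_single_cycle(cycles[0], paths["fig_cycle"])
        paths["fig_box"] = fig_dir / "stratum_boxplots.png"
        plot_stratum_boxplots(by_label, step, paths["fig_box"])
        raw = [s for s in summaries if not s.normalized]
        norm = [s for s in summaries if s.normalized]
        paths["fig_meansem"] = fig_dir / "mean_sem.png"
        plot_mean_sem_panels(raw, norm, paths["fig_meansem"])
    return paths


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _shade_on_band(ax) -> None:
    ax.axhspan(-1, 1, color="#cfe8ff", alpha=0.6, zorder=0)
    ax.set_ylim(-4.2, 4.2)
    ax.set_ylabel("severity (scale units)")


def plot_daily_series(series: Pd9Series, events: Sequence[MedicationEvent], path) -> None:
    """Per-day severity graph: ON band shaded, vertical lines at dose times."""
    minutes = series.minutes
    days = np.unique(minutes // MINUTES_PER_DAY)
    fig, axes = plt.subplots(len(days), 1, figsize=(10, 2.2 * len(days)), squeeze=False, sharex=True)
    for ax, day in zip(axes.ravel(), days):
        mask = minutes // MINUTES_PER_DAY == day
        mod = minutes[mask] % MINUTES_PER_DAY
        vals = series.values.to_numpy()[mask]
        # break the line across gaps
        jump = np.flatnonzero(np.diff(mod) > 1)
        segs = np.split(np.arange(len(mod)), jump + 1)
        _shade_on_band(ax)
        for seg in segs:
            ax.plot(mod[seg] / 60.0, vals[seg], color="#1f3b70", lw=0.8)
        for e in events:
            if e.time // MINUTES_PER_DAY == day:
                ax.axvline((e.time % MINUTES_PER_DAY) / 60.0, color="tab:blue", lw=1.2)
        ax.set_xlim(0, 24)
        ax.set_title(str(timestamps_from_minutes([int(day) * MINUTES_PER_DAY])[0].date()), fontsize=9)
    axes.ravel()[-1].set_xlabel("clock time (h)")
    fig.suptitle(f"patient {series.patient_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_single_cycle(cycle: LevodopaCycle, path) -> None:
    """One medication-locked window; the vertical line marks intake (t = 0)."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    _shade_on_band(ax)
    ax.plot(cycle.offsets, cycle.values, color="#1f3b70", lw=1.2)
    ax.axvline(0, color="tab:blue", lw=1.5, label="medication intake (t = 0)")
    ax.set_xlabel("minutes from intake")
    ax.set_title(f"patient {cycle.patient_id}, intake state {cycle.state_at_intake}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_stratum_boxplots(by_label: dict[str, list[LevodopaCycle]], step: int, path) -> None:
    """Per-stratum boxplot panels of severity at each grid offset."""
    from .response import sample_grid

    labels = [lab for lab in STRATA if by_label.get(lab)]
    fig, axes = plt.subplots(len(labels), 1, figsize=(10, 2.8 * len(labels)), squeeze=False)
    for ax, lab in zip(axes.ravel(), labels):
        sampled = [sample_grid(c, step) for c in by_label[lab]]
        offsets = sorted(sampled[0])
        data = [[s[o] for s in sampled] for o in offsets]
        _shade_on_band(ax)
        ax.boxplot(data, positions=offsets, widths=step * 0.6, manage_ticks=False,
                   flierprops={"markersize": 2})
        ax.axvline(0, color="tab:blue", lw=1.2)
        ax.set_xlim(offsets[0] - step, offsets[-1] + step)
        ax.set_title(f"{lab} at intake (n = {len(by_label[lab])})", fontsize=9)
    axes.ravel()[-1].set_xlabel("minutes from intake")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_mean_sem_panels(
    raw: Sequence[ResponseSummary], normalized: Sequence[ResponseSummary], path
) -> None:
    """Mean ± SEM per stratum: raw severity (left) and change from baseline (right)."""
    panels = [p for p in (raw, normalized) if p]
    fig, axes = plt.subplots(1, len(panels), figsize=(6 * len(panels), 3.5), squeeze=False)
    colors = {"ALL": "0.4", "OFF": "tab:red", "ON": "tab:green", "DYS": "tab:purple"}
    for ax, group in zip(axes.ravel(), panels):
        for s in group:
            if s.rows.empty:
                continue
            m, e = s.rows["mean"], s.rows["sem"]
            ax.plot(s.offsets, m, color=colors.get(s.stratum, "k"), label=f"{s.stratum} (n={s.n})")
            ax.fill_between(s.offsets, m - e, m + e, color=colors.get(s.stratum, "k"), alpha=0.2)
        is_norm = group[0].normalized
        if not is_norm:
            _shade_on_band(ax)
        else:
            ax.axhline(0, color="0.6", lw=0.8)
            ax.set_ylabel("change from baseline (scale units)")
        ax.axvline(0, color="tab:blue", lw=1.0)
        ax.set_xlabel("minutes from intake")
        ax.set_title("change from baseline" if is_norm else "raw severity", fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
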