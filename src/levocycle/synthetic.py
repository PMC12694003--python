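"""Synthetic cohort generator: PK/PD motor-state series with medication logs.

No public minute-resolution motor-state dataset exists for this analysis, so
the pipeline is exercised on simulated cohorts built from the simplest
standard pharmacometric structure that reproduces the described levodopa
phenomenology:

* one-compartment oral absorption/elimination (Bateman plasma curve), with
  plasma peak 0.5-2 h post-dose and substantial decline by 4-5 h;
* a first-order effect compartment (rate ``ke0``) giving the ~20 min lag
  between ingestion and clinical onset;
* a sigmoid-Emax (Hill) severity response on top of an OFF baseline, so that
  dyskinesia is overshoot of the same single severity axis past +1 rather
  than a separate process;
* AR(1) noise plus a weak circadian modulation, clamped to the [-4, +4]
  scale after summation;
* overnight non-wear gaps and random daytime gaps.

Three phenotypes control where the response lands on the scale: ``stable``
(wide therapeutic window, peaks stay inside the ON band), ``wearing_off``
(deep OFF baseline, inter-dose troughs re-enter OFF), and
``brittle_fluctuator`` (narrow window, peaks overshoot into dyskinesia).

Concentrations are in arbitrary units anchored only by ``ec50``; dose enters
linearly, so only dose/ec50 ratios matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    Formulation,
    MedicationEvent,
    Pd9Series,
    SCALE_MAX,
    SCALE_MIN,
    ValidationError,
    minutes_from_timestamps,
)

__all__ = [
    "PatientPkParams",
    "NoiseSpec",
    "DoseSpec",
    "WearGapSpec",
    "CohortConfig",
    "PHENOTYPES",
    "plasma_concentration",
    "effect_site_concentration",
    "effect_to_pd9",
    "apply_wear_gaps",
    "generate_cohort",
    "write_manifest",
]

PHENOTYPES = ("stable", "wearing_off", "brittle_fluctuator")

#: simulation start for generated cohorts (any date works; minutes are absolute)
_SIM_START = "2024-03-04T00:00"
MINUTES_PER_DAY = 1440


def _clock_to_minutes(clock) -> int:
    """'HH:MM' (or an int minute-of-day) -> minute of day in [0, 1440)."""
    if isinstance(clock, (int, np.integer)):
        m = int(clock)
    else:
        h, mi = str(clock).split(":")
        m = int(h) * 60 + int(mi)
    if not (0 <= m < MINUTES_PER_DAY):
        raise ValidationError([f"clock time {clock!r} is not within one day"])
    return m


@dataclass(frozen=True)
class PatientPkParams:
    """PK/PD parameters of one simulated patient.

    ka, ke, ke0 : float
        First-order absorption, elimination and effect-compartment
        equilibration rates, 1/h; requires ka > ke > 0 and ke0 > 0.
    ec50 : float
        Effect-site concentration (arbitrary units) at half-maximal response.
    hill : float
        Hill exponent, >= 1; steeper values narrow the therapeutic window.
    baseline : float
        Untreated severity (scale units), in [-4, 0].
    span : float
        Maximal severity excursion above baseline at saturating effect-site
        concentration (> 0); baseline + span may exceed +4 — the realized
        series is clamped, the parameter is not.
    cr_ka_factor : float
        Multiplier < 1 applied to ka for controlled-release doses.
    """

    ka: float
    ke: float
    ke0: float
    ec50: float
    hill: float
    baseline: float
    span: float
    cr_ka_factor: float = 0.4

    def __post_init__(self) -> None:
        problems = []
        if not (self.ka > self.ke > 0):
            problems.append(f"requires ka > ke > 0, got ka={self.ka}, ke={self.ke}")
        if not (self.ke0 > 0):
            problems.append(f"ke0 must be positive, got {self.ke0}")
        if not (self.ec50 > 0):
            problems.append(f"ec50 must be positive, got {self.ec50}")
        if not (self.hill >= 1):
            problems.append(f"hill must be >= 1, got {self.hill}")
        if not (SCALE_MIN <= self.baseline <= 0):
            problems.append(f"baseline must lie in [-4, 0], got {self.baseline}")
        if not (self.span > 0):
            problems.append(f"span must be positive, got {self.span}")
        if not (0 < self.cr_ka_factor < 1):
            problems.append(f"cr_ka_factor must be in (0, 1), got {self.cr_ka_factor}")
        if problems:
            raise ValidationError(problems)


@dataclass(frozen=True)
class NoiseSpec:
    """Minute-resolution AR(1) noise plus a 24-h sinusoidal modulation.

    sigma is the innovation standard deviation (scale units); phi the lag-1
    autocorrelation (|phi| < 1), so the stationary standard deviation is
    sigma / sqrt(1 - phi^2).  circadian_phase is the clock time of the
    modulation minimum ('HH:MM').
    """

    sigma: float = 0.3
    phi: float = 0.8
    circadian_amplitude: float = 0.15
    circadian_phase: str = "04:00"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError([f"sigma must be >= 0, got {self.sigma}"])
        if not (abs(self.phi) < 1):
            raise ValidationError([f"|phi| must be < 1, got {self.phi}"])


@dataclass(frozen=True)
class DoseSpec:
    """One scheduled daily dose: clock time, dose in mg, formulation."""

    clock: str
    dose_mg: float = 100.0
    formulation: Formulation = Formulation.IMMEDIATE_RELEASE


#: Fig-2-style default regimen: five immediate-release doses at three-hour
#: intervals from 07:00 to 19:00, plus a controlled-release dose at bedtime.
DEFAULT_SCHEDULE = (
    DoseSpec("07:00"),
    DoseSpec("10:00"),
    DoseSpec("13:00"),
    DoseSpec("16:00"),
    DoseSpec("19:00"),
    DoseSpec("22:00", dose_mg=200.0, formulation=Formulation.CONTROLLED_RELEASE),
)


@dataclass(frozen=True)
class WearGapSpec:
    """Non-wear gaps: a fixed nightly interval plus random daytime gaps.

    The nightly interval is half-open [night_start, night_end) in clock time
    and may wrap midnight; ``None`` endpoints mean no nightly gap, while
    equal endpoints denote the full 24 h (rejected downstream — no data
    would remain).  Daytime gaps arrive at ``daytime_gap_rate`` per worn
    hour with geometric lengths of mean ``gap_length_mean_min`` minutes.
    """

    night_start: str | None = "23:00"
    night_end: str | None = "06:00"
    daytime_gap_rate: float = 0.0
    gap_length_mean_min: float = 10.0

    def night_minutes_of_day(self) -> np.ndarray:
        if self.night_start is None or self.night_end is None:
            return np.empty(0, dtype=np.int64)
        a = _clock_to_minutes(self.night_start)
        b = _clock_to_minutes(self.night_end)
        if a == b:  # wraps all the way around
            return np.arange(MINUTES_PER_DAY, dtype=np.int64)
        if a < b:
            return np.arange(a, b, dtype=np.int64)
        return np.concatenate(
            [np.arange(a, MINUTES_PER_DAY, dtype=np.int64), np.arange(0, b, dtype=np.int64)]
        )


NO_GAPS = WearGapSpec(night_start=None, night_end=None)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"stable": 0.3, "wearing_off": 0.45, "brittle_fluctuator": 0.25}
    )
    dose_schedule: Sequence[DoseSpec] = DEFAULT_SCHEDULE
    n_days: int = 3
    noise: NoiseSpec = NoiseSpec()
    wear_gaps: WearGapSpec = WearGapSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError([f"n_patients must be >= 0, got {self.n_patients}"])
        unknown = set(self.phenotype_mix) - set(PHENOTYPES)
        if unknown:
            raise ValidationError([f"unknown phenotype(s) {sorted(unknown)}; expected {PHENOTYPES}"])
        total = float(sum(self.phenotype_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError([f"phenotype_mix proportions must sum to 1, got {total}"])
        if self.n_days < 1:
            raise ValidationError([f"n_days must be >= 1, got {self.n_days}"])


# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------

def plasma_concentration(
    events: Sequence[MedicationEvent], params: PatientPkParams, grid: np.ndarray
) -> np.ndarray:
    """Plasma concentration on a minute grid by Bateman superposition.

    Each dose contributes ``D * ka/(ka-ke) * (exp(-ke*tau) - exp(-ka*tau))``
    for tau = t - t_dose >= 0 (hours) and nothing before its ingestion;
    controlled-release doses use ``ka * cr_ka_factor``.  Concentration units
    are arbitrary (mg-scaled); only ratios to ec50 matter downstream.
    """
    grid = np.asarray(grid, dtype=np.int64)
    conc = np.zeros(grid.shape, dtype=float)
    ke = params.ke
    for ev in events:
        ka = params.ka * (params.cr_ka_factor if ev.formulation is Formulation.CONTROLLED_RELEASE else 1.0)
        if abs(ka - ke) < 1e-12:
            raise ValidationError(
                [f"degenerate Bateman form: effective ka ({ka}/h) equals ke ({ke}/h)"]
            )
        tau_h = (grid - ev.time) / 60.0
        pos = tau_h >= 0
        t = tau_h[pos]
        conc[pos] += ev.dose_mg * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    return np.maximum(conc, 0.0)


def effect_site_concentration(
    plasma: np.ndarray, ke0: float, dt_minutes: float = 1.0, grid: np.ndarray | None = None
) -> np.ndarray:
    """Effect-compartment concentration lagging plasma with rate ``ke0`` (1/h).

    Solves dCe/dt = ke0 * (Cp - Ce), Ce(0) = 0, by the exact exponential
    update for plasma interpolated linearly over each minute step:
    ``Ce[i+1] = Cp[i+1] - s/k + (Ce[i] - Cp[i] + s/k) * exp(-k)`` with
    ``s = Cp[i+1] - Cp[i]`` and ``k = ke0 * dt``.  Unlike a piecewise-
    constant update this introduces no artificial one-step lag, so Ce
    converges to Cp pointwise as ke0 grows.
    """
    if ke0 <= 0:
        raise ValidationError([f"ke0 must be positive, got {ke0}"])
    if grid is not None:
        grid = np.asarray(grid)
        d = np.diff(grid)
        if d.size and not np.all(d == d[0]):
            raise ValidationError(["effect-site update requires a uniform minute grid"])
        if d.size:
            dt_minutes = float(d[0])
    cp = np.asarray(plasma, dtype=float)
    if cp.size == 0:
        return cp.copy()
    k = ke0 * dt_minutes / 60.0
    a = np.exp(-k)
    ce = np.empty_like(cp)
    ce[0] = 0.0
    if cp.size > 1:
        s = np.diff(cp)
        # recurrence ce[i+1] = a*ce[i] + u[i]
        u = cp[1:] - a * cp[:-1] - s * (1.0 - a) / k
        ce[1:] = lfilter([1.0], [1.0, -a], u)
    return np.maximum(ce, 0.0)


# ---------------------------------------------------------------------------
# Pharmacodynamics: concentration -> severity
# ---------------------------------------------------------------------------

def _sigmoid_fraction(ce: np.ndarray, params: PatientPkParams) -> np.ndarray:
    ratio = np.asarray(ce, dtype=float) / params.ec50
    rh = np.power(ratio, params.hill, where=ratio > 0, out=np.zeros_like(ratio))
    return rh / (1.0 + rh)


def _circadian_term(grid: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.circadian_amplitude == 0:
        return np.zeros(len(grid))
    phase = _clock_to_minutes(noise.circadian_phase)
    minute_of_day = np.asarray(grid, dtype=np.int64) % MINUTES_PER_DAY
    # minimum of the modulation at the phase clock time
    return -noise.circadian_amplitude * np.cos(
        2.0 * np.pi * (minute_of_day - phase) / MINUTES_PER_DAY
    )


def _ar1(n: int, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.sigma == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, noise.sigma, size=n)
    innov[0] = rng.normal(0.0, noise.sigma / np.sqrt(1.0 - noise.phi**2))
    return lfilter([1.0], [1.0, -noise.phi], innov)


def effect_to_pd9(
    ce: np.ndarray,
    params: PatientPkParams,
    noise: NoiseSpec,
    seed: int,
    grid: np.ndarray,
    patient_id: str = "sim",
    session_id: str = "s1",
) -> Pd9Series:
    """Map effect-site concentration to a clamped severity series.

    Mean path: ``baseline + span * Ce^h / (ec50^h + Ce^h)`` plus the circadian
    term; realized value adds stationary AR(1) noise and is clamped to
    [-4, +4].  Identical seeds give identical output.
    """
    grid = np.asarray(grid, dtype=np.int64)
    mean_path = params.baseline + params.span * _sigmoid_fraction(ce, params)
    mean_path = mean_path + _circadian_term(grid, noise)
    rng = np.random.default_rng(seed)
    values = np.clip(mean_path + _ar1(len(grid), noise, rng), SCALE_MIN, SCALE_MAX)
    return Pd9Series(
        patient_id=patient_id,
        session_id=session_id,
        values=pd.Series(values, index=grid),
    )


# ---------------------------------------------------------------------------
# Non-wear gaps
# ---------------------------------------------------------------------------

def apply_wear_gaps(series: Pd9Series, spec: WearGapSpec, seed: int) -> Pd9Series:
    """Drop non-wear minutes: the nightly clock interval plus random daytime gaps.

    Remaining values are unchanged; reproducible under ``seed``.  A spec whose
    nightly interval covers the whole day is rejected (no data would remain).
    """
    night = spec.night_minutes_of_day()
    if len(night) >= MINUTES_PER_DAY:
        raise ValidationError(["wear-gap spec removes the entire day; no data would remain"])
    minutes = series.minutes
    if minutes.size == 0:
        return series
    keep = ~np.isin(minutes % MINUTES_PER_DAY, night)
    if spec.daytime_gap_rate > 0:
        rng = np.random.default_rng(seed)
        worn = minutes[keep]
        day_ids = np.unique(worn // MINUTES_PER_DAY)
        drop: list[np.ndarray] = []
        for day in day_ids:
            day_minutes = worn[worn // MINUTES_PER_DAY == day]
            hours_worn = len(day_minutes) / 60.0
            n_gaps = rng.poisson(spec.daytime_gap_rate * hours_worn)
            for _ in range(n_gaps):
                start = rng.choice(day_minutes)
                length = rng.geometric(1.0 / max(spec.gap_length_mean_min, 1.0))
                drop.append(np.arange(start, start + length))
        if drop:
            keep &= ~np.isin(minutes, np.concatenate(drop))
    return replace(series, values=series.values.iloc[np.flatnonzero(keep)])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # substream keyed on (root seed, patient index): adding patients to a
    # cohort never reshuffles existing ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient_index)]))


def _draw_phenotype(mix: Mapping[str, float], rng: np.random.Generator) -> str:
    names = [p for p in PHENOTYPES if mix.get(p, 0.0) > 0]
    probs = np.array([mix[p] for p in names], dtype=float)
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


#: per-phenotype draw ranges: (baseline low/high, target peak severity
#: low/high, hill low/high).  The target peak is where the noise-free mean
#: path tops out on the scale; span is solved from it.
_PHENOTYPE_RANGES = {
    "stable": ((-0.9, -0.4), (0.2, 0.7), (1.8, 2.8)),
    "wearing_off": ((-3.0, -2.1), (-0.3, 0.6), (2.2, 3.5)),
    "brittle_fluctuator": ((-3.2, -2.4), (1.8, 3.2), (2.8, 4.5)),
}


def _draw_params(
    phenotype: str,
    schedule_events: Sequence[MedicationEvent],
    grid: np.ndarray,
    rng: np.random.Generator,
) -> PatientPkParams:
    """Draw PK/PD parameters so the noise-free peak lands where the phenotype says.

    ka/ke/ke0 are drawn so the effect-site peak falls inside the 0.5-2 h
    post-dose band.  ec50 is anchored to the single-dose peak effect-site
    concentration (half-maximal response near the first dose's peak); span is
    then solved so the schedule's noise-free maximum equals the drawn target
    peak severity.
    """
    (b_lo, b_hi), (p_lo, p_hi), (h_lo, h_hi) = _PHENOTYPE_RANGES[phenotype]
    ka = rng.uniform(1.2, 1.9)
    ke = rng.uniform(0.28, 0.42)
    ke0 = rng.uniform(0.9, 1.5)
    hill = rng.uniform(h_lo, h_hi)
    baseline = rng.uniform(b_lo, b_hi)
    target_peak = rng.uniform(p_lo, p_hi)

    # single-dose anchor for ec50: peak effect-site level of the first dose
    ref = schedule_events[0]
    probe_grid = np.arange(ref.time, ref.time + 10 * 60, dtype=np.int64)
    trial = PatientPkParams(
        ka=ka, ke=ke, ke0=ke0, ec50=1.0, hill=hill, baseline=baseline, span=1.0
    )
    cp = plasma_concentration([ref], trial, probe_grid)
    ce_peak = float(effect_site_concentration(cp, ke0).max())
    ec50 = ce_peak * rng.uniform(0.8, 1.2)

    # solve span so the noise-free schedule maximum hits target_peak
    params = PatientPkParams(
        ka=ka, ke=ke, ke0=ke0, ec50=ec50, hill=hill, baseline=baseline, span=1.0
    )
    cp_full = plasma_concentration(schedule_events, params, grid)
    ce_full = effect_site_concentration(cp_full, ke0)
    f_max = float(_sigmoid_fraction(ce_full, params).max())
    span = (target_peak - baseline) / max(f_max, 1e-9)
    return replace(params, span=span)


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[Pd9Series, list[MedicationEvent], PatientPkParams]]:
    """Generate a full synthetic cohort from the study conditions in ``config``.

    For each patient: draw a phenotype and PK/PD parameters from that
    phenotype's distributions, compose plasma -> effect site -> severity ->
    wear gaps over ``n_days`` of the daily dose schedule, and emit the dosing
    log actually used.  A pure function of ``config`` (including its seed).
    """
    start_minute = int(minutes_from_timestamps(_SIM_START)[0])
    grid = np.arange(start_minute, start_minute + config.n_days * MINUTES_PER_DAY, dtype=np.int64)
    cohort: list[tuple[Pd9Series, list[MedicationEvent], PatientPkParams]] = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"sim{i + 1:03d}"
        phenotype = _draw_phenotype(config.phenotype_mix, rng)
        events = [
            MedicationEvent(
                time=start_minute + day * MINUTES_PER_DAY + _clock_to_minutes(d.clock),
                patient_id=pid,
                dose_mg=d.dose_mg,
                formulation=d.formulation,
            )
            for day in range(config.n_days)
            for d in config.dose_schedule
        ]
        events.sort()
        params = _draw_params(phenotype, events, grid, rng)
        cp = plasma_concentration(events, params, grid)
        ce = effect_site_concentration(cp, params.ke0)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        series = effect_to_pd9(
            ce, params, config.noise, noise_seed, grid, patient_id=pid, session_id=f"{pid}-rec"
        )
        gap_seed = int(rng.integers(0, 2**31 - 1))
        series = apply_wear_gaps(series, config.wear_gaps, gap_seed)
        cohort.append((series, events, params))
    return cohort


def write_manifest(
    cohort: Sequence[tuple[Pd9Series, Sequence[MedicationEvent], PatientPkParams]],
    path,
    seed: int,
) -> None:
    """Write one record per patient with all drawn parameters and the root seed."""
    rows = [
        {
            "patient_id": series.patient_id,
            "root_seed": seed,
            "n_events": len(events),
            "ka": p.ka,
            "ke": p.ke,
            "ke0": p.ke0,
            "ec50": p.ec50,
            "hill": p.hill,
            "baseline": p.baseline,
            "span": p.span,
            "cr_ka_factor": p.cr_ka_factor,
        }
        for series, events, p in cohort
    ]
    pd.DataFrame(rows, columns=[
        "patient_id", "root_seed", "n_events", "ka", "ke", "ke0", "ec50",
        "hill", "baseline", "span", "cr_ka_factor",
    ]).to_csv(path, index=False)
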