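import numpy as np
import pandas as pd
import pytest

from levocycle import (
    CohortConfig,
    MedicationEvent,
    NoiseSpec,
    Pd9Series,
)
from levocycle.synthetic import DoseSpec


def make_series(start: int, values, patient_id: str = "p1", session_id: str = "s1") -> Pd9Series:
    """Gap-free series starting at absolute minute ``start``."""
    values = np.asarray(values, dtype=float)
    return Pd9Series(
        patient_id=patient_id,
        session_id=session_id,
        values=pd.Series(values, index=np.arange(start, start + len(values))),
    )


def make_event(time: int, patient_id: str = "p1", dose: float = 100.0) -> MedicationEvent:
    return MedicationEvent(time=time, patient_id=patient_id, dose_mg=dose)


@pytest.fixture
def flat_series():
    """240 gap-free minutes at constant mild-OFF severity."""
    return make_series(1000, np.full(240, -1.5))


@pytest.fixture
def four_dose_schedule():
    return tuple(DoseSpec(c) for c in ("08:00", "11:00", "14:00", "17:00"))


@pytest.fixture
def small_cohort_config(four_dose_schedule):
    """A small mixed cohort, cheap enough for per-test generation."""
    return CohortConfig(
        n_patients=6,
        phenotype_mix={"stable": 0.34, "wearing_off": 0.33, "brittle_fluctuator": 0.33},
        dose_schedule=four_dose_schedule,
        n_days=1,
        noise=NoiseSpec(sigma=0.3, phi=0.8),
        seed=7,
    )
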