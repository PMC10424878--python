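import numpy as np
import pandas as pd
import pytest

from prosirs import SimConfig, generate_cohort

PARAM_VALUE_POOLS = {
    # values straddling each rule threshold, including exact boundaries
    "heart_rate": [70, 85, 90, 91, 95, 120],
    "dose_noradrenaline": [0.0, 0.0, 3.5, 8.0],
    "dose_adrenaline": [0.0, 2.0],
    "dose_dobutamine": [0.0, 5.0],
    "respiratory_rate": [12, 18, 20, 21, 26],
    "paco2": [25, 30, 31.9, 32, 38, 45],
    "emv": [0.0, 0.0, 5.5, 7.2],
    "temperature": [35.0, 35.9, 36.0, 37.2, 38.0, 38.1, 39.5],
    "leukocytes": [2500, 3999, 4000, 8000, 12000, 12001, 16000],
    "spo2": [92, 96, 99],
}


def random_encounter_events(
    rng: np.random.Generator,
    n_events: int = 80,
    minute_range: tuple[int, int] = (-200, 400),
    encounter_id: str = "e1",
) -> pd.DataFrame:
    """Adversarial random chart stream: boundary values, duplicate minutes, all parameters."""
    params = rng.choice(list(PARAM_VALUE_POOLS), size=n_events)
    minutes = rng.integers(minute_range[0], minute_range[1], size=n_events)
    # force some same-minute collisions to exercise charting-order precedence
    n_dup = max(1, n_events // 10)
    minutes[-n_dup:] = minutes[:n_dup]
    values = [float(rng.choice(PARAM_VALUE_POOLS[p])) for p in params]
    frame = pd.DataFrame(
        {
            "encounter_id": encounter_id,
            "minute": minutes,
            "parameter": params,
            "value": values,
        }
    )
    return frame.sort_values("minute", kind="mergesort").reset_index(drop=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-encounter effect-mode cohort shared across tests (seeded, deterministic)."""
    manifest, events = generate_cohort(SimConfig(n_encounters=50, seed=20260926))
    return manifest, events


@pytest.fixture
def toy_manifest():
    return pd.DataFrame(
        {
            "encounter_id": ["a", "b", "c", "d", "e"],
            "admission": [0, 100, 50, 0, 10],
            "end": [5000, 3100, 2050, 10000, 1460],
            "sepsis": [1, 0, 1, 0, 0],
            "sepsis_onset": [3000, pd.NA, 2000, pd.NA, pd.NA],
            "age": [40.0, 55.0, 70.0, 16.0, 33.0],
            "trauma_offset_days": [0, 1, 0, 1, 0],
        }
    )
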