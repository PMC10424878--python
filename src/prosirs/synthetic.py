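"""Seeded synthetic ICU cohort generator.

Emits an encounter manifest plus an irregularly sampled long-format
chart-event stream with parameter-specific charting cadences, ventilation
and catecholamine therapy episodes, and a configurable pre-sepsis
inflammation effect: inside a window before sepsis onset, charted values of
the criterion-relevant parameters are drawn from out-of-range distributions
with configurable uplift probabilities.  With all uplifts at zero ("null
mode") the case and control groups are exchangeable with respect to their
SIRS level series.

Defaults emulate a post-surgical polytrauma ICU cohort: 415 encounters of
which 34% develop sepsis; length-of-stay log-normal with moments matched to
25.4 +- 17.8 days (sepsis) and 8.5 +- 6.8 days (no sepsis).  Abnormality is
injected by sampling values beyond the rule thresholds — never by toggling
criterion states directly — so the rule engine is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chart_io import MANIFEST_COLUMNS

MINUTES_PER_DAY = 1440


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class EffectConfig:
    """Pre-onset inflammation effect for septic encounters.

    Within [onset - window, onset), each charted value of a criterion's
    parameter is replaced by an out-of-range draw with the stated
    probability; ventilation additionally starts with probability
    ``ventilation`` if not already running.
    """

    window: int = 1440  # minutes before onset
    tachycardia: float = 0.4
    fever: float = 0.4
    leukocytes: float = 0.4
    paco2: float = 0.3
    ventilation: float = 0.3
    #: mild persistent (whole-stay) abnormality elevation in septic encounters,
    #: reflecting the stronger post-trauma inflammatory response that precedes sepsis
    chronic: float = 0.12

    def __post_init__(self):
        for name in ("tachycardia", "fever", "leukocytes", "paco2", "ventilation", "chronic"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"effect probability {name} must be in [0, 1]")
        if self.window <= 0:
            raise ValueError("effect window must be positive")

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(
            tachycardia=0.0, fever=0.0, leukocytes=0.0, paco2=0.0, ventilation=0.0, chronic=0.0
        )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (times in minutes unless noted)."""

    n_encounters: int = 415
    sepsis_fraction: float = 143 / 415
    # length-of-stay log-normals, parameters in days
    stay_mean_days_sepsis: float = 25.4
    stay_sd_days_sepsis: float = 17.8
    stay_mean_days_nosepsis: float = 8.5
    stay_sd_days_nosepsis: float = 6.8
    min_stay: int = MINUTES_PER_DAY + 1
    min_time_to_sepsis: int = MINUTES_PER_DAY
    # mean inter-record gaps per parameter
    cadence_heart_rate: float = 5.0
    cadence_spo2: float = 5.0
    cadence_emv: float = 5.0  # during ventilation episodes
    cadence_respiratory_rate: float = 15.0  # off ventilation
    cadence_temperature: float = 120.0
    cadence_paco2: float = 360.0
    cadence_leukocytes: float = 1440.0
    catecholamine_record_gap: float = 60.0  # hourly during therapy
    ventilated_fraction: float = 0.6
    ventilation_mean_days: float = 3.0
    catecholamine_fraction: float = 0.3
    catecholamine_mean_days: float = 2.0
    effect: EffectConfig = field(default_factory=EffectConfig)
    violation_fraction: float = 0.0  # encounters built to fail the cohort filters
    #: optional cap on charting: no events are emitted later than admission +
    #: chart_horizon minutes (manifest times are unaffected).  A pure
    #: performance option for analyses that only read an early-stay window.
    chart_horizon: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.sepsis_fraction < 1.0:
            raise ValueError("sepsis_fraction must be in (0, 1)")
        for name in (
            "cadence_heart_rate",
            "cadence_spo2",
            "cadence_emv",
            "cadence_respiratory_rate",
            "cadence_temperature",
            "cadence_paco2",
            "cadence_leukocytes",
            "catecholamine_record_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_time_to_sepsis >= self.min_stay + MINUTES_PER_DAY * 200:
            raise ValueError("inconsistent stay/time-to-sepsis configuration")
        if not 0.0 <= self.violation_fraction <= 1.0:
            raise ValueError("violation_fraction must be in [0, 1]")

    def null_effect(self) -> "SimConfig":
        return replace(self, effect=EffectConfig.null())


# baseline value distributions (normal loc/scale in clinical units)
_BASELINES = {
    "heart_rate": (85.0, 12.0),
    "spo2": (97.0, 2.0),
    "respiratory_rate": (16.0, 4.0),
    "temperature": (37.0, 0.5),
    "paco2": (40.0, 5.0),
    "leukocytes": (9000.0, 2800.0),
    "emv": (7.0, 1.5),
}

# out-of-range distributions used inside the pre-onset effect window
_ABNORMAL = {
    "heart_rate": (105.0, 8.0, 91.0, None),
    "temperature": (38.6, 0.3, 38.1, 42.4),
    "leukocytes": (14500.0, 1500.0, 12100.0, None),
    "paco2": (28.0, 2.0, None, 31.0),
}


def _record_times(rng: np.random.Generator, start: int, end: int, gap: float) -> np.ndarray:
    """Irregular charting minutes in [start, end) with mean inter-record gap."""
    if end <= start:
        return np.array([], dtype=np.int64)
    n_expect = int((end - start) / gap * 1.6) + 8
    gaps = rng.exponential(gap, size=n_expect)
    times = start + np.cumsum(gaps)
    times = times[times < end]
    return np.unique(np.floor(times).astype(np.int64))


def _abnormal_draw(rng: np.random.Generator, parameter: str, size: int) -> np.ndarray:
    loc, scale, lo, hi = _ABNORMAL[parameter]
    vals = rng.normal(loc, scale, size=size)
    if lo is not None:
        vals = np.maximum(vals, lo)
    if hi is not None:
        vals = np.minimum(vals, hi)
    return vals


_AR_PHI = 0.85  # record-to-record persistence of vital signs


def _baseline_draw(rng: np.random.Generator, parameter: str, size: int) -> np.ndarray:
    """Autocorrelated baseline series: patient offset + stationary AR(1) noise."""
    loc, scale = _BASELINES[parameter]
    if size == 0:
        return np.empty(0)
    offset = rng.normal(0.0, 0.6 * scale)
    innovations = rng.normal(0.0, scale, size=size)
    noise = np.empty(size)
    noise[0] = innovations[0]
    damp = math.sqrt(1.0 - _AR_PHI**2)
    for t in range(1, size):
        noise[t] = _AR_PHI * noise[t - 1] + damp * innovations[t]
    vals = loc + offset + noise
    if parameter in ("leukocytes", "emv", "respiratory_rate", "heart_rate"):
        vals = np.maximum(vals, 0.5)
    if parameter == "spo2":
        vals = np.clip(vals, 50.0, 100.0)
    if parameter == "temperature":
        vals = np.clip(vals, 33.0, 41.0)
    return vals


def generate_cohort(config: SimConfig | None = None, seed: int | None = None):
    """Generate (manifest, events) for a synthetic ICU cohort.

    Byte-identical outputs for identical (config, seed).  Unless a
    ``violation_fraction`` is requested, every encounter satisfies the
    default cohort filters by construction (stay > 24 h, onset >= 24 h after
    admission, age >= 16, trauma offset <= 1 day).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_encounters
    n_sepsis = int(round(n * config.sepsis_fraction))
    septic_flags = np.zeros(n, dtype=int)
    septic_flags[rng.choice(n, size=n_sepsis, replace=False)] = 1

    manifest_rows = []
    event_frames = []
    for i in range(n):
        eid = f"e{i + 1:04d}"
        septic = bool(septic_flags[i])
        violate = rng.random() < config.violation_fraction
        mu, sigma = _lognormal_params(
            config.stay_mean_days_sepsis if septic else config.stay_mean_days_nosepsis,
            config.stay_sd_days_sepsis if septic else config.stay_sd_days_nosepsis,
        )
        stay = int(rng.lognormal(mu, sigma) * MINUTES_PER_DAY)
        stay = max(stay, config.min_stay)
        admission = int(rng.integers(0, 10_000))
        end = admission + stay
        age = float(np.clip(rng.normal(50.0, 20.0), 16.0, 95.0))
        trauma_offset = int(rng.integers(0, 2))
        onset = None
        if septic:
            slack = stay - config.min_time_to_sepsis
            onset = admission + config.min_time_to_sepsis + int(rng.random() * slack)
            onset = min(onset, end)
        if violate:
            # break exactly one randomly chosen filter
            which = rng.integers(0, 4)
            if which == 0:
                age = float(rng.uniform(1.0, 15.9))
            elif which == 1:
                stay = int(rng.integers(60, MINUTES_PER_DAY - 1))
                end = admission + stay
                onset = admission + stay if septic else None
            elif which == 2:
                trauma_offset = int(rng.integers(2, 10))
            elif which == 3 and septic:
                onset = admission + int(rng.integers(30, config.min_time_to_sepsis - 1))

        events = _encounter_events(rng, eid, admission, end, onset, config)
        event_frames.append(events)
        manifest_rows.append(
            {
                "encounter_id": eid,
                "admission": admission,
                "end": end,
                "sepsis": int(septic),
                "sepsis_onset": onset if septic else pd.NA,
                "age": round(age, 1),
                "trauma_offset_days": trauma_offset,
            }
        )

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    events = pd.concat(event_frames, ignore_index=True)
    events = events.sort_values(["encounter_id", "minute"], kind="mergesort").reset_index(
        drop=True
    )
    return manifest, events


def _effect_mask(times: np.ndarray, onset: int | None, window: int) -> np.ndarray:
    if onset is None:
        return np.zeros(len(times), dtype=bool)
    return (times >= onset - window) & (times < onset)


def _encounter_events(rng, eid, admission, end, onset, config: SimConfig) -> pd.DataFrame:
    effect = config.effect
    chart_end = (
        end if config.chart_horizon is None else min(end, admission + config.chart_horizon)
    )
    frames = []

    def emit(parameter: str, minutes: np.ndarray, values: np.ndarray):
        if len(minutes):
            frames.append(
                pd.DataFrame(
                    {
                        "encounter_id": eid,
                        "minute": minutes.astype(np.int64),
                        "parameter": parameter,
                        "value": values,
                    }
                )
            )

    def uplifted(parameter: str, times: np.ndarray, acute_p: float) -> np.ndarray:
        """Baseline series with abnormal replacements (acute pre-onset + chronic)."""
        vals = _baseline_draw(rng, parameter, len(times))
        if onset is not None and len(times):
            p = np.where(_effect_mask(times, onset, effect.window), acute_p, effect.chronic)
            replace_mask = rng.random(len(times)) < p
            vals[replace_mask] = _abnormal_draw(rng, parameter, int(replace_mask.sum()))
        return vals

    # heart rate and SpO2 anchor the record span exactly at admission and end
    hr_times = _record_times(rng, admission, chart_end, config.cadence_heart_rate)
    hr_times = np.unique(np.concatenate([[admission], hr_times, [chart_end]]))
    emit("heart_rate", hr_times, uplifted("heart_rate", hr_times, effect.tachycardia))

    spo2_times = _record_times(rng, admission, chart_end, config.cadence_spo2)
    emit("spo2", spo2_times, _baseline_draw(rng, "spo2", len(spo2_times)))

    t_times = _record_times(rng, admission, chart_end, config.cadence_temperature)
    emit("temperature", t_times, uplifted("temperature", t_times, effect.fever))

    l_times = _record_times(rng, admission, chart_end, config.cadence_leukocytes)
    emit("leukocytes", l_times, uplifted("leukocytes", l_times, effect.leukocytes))

    p_times = _record_times(rng, admission, chart_end, config.cadence_paco2)
    emit("paco2", p_times, uplifted("paco2", p_times, effect.paco2))

    # ventilation episodes: EMV charted during episodes, zero record at stop
    episodes = []
    if rng.random() < config.ventilated_fraction:
        vent_len = int(rng.lognormal(*_lognormal_params(config.ventilation_mean_days, 1.5)) * MINUTES_PER_DAY)
        # ventilation after polytrauma starts early (within 12 h of admission);
        # an absolute offset keeps the early-stay event law independent of stay length
        vent_start = admission + int(rng.uniform(0, 720))
        episodes.append((vent_start, min(vent_start + max(vent_len, 60), end)))
    if onset is not None and effect.ventilation > 0 and rng.random() < effect.ventilation:
        pre_start = max(admission, onset - effect.window)
        if not any(a <= pre_start and onset <= b for a, b in episodes):
            episodes.append((pre_start, min(onset + 120, end)))
    for a, b in episodes:
        if a >= chart_end:
            continue
        e_times = _record_times(rng, a, min(b, chart_end), config.cadence_emv)
        e_times = np.unique(np.concatenate([[a], e_times]))
        emit("emv", e_times, _baseline_draw(rng, "emv", len(e_times)))
        if b < end and b <= chart_end:
            emit("emv", np.array([b]), np.array([0.0]))

    # respiratory rate charted off ventilation
    rr_times = _record_times(rng, admission, chart_end, config.cadence_respiratory_rate)
    if episodes:
        off = np.ones(len(rr_times), dtype=bool)
        for a, b in episodes:
            off &= ~((rr_times >= a) & (rr_times < b))
        rr_times = rr_times[off]
    emit("respiratory_rate", rr_times, _baseline_draw(rng, "respiratory_rate", len(rr_times)))

    # catecholamine therapy: dose records at start, hourly, and a zero at stop
    if rng.random() < config.catecholamine_fraction:
        drug = ("dose_noradrenaline", "dose_adrenaline", "dose_dobutamine")[rng.integers(0, 3)]
        dur = int(rng.lognormal(*_lognormal_params(config.catecholamine_mean_days, 1.5)) * MINUTES_PER_DAY)
        # circulatory support likewise starts early (within 2 days), absolute offset
        start = admission + int(rng.uniform(0, 2880))
        stop = min(start + max(dur, 120), end)
        if start < chart_end:
            d_times = _record_times(rng, start, min(stop, chart_end), config.catecholamine_record_gap)
            d_times = np.unique(np.concatenate([[start], d_times]))
            emit(drug, d_times, rng.uniform(2.0, 20.0, size=len(d_times)))
            if stop < end and stop <= chart_end:
                emit(drug, np.array([stop]), np.array([0.0]))

    if not frames:
        return pd.DataFrame(columns=["encounter_id", "minute", "parameter", "value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("minute", kind="mergesort").reset_index(drop=True)


def write_cohort(manifest: pd.DataFrame, events: pd.DataFrame, out_dir) -> tuple[str, str]:
    """Write manifest and events CSVs in the chart_io input schema."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    events_path = os.path.join(out_dir, "events.csv")
    manifest.to_csv(manifest_path, index=False)
    events.rename(columns={"minute": "time"}).to_csv(events_path, index=False)
    return manifest_path, events_path
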