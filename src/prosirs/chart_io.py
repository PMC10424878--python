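"""Reading, validation and filtering of ICU chart-event streams and encounter manifests.

Chart events are long-format records: one timestamped measurement of one
clinical parameter for one encounter.  All downstream logic runs on an
integer minute grid; timestamps are floored to whole minutes on ingest.

The canonical CSV schema is ``encounter_id,time,parameter,value`` for events
and ``encounter_id,admission,end,sepsis,sepsis_onset,age,trauma_offset_days``
for the encounter manifest.  A *dialect* (column-name mapping) adapts other
headers to this schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("prosirs")

#: Clinical parameters the rule engine understands.  Rows naming anything
#: else are dropped on ingest (with a logged count).
KNOWN_PARAMETERS = frozenset(
    {
        "heart_rate",
        "dose_noradrenaline",
        "dose_adrenaline",
        "dose_dobutamine",
        "respiratory_rate",
        "paco2",
        "emv",
        "temperature",
        "leukocytes",
        "spo2",
    }
)

#: Parameters whose values must be non-negative (drug doses, expired minute volume).
NONNEGATIVE_PARAMETERS = frozenset(
    {"dose_noradrenaline", "dose_adrenaline", "dose_dobutamine", "emv"}
)

#: Parameters that define the ICU record span (admission / end of stay).
SPAN_PARAMETERS = frozenset({"heart_rate", "spo2"})

EVENT_COLUMNS = ["encounter_id", "minute", "parameter", "value"]

#: Temperature artifact bounds (degrees C): records at or beyond these bounds
#: are treated as mis-recorded ambient temperatures / sensor errors.
TEMPERATURE_ARTIFACT_LOW = 29.0
TEMPERATURE_ARTIFACT_HIGH = 42.5


class ChartDataError(ValueError):
    """Raised for unparseable or structurally invalid chart data."""


def _times_to_minutes(raw: pd.Series) -> pd.Series:
    """Convert a time column (integer minutes or ISO-8601 timestamps) to int minutes.

    ISO timestamps are measured from the Unix epoch and floored to the minute.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return np.floor(numeric).astype(np.int64)
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & numeric.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise ChartDataError(f"unparseable timestamp {raw.loc[row]!r} in row {row}")
    minutes = parsed.astype("int64") // (60 * 10**9)
    # mixed numeric / ISO columns: prefer the numeric reading where available
    out = minutes.where(numeric.isna(), np.floor(numeric)).astype(np.int64)
    return out


def read_chart_events(
    path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a long-format chart-event CSV into the canonical event frame.

    Parameters
    ----------
    path : str or file-like
        CSV with (mapped) columns encounter_id, time, parameter, value.
    dialect : mapping, optional
        Maps canonical names {"encounter_id","time","parameter","value"} to
        the column names actually present in the file.

    Returns
    -------
    DataFrame with columns encounter_id, minute, parameter, value, sorted by
    (encounter_id, minute) with the input order preserved for ties.  Unknown
    parameters are dropped with a logged count.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path)
    colmap = {
        canonical: dialect.get(canonical, canonical)
        for canonical in ("encounter_id", "time", "parameter", "value")
    }
    missing = [src for src in colmap.values() if src not in frame.columns]
    if missing:
        raise ChartDataError(f"missing mapped column(s): {missing}")
    if frame.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {"minute": np.int64, "value": float}
        )

    events = pd.DataFrame(
        {
            "encounter_id": frame[colmap["encounter_id"]].astype(str),
            "minute": _times_to_minutes(frame[colmap["time"]]),
            "parameter": frame[colmap["parameter"]].astype(str),
            "value": pd.to_numeric(frame[colmap["value"]], errors="coerce"),
        }
    )
    bad_value = events["value"].isna() | ~np.isfinite(events["value"])
    if bad_value.any():
        row = int(bad_value.idxmax())
        raise ChartDataError(f"non-numeric or non-finite value in row {row}")

    known = events["parameter"].isin(KNOWN_PARAMETERS)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("read_chart_events: dropped %d event(s) with unknown parameters", n_dropped)
    events = events[known]

    negative = events["parameter"].isin(NONNEGATIVE_PARAMETERS) & (events["value"] < 0)
    if negative.any():
        row = int(negative.idxmax())
        raise ChartDataError(f"negative dose/EMV value in row {row}")

    # stable sort keeps the charting order of same-minute records
    events = events.sort_values(["encounter_id", "minute"], kind="mergesort")
    return events.reset_index(drop=True)


def write_chart_events(events: pd.DataFrame, path) -> None:
    """Write the canonical event frame back to CSV (round-trips with read_chart_events)."""
    out = events.rename(columns={"minute": "time"})
    out.to_csv(path, index=False, columns=["encounter_id", "time", "parameter", "value"])


def filter_artifact_temperatures(
    events: pd.DataFrame,
    low: float = TEMPERATURE_ARTIFACT_LOW,
    high: float = TEMPERATURE_ARTIFACT_HIGH,
) -> pd.DataFrame:
    """Drop physically implausible temperature records (value <= low or >= high).

    Such records typically mirror ambient-temperature recordings after sensor
    dislocation.  Non-temperature events pass through untouched; the operation
    is idempotent.
    """
    is_temp = events["parameter"] == "temperature"
    artifact = is_temp & ((events["value"] <= low) | (events["value"] >= high))
    n = int(artifact.sum())
    if n:
        logger.info("filter_artifact_temperatures: removed %d artifact record(s)", n)
    return events[~artifact].reset_index(drop=True)


def derive_admission_and_end(events: pd.DataFrame, encounter_id: str) -> tuple[int, int]:
    """Admission and end-of-stay minutes for one encounter.

    The admission time point is the first chart minute with a valid heart
    rate or pulse-oximetric SpO2 value; the end of the stay is determined
    symmetrically as the last such minute.
    """
    sub = events[
        (events["encounter_id"].astype(str) == str(encounter_id))
        & events["parameter"].isin(SPAN_PARAMETERS)
    ]
    if sub.empty:
        raise ChartDataError(
            f"encounter {encounter_id!r} has no heart_rate or spo2 record; span undefined"
        )
    return int(sub["minute"].min()), int(sub["minute"].max())


MANIFEST_COLUMNS = [
    "encounter_id",
    "admission",
    "end",
    "sepsis",
    "sepsis_onset",
    "age",
    "trauma_offset_days",
]


def read_manifest(path) -> pd.DataFrame:
    """Read an encounter manifest CSV and validate its basic invariants."""
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ChartDataError(f"manifest missing column(s): {missing}")
    manifest = manifest.copy()
    manifest["encounter_id"] = manifest["encounter_id"].astype(str)
    for col in ("admission", "end"):
        manifest[col] = manifest[col].astype(np.int64)
    manifest["sepsis"] = manifest["sepsis"].astype(int)
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: pd.DataFrame) -> None:
    if (manifest["end"] <= manifest["admission"]).any():
        bad = manifest.loc[manifest["end"] <= manifest["admission"], "encounter_id"].iloc[0]
        raise ChartDataError(f"encounter {bad!r}: end must be after admission")
    septic = manifest[manifest["sepsis"] == 1]
    onset = septic["sepsis_onset"]
    if onset.isna().any():
        bad = septic.loc[onset.isna(), "encounter_id"].iloc[0]
        raise ChartDataError(f"septic encounter {bad!r} lacks sepsis_onset")
    out_of_span = (onset <= septic["admission"]) | (onset > septic["end"])
    if out_of_span.any():
        bad = septic.loc[out_of_span, "encounter_id"].iloc[0]
        raise ChartDataError(f"encounter {bad!r}: sepsis_onset outside (admission, end]")


@dataclass(frozen=True)
class CohortFilterReport:
    """Per-filter exclusion counts from :func:`apply_cohort_filters`."""

    n_input: int
    n_retained: int
    excluded_age: int
    excluded_stay: int
    excluded_trauma_offset: int
    excluded_time_to_sepsis: int


def apply_cohort_filters(
    manifest: pd.DataFrame,
    min_age: float = 16.0,
    min_stay: int = 1440,
    min_time_to_sepsis: int = 1440,
    max_trauma_offset: int = 1,
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply the timing/age exclusion filters to an encounter manifest.

    Retains encounters with age >= ``min_age`` (inclusive boundary), stay
    >= ``min_stay`` minutes, trauma-onset offset <= ``max_trauma_offset``
    days and — for septic encounters — onset at least ``min_time_to_sepsis``
    minutes after admission.  Order-preserving; returns the retained subset
    plus per-filter exclusion counts (counted independently per filter).
    """
    age_ok = manifest["age"] >= min_age
    stay_ok = (manifest["end"] - manifest["admission"]) >= min_stay
    trauma_ok = manifest["trauma_offset_days"] <= max_trauma_offset
    septic = manifest["sepsis"] == 1
    tts_ok = ~septic | (
        (manifest["sepsis_onset"] - manifest["admission"]) >= min_time_to_sepsis
    )
    keep = age_ok & stay_ok & trauma_ok & tts_ok
    report = CohortFilterReport(
        n_input=len(manifest),
        n_retained=int(keep.sum()),
        excluded_age=int((~age_ok).sum()),
        excluded_stay=int((~stay_ok).sum()),
        excluded_trauma_offset=int((~trauma_ok).sum()),
        excluded_time_to_sepsis=int((~tts_ok).sum()),
    )
    logger.info("apply_cohort_filters: %s", report)
    return manifest[keep].reset_index(drop=True), report
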