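"""Construction of the sepsis prediction and diagnosis task datasets.

*Prediction* uses the first 24 h after ICU admission: one descriptor row per
encounter, labelled with the sepsis-ever flag S irrespective of follow-up
time, plus the time-to-event T (onset - admission for cases, end - admission
for non-cases) for survival modelling.

*Diagnosis* uses the last 24 h before an index time in a nested case-control
design: for each septic encounter (case) with treatment duration
tau = onset - admission, the risk set consists of all other admissions
treated at least tau minutes; each control's index time is its own admission
plus tau.  A control may appear in many risk sets (once per case), each time
with a different window; cases with identical tau share an identical risk
set and are counted in one stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .descriptors import compute_descriptors
from .sirs_engine import RuleConfig, all_criterion_intervals, level_series
from .weighting import WeightingScheme

logger = logging.getLogger("prosirs")

WINDOW_LENGTH = 1440  # minutes; 24 h

DESCRIPTOR_COLUMNS = [
    "encounter_id",
    "task",
    "scheme",
    "lambda_mean",
    "lambda_trend",
    "n_changes",
    "outcome",
    "time_to_event",
    "stratum",
    "window_start",
    "window_end",
]


def _descriptor_row(events_by_encounter, encounter_id, window, scheme, config):
    ev = events_by_encounter.get(encounter_id)
    if ev is None:
        ev = pd.DataFrame(columns=["encounter_id", "minute", "parameter", "value"])
    sets = all_criterion_intervals(ev, config, horizon=window)
    series = level_series(sets, scheme, window)
    return compute_descriptors(series)


def _group_events(events: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {str(eid): sub for eid, sub in events.groupby("encounter_id", sort=False)}


def build_prediction_dataset(
    manifest: pd.DataFrame,
    events: pd.DataFrame,
    scheme: WeightingScheme,
    config: RuleConfig | None = None,
    window_length: int = WINDOW_LENGTH,
) -> pd.DataFrame:
    """One descriptor row per encounter over [admission, admission + L).

    outcome = sepsis-ever flag; time_to_event = onset - admission for cases
    and end - admission for censored encounters.
    """
    config = config or RuleConfig()
    by_enc = _group_events(events)
    rows = []
    for enc in manifest.itertuples(index=False):
        admission, end = int(enc.admission), int(enc.end)
        if end - admission < window_length:
            raise ValueError(
                f"encounter {enc.encounter_id!r}: record span shorter than the "
                f"{window_length}-min prediction window"
            )
        window = (admission, admission + window_length)
        lam, trend, changes = _descriptor_row(by_enc, str(enc.encounter_id), window, scheme, config)
        septic = int(enc.sepsis) == 1
        t_event = (int(enc.sepsis_onset) - admission) if septic else (end - admission)
        rows.append(
            {
                "encounter_id": str(enc.encounter_id),
                "task": "prediction",
                "scheme": scheme.id,
                "lambda_mean": lam,
                "lambda_trend": trend,
                "n_changes": changes,
                "outcome": int(septic),
                "time_to_event": t_event,
                "stratum": pd.NA,
                "window_start": window[0],
                "window_end": window[1],
            }
        )
    return pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)


@dataclass
class RiskSet:
    """Matched risk set for one septic case in the diagnosis task."""

    stratum: int
    case_id: str
    tau: int  # case treatment duration until onset, minutes
    case_index_minute: int  # = case admission + tau = onset
    controls: list[tuple[str, int]] = field(default_factory=list)  # (encounter_id, index_minute)


def build_diagnosis_risksets(
    manifest: pd.DataFrame, strict_at_risk: bool = True
) -> list[RiskSet]:
    """One risk set per septic case, matched on ICU length-of-stay.

    Eligible controls for a case with treatment duration tau are all *other*
    admissions with stay >= tau.  With ``strict_at_risk`` (default) an
    encounter already septic by tau minutes after its own admission is not
    an eligible control (the at-risk convention of nested case-control
    sampling); set it False for the permissive stay-only reading.
    Cases sharing an identical tau have identical risk sets and share a
    stratum id.
    """
    cases = manifest[manifest["sepsis"] == 1]
    if cases["sepsis_onset"].isna().any():
        bad = cases.loc[cases["sepsis_onset"].isna(), "encounter_id"].iloc[0]
        raise ValueError(f"case {bad!r} lacks a sepsis onset time")
    taus = (cases["sepsis_onset"].astype(int) - cases["admission"]).to_dict()
    stay = (manifest["end"] - manifest["admission"]).astype(int)
    stratum_of_tau = {t: i + 1 for i, t in enumerate(sorted(set(taus.values())))}

    risksets = []
    for idx, case in cases.iterrows():
        tau = int(taus[idx])
        controls = []
        for jdx, cand in manifest.iterrows():
            if str(cand.encounter_id) == str(case.encounter_id):
                continue
            if stay[jdx] < tau:
                continue
            if strict_at_risk and int(cand.sepsis) == 1:
                own_tau = int(cand.sepsis_onset) - int(cand.admission)
                if own_tau <= tau:
                    continue
            controls.append((str(cand.encounter_id), int(cand.admission) + tau))
        risksets.append(
            RiskSet(
                stratum=stratum_of_tau[tau],
                case_id=str(case.encounter_id),
                tau=tau,
                case_index_minute=int(case.admission) + tau,
                controls=controls,
            )
        )
    return risksets


def n_strata(risksets: list[RiskSet]) -> int:
    return len({rs.stratum for rs in risksets})


def total_controls(risksets: list[RiskSet]) -> int:
    """Control count summed with multiplicity across risk sets."""
    return sum(len(rs.controls) for rs in risksets)


def build_diagnosis_dataset(
    risksets: list[RiskSet],
    manifest: pd.DataFrame,
    events: pd.DataFrame,
    scheme: WeightingScheme,
    config: RuleConfig | None = None,
    window_length: int = WINDOW_LENGTH,
) -> pd.DataFrame:
    """Descriptor rows over the last L minutes before each index time.

    One row per case (window ending at its sepsis onset) and one row per
    control occurrence per risk set (window ending at that risk set's index
    time).  Rows whose window would start before the encounter's admission
    are dropped with a logged warning.
    """
    config = config or RuleConfig()
    by_enc = _group_events(events)
    admission = manifest.set_index(manifest["encounter_id"].astype(str))["admission"].to_dict()
    rows = []
    n_dropped = 0

    def add_row(encounter_id: str, index_minute: int, outcome: int, stratum: int) -> None:
        nonlocal n_dropped
        window = (index_minute - window_length, index_minute)
        if window[0] < admission[encounter_id]:
            n_dropped += 1
            logger.warning(
                "diagnosis window for %s at index %d underflows admission; row dropped",
                encounter_id,
                index_minute,
            )
            return
        lam, trend, changes = _descriptor_row(by_enc, encounter_id, window, scheme, config)
        rows.append(
            {
                "encounter_id": encounter_id,
                "task": "diagnosis",
                "scheme": scheme.id,
                "lambda_mean": lam,
                "lambda_trend": trend,
                "n_changes": changes,
                "outcome": outcome,
                "time_to_event": pd.NA,
                "stratum": stratum,
                "window_start": window[0],
                "window_end": window[1],
            }
        )

    seen_case_strata = set()
    for rs in risksets:
        add_row(rs.case_id, rs.case_index_minute, 1, rs.stratum)
        if rs.stratum in seen_case_strata:
            continue  # identical tau => identical control set; emit controls once per stratum
        seen_case_strata.add(rs.stratum)
        for control_id, index_minute in rs.controls:
            add_row(control_id, index_minute, 0, rs.stratum)
    if n_dropped:
        logger.warning("build_diagnosis_dataset: dropped %d underflowing row(s)", n_dropped)
    return pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
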