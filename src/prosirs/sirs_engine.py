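"""Prospective SIRS rule engine.

Converts one encounter's chart-event stream into per-criterion validity
intervals on the minute grid and into a per-minute weighted SIRS level
series.  The engine is strictly prospective: the state at minute t depends
only on records charted at or before t.

Rule frame
----------
Every record of an involved parameter is taken at face value when charted.
An out-of-range record opens criterion validity at its chart minute for at
most the criterion's maximum validity length; a subsequent record that
re-enters the normal range (or, for therapy-style sub-criteria, a zero
record) terminates validity at its own chart minute.  Intervals are
half-open ``[start, end)`` minutes: a record at minute t affects minute t,
and a terminating record at minute u makes the criterion false from u on.

Criteria and default rules (thresholds in clinical units, maximum validity):

* TC (tachycardia) = heart rate > 90 /min (30 min)  OR  any positive
  catecholamine dose — noradrenaline, adrenaline or dobutamine (60 min;
  each drug tracked as its own stream, terminated by a zero dose of the
  same drug).
* TP (tachypnea) = EMV > 0 L (mechanical ventilation, 60 min)  OR
  respiratory rate > 20 /min (30 min)  OR  PaCO2 < 32 mmHg (480 min).
  A respiratory-rate or PaCO2 record opens nothing if any EMV record > 0
  was charted within the preceding hour (closed lookback [t-60, t]), and
  an EMV record > 0 terminates open RR/PaCO2 validity.
* Tem = temperature outside [36, 38] degrees C (240 min).
* Leu = leukocyte count outside [4000, 12000] /uL (1440 min).

The ``non_icu`` variant drops the ICU-specific adjustments: catecholamine
and EMV sub-criteria are disabled and EMV neither suppresses nor terminates
the RR/PaCO2 sub-criteria; temperature and leukocyte rules are unchanged.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .weighting import CRITERIA, WeightingScheme

Variant = str  # "prospective" | "non_icu"
VARIANTS = ("prospective", "non_icu")

CATECHOLAMINES = ("dose_noradrenaline", "dose_adrenaline", "dose_dobutamine")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and maximum validity lengths (minutes) of the rule set.

    Defaults reproduce the published rule table.  ``catecholamine_validity``
    defaults to 60 min; a 30-min reading of the same rule is in circulation
    and can be configured here.
    """

    variant: Variant = "prospective"
    heart_rate_threshold: float = 90.0
    heart_rate_validity: int = 30
    catecholamine_validity: int = 60
    emv_validity: int = 60
    respiratory_rate_threshold: float = 20.0
    respiratory_rate_validity: int = 30
    paco2_threshold: float = 32.0
    paco2_validity: int = 480
    temperature_range: tuple[float, float] = (36.0, 38.0)
    temperature_validity: int = 240
    leukocyte_range: tuple[float, float] = (4000.0, 12000.0)
    leukocyte_validity: int = 1440
    emv_lookback: int = 60  # "within the preceding hour", closed [t-60, t]

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in (
            "heart_rate_validity",
            "catecholamine_validity",
            "emv_validity",
            "respiratory_rate_validity",
            "paco2_validity",
            "temperature_validity",
            "leukocyte_validity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_variant(self, variant: Variant) -> "RuleConfig":
        return replace(self, variant=variant)


@dataclass
class CriterionIntervalSet:
    """Sorted, disjoint half-open minute intervals during which one criterion holds."""

    criterion: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def total_minutes(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def contains(self, minute: int) -> bool:
        i = bisect_right(self.intervals, (minute, np.inf)) - 1
        return i >= 0 and self.intervals[i][0] <= minute < self.intervals[i][1]

    def indicator(self, window: tuple[int, int]) -> np.ndarray:
        """Boolean per-minute fulfillment over ``window = [start, end)``."""
        start, end = window
        out = np.zeros(end - start, dtype=bool)
        for a, b in self.intervals:
            lo, hi = max(a, start), min(b, end)
            if lo < hi:
                out[lo - start : hi - start] = True
        return out


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; touching intervals are merged."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _clip(intervals: list[tuple[int, int]], horizon: tuple[int, int]) -> list[tuple[int, int]]:
    start, end = horizon
    return [(max(a, start), min(b, end)) for a, b in intervals if max(a, start) < min(b, end)]


def _sub_intervals(
    records: list[tuple[int, int, str]],
    maxlen: int,
    suppress_minutes: list[int] | None = None,
    lookback: int = 60,
) -> list[tuple[int, int]]:
    """Validity intervals of one sub-criterion.

    ``records`` is the chronologically ordered (minute, sequence, kind)
    stream relevant to this sub-criterion, kind in {"open", "close"}; the
    sequence number breaks same-minute ties by charting order.  An "open"
    record at minute t starts validity [t, t+maxlen) unless a later "close"
    record ends it earlier; an "open" at t is ignored entirely if a
    suppressing minute lies in [t - lookback, t].
    """
    suppress = sorted(suppress_minutes or [])
    out: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None  # currently open validity [a, b)
    for minute, _seq, kind in records:
        if cur is not None and minute >= cur[1]:
            out.append(cur)
            cur = None
        if kind == "close":
            if cur is not None:
                if minute > cur[0]:
                    out.append((cur[0], minute))
                cur = None
        else:  # open
            if suppress:
                i = bisect_left(suppress, minute - lookback)
                if i < len(suppress) and suppress[i] <= minute:
                    continue
            end = minute + maxlen
            if cur is not None:
                cur = (cur[0], max(cur[1], end))
            else:
                cur = (minute, end)
    if cur is not None:
        out.append(cur)
    return _merge(out)


def _records(
    sub: pd.DataFrame, is_open, extra_closes: list[tuple[int, int]] | None = None
) -> list[tuple[int, int, str]]:
    """Tag a parameter stream with open/close kinds and interleave external closers."""
    recs = [
        (int(m), int(s), "open" if o else "close")
        for m, s, o in zip(sub["minute"], sub["_seq"], is_open)
    ]
    if extra_closes:
        recs.extend((m, s, "close") for m, s in extra_closes)
    # same-minute records resolve by charting order: later record wins
    recs.sort(key=lambda r: (r[0], r[1]))
    return recs


def _prepare(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.reset_index(drop=True).copy()
    ev["_seq"] = np.arange(len(ev))
    return ev


def criterion_intervals(
    events: pd.DataFrame,
    criterion: str,
    config: RuleConfig | None = None,
    horizon: tuple[int, int] | None = None,
) -> CriterionIntervalSet:
    """Validity intervals of one SIRS criterion for one encounter.

    Parameters
    ----------
    events : DataFrame
        One encounter's chart events (canonical columns), sorted by minute
        with charting order preserved.  Records before the horizon are used
        as lookback so validity opened earlier persists into it.
    criterion : {"TC", "TP", "Tem", "Leu"}
    horizon : (start, end), optional
        Half-open minute window the result is clipped to.
    """
    config = config or RuleConfig()
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    ev = _prepare(events)
    if horizon is not None:
        ev = ev[ev["minute"] < horizon[1]]

    def param(name: str) -> pd.DataFrame:
        return ev[ev["parameter"] == name]

    icu = config.variant == "prospective"
    intervals: list[tuple[int, int]] = []

    if criterion == "TC":
        hr = param("heart_rate")
        intervals += _sub_intervals(
            _records(hr, hr["value"] > config.heart_rate_threshold),
            config.heart_rate_validity,
        )
        if icu:
            for drug in CATECHOLAMINES:
                d = param(drug)
                intervals += _sub_intervals(
                    _records(d, d["value"] > 0), config.catecholamine_validity
                )
    elif criterion == "TP":
        emv = param("emv")
        emv_pos = [
            (int(m), int(s)) for m, s, v in zip(emv["minute"], emv["_seq"], emv["value"]) if v > 0
        ]
        if icu:
            intervals += _sub_intervals(_records(emv, emv["value"] > 0), config.emv_validity)
        rr = param("respiratory_rate")
        intervals += _sub_intervals(
            _records(
                rr,
                rr["value"] > config.respiratory_rate_threshold,
                extra_closes=emv_pos if icu else None,
            ),
            config.respiratory_rate_validity,
            suppress_minutes=[m for m, _ in emv_pos] if icu else None,
            lookback=config.emv_lookback,
        )
        pc = param("paco2")
        intervals += _sub_intervals(
            _records(
                pc,
                pc["value"] < config.paco2_threshold,
                extra_closes=emv_pos if icu else None,
            ),
            config.paco2_validity,
            suppress_minutes=[m for m, _ in emv_pos] if icu else None,
            lookback=config.emv_lookback,
        )
    elif criterion == "Tem":
        lo, hi = config.temperature_range
        t = param("temperature")
        intervals += _sub_intervals(
            _records(t, (t["value"] < lo) | (t["value"] > hi)), config.temperature_validity
        )
    else:  # Leu
        lo, hi = config.leukocyte_range
        leu = param("leukocytes")
        intervals += _sub_intervals(
            _records(leu, (leu["value"] < lo) | (leu["value"] > hi)),
            config.leukocyte_validity,
        )

    merged = _merge(intervals)
    if horizon is not None:
        merged = _clip(merged, horizon)
    return CriterionIntervalSet(criterion=criterion, intervals=merged)


def all_criterion_intervals(
    events: pd.DataFrame,
    config: RuleConfig | None = None,
    horizon: tuple[int, int] | None = None,
) -> dict[str, CriterionIntervalSet]:
    """Interval sets for all four criteria."""
    return {c: criterion_intervals(events, c, config, horizon) for c in CRITERIA}


@dataclass
class SirsLevelSeries:
    """Per-minute weighted SIRS levels over a window.

    Levels are held exactly as integer numerators over a common denominator
    (the weights are rationals), so equality of consecutive levels — and
    hence the change count C — is exact.  ``levels`` exposes floats.
    """

    window_start: int
    numerators: np.ndarray  # int64, length L
    denominator: int
    scheme_id: str = "custom"

    @property
    def length(self) -> int:
        return len(self.numerators)

    @property
    def levels(self) -> np.ndarray:
        return self.numerators / self.denominator

    def level_at(self, minute: int) -> float:
        return float(self.numerators[minute - self.window_start] / self.denominator)

    def exact_levels(self) -> list[Fraction]:
        return [Fraction(int(n), self.denominator) for n in self.numerators]


def level_series(
    interval_sets: dict[str, CriterionIntervalSet],
    scheme: WeightingScheme,
    window: tuple[int, int],
) -> SirsLevelSeries:
    """Weighted SIRS level lambda_l for every minute l of ``window = [start, end)``.

    lambda_l = sum_c w_c * 1{criterion c fulfilled in minute l}, in [0, 1].
    Under equal weighting the attainable values {0, .25, .5, .75, 1}
    correspond to 0..4 concurrently fulfilled criteria.
    """
    start, end = window
    if end <= start:
        raise ValueError("window must be non-empty")
    if sum(scheme.weights) != 1 or any(w < 0 for w in scheme.weights):
        raise ValueError("weights must be non-negative and sum to 1")
    nums, denom = scheme.integer_weights()
    acc = np.zeros(end - start, dtype=np.int64)
    for criterion, w_num in zip(CRITERIA, nums):
        if w_num == 0:
            continue
        acc += w_num * interval_sets[criterion].indicator(window)
    return SirsLevelSeries(
        window_start=start, numerators=acc, denominator=denom, scheme_id=scheme.id
    )


def conventional_sirs_flag(
    interval_sets: dict[str, CriterionIntervalSet], window: tuple[int, int]
) -> bool:
    """Traditional SIRS call: >= 2 criteria concurrently fulfilled for >= 1 minute.

    Equivalent to the equal-weighting level reaching 0.5 in some minute of
    the window.
    """
    start, end = window
    count = np.zeros(end - start, dtype=np.int64)
    for c in CRITERIA:
        count += interval_sets[c].indicator(window)
    return bool((count >= 2).any())
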