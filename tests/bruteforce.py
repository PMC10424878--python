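"""Independent brute-force oracles used by the test suite.

The per-minute SIRS rule oracle transcribes the criterion sentences
directly, rescanning the record list for every minute.  It is deliberately
structured record-by-record (not interval-by-interval) so it shares no code
or representation with the production engine.
"""

from __future__ import annotations

import pandas as pd

from prosirs.sirs_engine import CATECHOLAMINES, RuleConfig


def _tagged(events: pd.DataFrame, parameter: str) -> list[tuple[int, int, float]]:
    """(minute, charting sequence, value) records of one parameter."""
    ev = events.reset_index(drop=True)
    sub = ev[ev["parameter"] == parameter]
    return [(int(m), int(s), float(v)) for s, (m, v) in zip(sub.index, zip(sub["minute"], sub["value"]))]


def _sub_fulfilled(
    minute: int,
    abnormal: list[tuple[int, int, float]],
    terminators: list[tuple[int, int]],
    maxlen: int,
    suppressors: list[int] | None = None,
    lookback: int = 60,
) -> bool:
    """Does any abnormal record keep this sub-criterion valid at `minute`?"""
    for t, s, _v in abnormal:
        if not (t <= minute < t + maxlen):
            continue
        if suppressors is not None and any(t - lookback <= u <= t for u in suppressors):
            continue
        killed = any(uq <= minute and (uq, sq) > (t, s) for uq, sq in terminators)
        if not killed:
            return True
    return False


def criterion_fulfilled_at(
    events: pd.DataFrame, criterion: str, minute: int, config: RuleConfig | None = None
) -> bool:
    """Per-minute transcription of the published rule sentences."""
    config = config or RuleConfig()
    icu = config.variant == "prospective"

    if criterion == "TC":
        hr = _tagged(events, "heart_rate")
        abnormal = [r for r in hr if r[2] > config.heart_rate_threshold]
        terminators = [(t, s) for t, s, v in hr if v <= config.heart_rate_threshold]
        if _sub_fulfilled(minute, abnormal, terminators, config.heart_rate_validity):
            return True
        if icu:
            for drug in CATECHOLAMINES:
                d = _tagged(events, drug)
                if _sub_fulfilled(
                    minute,
                    [r for r in d if r[2] > 0],
                    [(t, s) for t, s, v in d if v == 0],
                    config.catecholamine_validity,
                ):
                    return True
        return False

    if criterion == "TP":
        emv = _tagged(events, "emv")
        emv_pos = [(t, s) for t, s, v in emv if v > 0]
        if icu and _sub_fulfilled(
            minute, [r for r in emv if r[2] > 0], [(t, s) for t, s, v in emv if v == 0],
            config.emv_validity,
        ):
            return True
        rr = _tagged(events, "respiratory_rate")
        rr_term = [(t, s) for t, s, v in rr if v <= config.respiratory_rate_threshold]
        if icu:
            rr_term = rr_term + emv_pos
        if _sub_fulfilled(
            minute,
            [r for r in rr if r[2] > config.respiratory_rate_threshold],
            rr_term,
            config.respiratory_rate_validity,
            suppressors=[t for t, _ in emv_pos] if icu else None,
            lookback=config.emv_lookback,
        ):
            return True
        pc = _tagged(events, "paco2")
        pc_term = [(t, s) for t, s, v in pc if v >= config.paco2_threshold]
        if icu:
            pc_term = pc_term + emv_pos
        return _sub_fulfilled(
            minute,
            [r for r in pc if r[2] < config.paco2_threshold],
            pc_term,
            config.paco2_validity,
            suppressors=[t for t, _ in emv_pos] if icu else None,
            lookback=config.emv_lookback,
        )

    if criterion == "Tem":
        lo, hi = config.temperature_range
        t = _tagged(events, "temperature")
        return _sub_fulfilled(
            minute,
            [r for r in t if r[2] < lo or r[2] > hi],
            [(m, s) for m, s, v in t if lo <= v <= hi],
            config.temperature_validity,
        )

    if criterion == "Leu":
        lo, hi = config.leukocyte_range
        leu = _tagged(events, "leukocytes")
        return _sub_fulfilled(
            minute,
            [r for r in leu if r[2] < lo or r[2] > hi],
            [(m, s) for m, s, v in leu if lo <= v <= hi],
            config.leukocyte_validity,
        )

    raise ValueError(criterion)


def fulfilled_minutes(
    events: pd.DataFrame, criterion: str, horizon: tuple[int, int], config: RuleConfig | None = None
) -> set[int]:
    return {
        m
        for m in range(horizon[0], horizon[1])
        if criterion_fulfilled_at(events, criterion, m, config)
    }


def pairwise_auroc(probabilities, outcomes) -> float:
    """O(n^2) concordance-count AUROC with half credit for ties."""
    pos = [p for p, y in zip(probabilities, outcomes) if y == 1]
    neg = [p for p, y in zip(probabilities, outcomes) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
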