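"""Window descriptors of a SIRS level series and group-level summaries.

A 24-h (L = 1440 min) level series lambda_1..lambda_L is summarised by

* Lambda — the mean level over the window, in [0, 1],
* Delta  — the trend lambda_L - lambda_1, in [-1, 1],
* C      — the number of minute-to-minute level changes, in {0, .., L-1}.

Level equality for C is evaluated on the exact quantized representation
(integer numerators over the scheme's common denominator), so C counts rule
state changes, never floating-point noise.
"""

from __future__ import annotations

from collections import Counter
from itertools import chain, combinations

import numpy as np
import pandas as pd

from .sirs_engine import CriterionIntervalSet, SirsLevelSeries
from .weighting import CRITERIA


def compute_descriptors(series: SirsLevelSeries) -> tuple[float, float, int]:
    """(Lambda, Delta, C) for one level series; requires length >= 2."""
    n = series.numerators
    if len(n) < 2:
        raise ValueError("descriptors need a series of length >= 2 (trend/changes undefined)")
    lam_mean = float(n.sum() / (series.denominator * len(n)))
    trend = float((int(n[-1]) - int(n[0])) / series.denominator)
    changes = int(np.count_nonzero(n[1:] != n[:-1]))
    return lam_mean, trend, changes


def all_criterion_subsets() -> list[tuple[str, ...]]:
    """The 16 subsets of {TC, TP, Tem, Leu}, empty set first, in stable order."""
    return list(
        chain.from_iterable(combinations(CRITERIA, r) for r in range(len(CRITERIA) + 1))
    )


def combination_frequencies(
    interval_sets_per_encounter: dict[str, dict[str, CriterionIntervalSet]],
    window_per_encounter: dict[str, tuple[int, int]],
    group_labels: dict[str, str],
) -> pd.DataFrame:
    """Share of person-minutes in which exactly each criterion subset is fulfilled.

    For each group g and each of the 16 subsets K of criteria, the
    percentage of the group's person-minutes (n_g encounters x L minutes)
    during which exactly the criteria in K hold concurrently.  Percentages
    sum to 100 within each group.

    Returns a tidy frame: group, combination (e.g. "TC+TP"), minutes, percent.
    """
    if not interval_sets_per_encounter:
        raise ValueError("no encounters given: every group must be non-empty")
    groups = sorted(set(group_labels.values()))
    lengths = {eid: w[1] - w[0] for eid, w in window_per_encounter.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError("all encounter windows must share the same length L")
    counts: dict[str, Counter] = {g: Counter() for g in groups}
    denominators: dict[str, int] = {g: 0 for g in groups}
    for eid, sets in interval_sets_per_encounter.items():
        window = window_per_encounter[eid]
        group = group_labels[eid]
        mask = np.zeros(window[1] - window[0], dtype=np.int64)
        for bit, c in enumerate(CRITERIA):
            mask |= sets[c].indicator(window).astype(np.int64) << bit
        denominators[group] += len(mask)
        codes, n = np.unique(mask, return_counts=True)
        for code, k in zip(codes, n):
            counts[group][int(code)] += int(k)
    for g in groups:
        if denominators[g] == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for g in groups:
        for subset in all_criterion_subsets():
            code = sum(1 << CRITERIA.index(c) for c in subset)
            minutes = counts[g].get(code, 0)
            rows.append(
                {
                    "group": g,
                    "combination": "+".join(subset) if subset else "none",
                    "minutes": minutes,
                    "percent": 100.0 * minutes / denominators[g],
                }
            )
    return pd.DataFrame(rows)


def group_mean_trajectory(
    series_collection: dict[str, SirsLevelSeries], group_labels: dict[str, str]
) -> pd.DataFrame:
    """Per-minute arithmetic mean of lambda within each group.

    All series must share the same window length.  Returns a tidy frame
    (minute, group, mean_level) with minute indexed 1..L within the window.
    """
    lengths = {len(s.numerators) for s in series_collection.values()}
    if len(lengths) > 1:
        raise ValueError("mixed series lengths")
    (length,) = lengths
    groups: dict[str, list[np.ndarray]] = {}
    for eid, series in series_collection.items():
        groups.setdefault(group_labels[eid], []).append(series.levels)
    rows = []
    for g, stack in sorted(groups.items()):
        mean = np.mean(stack, axis=0)
        rows.append(pd.DataFrame({"minute": np.arange(1, length + 1), "group": g, "mean_level": mean}))
    return pd.concat(rows, ignore_index=True)
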