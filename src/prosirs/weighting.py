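"""Weighting schemes for the four SIRS criteria.

A weighting scheme is a non-negative 4-tuple (w_TC, w_TP, w_Tem, w_Leu)
summing to 1, one weight per criterion: tachycardia (TC), tachypnea (TP),
abnormal temperature (Tem), abnormal leukocyte count (Leu).  Schemes are
organised in six composition types:

* type A — equal weights (1/4 each); 1 scheme,
* type B — full weight on exactly one criterion; 4 schemes,
* type C — 1/2 on exactly two criteria; 6 schemes,
* type D — 1/3 on exactly three criteria; 4 schemes,
* type E — one dominant weight of 1/2, the rest 1/6 each; 4 schemes,
* type F — the values (0.4, 0.3, 0.2, 0.1) in every order; 24 schemes,

43 schemes in total.  Weights are exact rationals so that weighted SIRS
levels stay on an exact quantized grid.  Within each type, schemes are
ordered lexicographically by descending weight tuple and numbered
sequentially across the type blocks A..F (ws1..ws43); scheme lookup by
explicit tuple is always available so no analysis needs to rely on ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, permutations
from math import lcm
from typing import Iterable, Sequence

CRITERIA = ("TC", "TP", "Tem", "Leu")


@dataclass(frozen=True)
class WeightingScheme:
    """A criterion weighting (w_TC, w_TP, w_Tem, w_Leu) with exact weights summing to 1."""

    id: str
    type_label: str
    weights: tuple[Fraction, Fraction, Fraction, Fraction]

    def __post_init__(self):
        if len(self.weights) != 4:
            raise ValueError("a weighting scheme needs exactly 4 weights")
        if any(w < 0 for w in self.weights):
            raise ValueError(f"scheme {self.id}: negative weight")
        if sum(self.weights) != 1:
            raise ValueError(f"scheme {self.id}: weights must sum to 1, got {sum(self.weights)}")

    @property
    def as_floats(self) -> tuple[float, float, float, float]:
        return tuple(float(w) for w in self.weights)

    def weight(self, criterion: str) -> Fraction:
        return self.weights[CRITERIA.index(criterion)]

    def integer_weights(self) -> tuple[tuple[int, int, int, int], int]:
        """Weights as integer numerators over their least common denominator."""
        denom = lcm(*(w.denominator for w in self.weights))
        return tuple(int(w * denom) for w in self.weights), denom

    def __str__(self):  # pragma: no cover - cosmetic
        parts = ", ".join(f"w_{c}={w}" for c, w in zip(CRITERIA, self.weights))
        return f"{self.id} (type {self.type_label}): {parts}"


def custom_scheme(weights: Sequence, id: str = "custom") -> WeightingScheme:
    """Build a custom scheme from floats, fractions or strings like '1/3'."""
    fracs = tuple(Fraction(w).limit_denominator(10**6) for w in weights)
    return WeightingScheme(id=id, type_label="custom", weights=fracs)


def _desc(tuples: Iterable[tuple]) -> list[tuple]:
    return sorted(set(tuples), reverse=True)


def enumerate_schemes() -> list[WeightingScheme]:
    """All 43 weighting schemes (types A-F) in their canonical order."""
    half, third, quarter, sixth = (
        Fraction(1, 2),
        Fraction(1, 3),
        Fraction(1, 4),
        Fraction(1, 6),
    )
    zero, one = Fraction(0), Fraction(1)
    blocks: list[tuple[str, list[tuple]]] = []

    blocks.append(("A", [(quarter,) * 4]))

    b = []
    for i in range(4):
        t = [zero] * 4
        t[i] = one
        b.append(tuple(t))
    blocks.append(("B", _desc(b)))

    c = []
    for i, j in combinations(range(4), 2):
        t = [zero] * 4
        t[i] = t[j] = half
        c.append(tuple(t))
    blocks.append(("C", _desc(c)))

    d = []
    for skip in range(4):
        t = [third] * 4
        t[skip] = zero
        d.append(tuple(t))
    blocks.append(("D", _desc(d)))

    e = []
    for i in range(4):
        t = [sixth] * 4
        t[i] = half
        e.append(tuple(t))
    blocks.append(("E", _desc(e)))

    f_values = (Fraction(4, 10), Fraction(3, 10), Fraction(2, 10), Fraction(1, 10))
    blocks.append(("F", _desc(permutations(f_values))))

    schemes: list[WeightingScheme] = []
    counter = 1
    for label, tuples in blocks:
        for weights in tuples:
            schemes.append(WeightingScheme(id=f"ws{counter}", type_label=label, weights=weights))
            counter += 1
    return schemes


_SCHEMES = None


def _all() -> list[WeightingScheme]:
    global _SCHEMES
    if _SCHEMES is None:
        _SCHEMES = enumerate_schemes()
    return _SCHEMES


def scheme_by_id(scheme_id: str) -> WeightingScheme:
    """Look up a scheme by its ws-id (e.g. 'ws18')."""
    for s in _all():
        if s.id == scheme_id:
            return s
    raise KeyError(f"unknown weighting scheme id {scheme_id!r}")


def scheme_by_weights(weights: Sequence) -> WeightingScheme:
    """Look up the enumerated scheme with exactly these weights."""
    target = tuple(Fraction(w).limit_denominator(10**6) for w in weights)
    for s in _all():
        if s.weights == target:
            return s
    raise KeyError(f"no enumerated scheme with weights {weights!r}")


#: The equal weighting scheme (type A) — the traditional SIRS view.
def equal_weighting() -> WeightingScheme:
    return scheme_by_id("ws1")
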