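"""Independent rational-arithmetic oracle for the toy fraction matrix.

Recomputes, from the raw toy counts and with :mod:`fractions` only, every
quantity the translation pipeline produces: depth-normalized counts,
occupancy proportions, TR and STR per donor, reference-group summaries and
qualification flags.  Shares no code with the package implementation (the
Welch p oracle is scipy's own ttest_ind, an independent implementation).
"""
from __future__ import annotations

import math
import statistics
from fractions import Fraction

from conftest import TOY_COUNTS, TOY_DONORS, TOY_GENES

CLASSES = range(4)
DONOR_IDS = [d.donor_id for d in TOY_DONORS]


def class_totals() -> dict[str, list[Fraction]]:
    return {
        d: [Fraction(sum(TOY_COUNTS[g][d][c] for g in TOY_GENES)) for c in CLASSES]
        for d in DONOR_IDS
    }


def proportions() -> dict[tuple[str, str], list[Fraction] | None]:
    """(gene, donor) -> 4 exact proportions, or None if undefined."""
    totals = class_totals()
    out: dict[tuple[str, str], list[Fraction] | None] = {}
    for g in TOY_GENES:
        for d in DONOR_IDS:
            normalized = [Fraction(TOY_COUNTS[g][d][c]) / totals[d][c] for c in CLASSES]
            s = sum(normalized)
            out[(g, d)] = None if s == 0 else [n / s for n in normalized]
    return out


def _ratio(num: Fraction, den: Fraction) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return float(num / den)


def tr(gene: str, donor: str) -> float:
    p = proportions()[(gene, donor)]
    if p is None:
        return math.nan
    return _ratio(p[2] + p[3], p[0] + p[1])


def str_(gene: str, donor: str) -> float:
    p = proportions()[(gene, donor)]
    if p is None:
        return math.nan
    return _ratio(p[3], p[0] + p[1] + p[2])


def summary(values: list[float]) -> tuple[float, float, float, bool]:
    """(mean, sample sd, cv, qualified) over a reference group's values."""
    finite = [v for v in values if math.isfinite(v)]
    if not finite:
        return (math.nan, math.nan, math.nan, False)
    mean = statistics.fmean(finite)
    sd = statistics.stdev(finite) if len(finite) > 1 else 0.0
    cv = sd / mean if mean != 0 else math.nan
    qualified = len(finite) == len(values) and not math.isnan(cv) and cv < 0.5
    return (mean, sd, cv, qualified)
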