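"""Proteomics / phosphoproteomics differential abundance.

Per-donor normalization divides every feature's value by the donor's
total, so each donor column sums to 1 and instrument loading differences
cancel.  Differential calls use the per-row Welch t-test at uncorrected
p < 0.05 with log2 fold change of group means; the volcano classification
adds the |log2FC| > 1 two-fold flag.  Calls from two instruments (e.g. a
Lumos spectral-count set and a TMT Orbitrap set) are merged at the level
of calls, never of numbers: a feature significant in both with opposite
directions is excluded from the combined set and reported.

The phosphoproteomics headline screen is the intersection of the
significant set and the >2-fold set.  ``western_normalize`` implements the
date-matched male/female densitometry arithmetic used to confirm
individual proteins.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AbundanceTable,
    DifferentialResult,
    NormalizationError,
    ValidationError,
)
from .stats import welch_t_test
from .translation import _log2_fold

log = logging.getLogger("polyte")

__all__ = [
    "normalize_abundance",
    "differential_abundance",
    "MergeReport",
    "merge_datasets",
    "cross_condition_compare",
    "collapse_duplicates",
    "differential_phosphorylation",
    "phospho_call_set",
    "western_normalize",
]


def normalize_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each donor column by its total; columns then sum to 1."""
    totals = table.values.sum(axis=0)
    if (totals == 0).any():
        donor = table.donors[int(np.argmax(totals == 0))].donor_id
        raise NormalizationError(f"zero abundance total for donor {donor!r}")
    return AbundanceTable(
        features=list(table.features),
        donors=list(table.donors),
        dataset=table.dataset,
        values=table.values / totals[None, :],
    )


def differential_abundance(
    table: AbundanceTable,
    group_a_donors: Sequence[str],
    group_b_donors: Sequence[str],
    p_cutoff: float = 0.05,
    log2_fold_cutoff: float = 1.0,
    normalize: bool = True,
) -> list[DifferentialResult]:
    """Welch per-feature comparison of group A vs group B donor columns.

    Values are per-donor normalized first (disable with ``normalize=False``
    if the table already is).  A zero mean in one group yields an infinite
    log2 fold change, kept as a sentinel (presence/absence features stay in
    the volcano).
    """
    if len(group_a_donors) < 2 or len(group_b_donors) < 2:
        raise ValidationError("each group needs at least two donors")
    overlap = set(group_a_donors) & set(group_b_donors)
    if overlap:
        raise ValidationError(f"donors in both groups: {sorted(overlap)}")
    if normalize:
        table = normalize_abundance(table)
    ids = table.donor_ids
    ai = [ids.index(d) for d in group_a_donors]
    bi = [ids.index(d) for d in group_b_donors]
    results = []
    for i, feature in enumerate(table.features):
        a = table.values[i, ai]
        b = table.values[i, bi]
        _, _, p = welch_t_test(a, b)
        results.append(
            DifferentialResult.from_stats(
                feature, _log2_fold(float(a.mean()), float(b.mean())), p,
                p_cutoff, log2_fold_cutoff,
            )
        )
    return results


@dataclass
class MergeReport:
    """Outcome of merging differential calls from two instrument datasets."""

    shared_features: list[str]
    a_only: list[str]
    b_only: list[str]
    conflicts_excluded: list[tuple[str, str, str]]  # (feature, dir_in_A, dir_in_B)
    combined_calls: list[DifferentialResult]

    def __post_init__(self) -> None:
        conflict_ids = {c[0] for c in self.conflicts_excluded}
        if conflict_ids & {r.feature for r in self.combined_calls}:
            raise ValidationError("conflicted features must not appear in combined calls")


def merge_datasets(
    calls_a: Sequence[DifferentialResult], calls_b: Sequence[DifferentialResult]
) -> MergeReport:
    """Union of significant calls across two datasets with conflict exclusion.

    A feature significant in both datasets with the same direction appears
    once (the dataset-A record is kept); significant in both with opposite
    directions is excluded and listed in ``conflicts_excluded``; significant
    in exactly one dataset is kept.
    """
    for name, calls in (("A", calls_a), ("B", calls_b)):
        ids = [r.feature for r in calls]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate features in call list {name}")
    by_a = {r.feature: r for r in calls_a}
    by_b = {r.feature: r for r in calls_b}
    shared = sorted(set(by_a) & set(by_b))
    a_only = sorted(set(by_a) - set(by_b))
    b_only = sorted(set(by_b) - set(by_a))

    combined: list[DifferentialResult] = []
    conflicts: list[tuple[str, str, str]] = []
    for f in sorted(set(by_a) | set(by_b)):
        ra, rb = by_a.get(f), by_b.get(f)
        sig_a = ra is not None and ra.significant
        sig_b = rb is not None and rb.significant
        if sig_a and sig_b:
            if ra.direction != rb.direction:
                conflicts.append((f, ra.direction, rb.direction))
                log.warning(
                    "feature %s significant in opposite directions (%s vs %s); excluded",
                    f, ra.direction, rb.direction,
                )
            else:
                combined.append(ra)
        elif sig_a:
            combined.append(ra)
        elif sig_b:
            combined.append(rb)
    return MergeReport(
        shared_features=shared,
        a_only=a_only,
        b_only=b_only,
        conflicts_excluded=conflicts,
        combined_calls=combined,
    )


def cross_condition_compare(
    calls_reference: Sequence[DifferentialResult],
    timepoint_table: AbundanceTable,
    group_a_donors: Sequence[str],
    group_b_donors: Sequence[str],
    p_cutoff: float = 0.05,
) -> list[DifferentialResult]:
    """Group-A vs group-B differential restricted to reference-significant features.

    Implements the stimulated-time-course cross comparison: take exactly the
    features significant in group A's stimulated-vs-unstimulated call list,
    then compare group A against group B on the per-donor values at that
    timepoint.  Features absent from the timepoint table are dropped with a
    log entry.
    """
    wanted = [r.feature for r in calls_reference if r.significant]
    present = set(timepoint_table.features)
    missing = [f for f in wanted if f not in present]
    if missing:
        log.info("cross_condition_compare: %d features missing from table; dropped", len(missing))
    keep = [f for f in wanted if f in present]
    if not keep:
        return []
    # normalize against the FULL table's donor totals before restricting,
    # so the restricted comparison is on the same scale as any other call
    normalized = normalize_abundance(timepoint_table)
    idx = [normalized.features.index(f) for f in keep]
    sub = AbundanceTable(
        features=keep,
        donors=list(normalized.donors),
        dataset=normalized.dataset,
        values=normalized.values[idx, :],
    )
    return differential_abundance(sub, group_a_donors, group_b_donors, p_cutoff, normalize=False)


def collapse_duplicates(
    features: Sequence[str], donors, dataset: str, values: np.ndarray
) -> AbundanceTable:
    """Build an :class:`AbundanceTable`, summing rows with identical feature ids.

    Used to pool phosphopeptides that map to the same protein+site across
    the two enrichment routes (TiO2 and Fe-NTA) before testing; distinct
    sites remain distinct features.
    """
    order = list(dict.fromkeys(features))
    fi = {f: i for i, f in enumerate(order)}
    out = np.zeros((len(order), values.shape[1]))
    for f, row in zip(features, values):
        out[fi[f]] += row
    return AbundanceTable(features=order, donors=list(donors), dataset=dataset, values=out)


def differential_phosphorylation(
    phospho_table: AbundanceTable,
    group_a_donors: Sequence[str],
    group_b_donors: Sequence[str],
    p_cutoff: float = 0.05,
    min_fold: float = 2.0,
) -> list[DifferentialResult]:
    """Per-phosphosite Welch comparison with a >=``min_fold`` screen.

    Same statistic as :func:`differential_abundance`; the headline call set
    (see :func:`phospho_call_set`) is the intersection of the significant set
    and the fold-change set.
    """
    if min_fold <= 0:
        raise ValidationError("min_fold must be positive")
    return differential_abundance(
        phospho_table,
        group_a_donors,
        group_b_donors,
        p_cutoff=p_cutoff,
        log2_fold_cutoff=math.log2(min_fold),
    )


def phospho_call_set(results: Sequence[DifferentialResult]) -> list[DifferentialResult]:
    """Features that are both significant and beyond the fold cutoff."""
    return [r for r in results if r.significant and r.two_fold]


def western_normalize(band_target: float, band_gapdh: float, paired_male_ratio: float) -> float:
    """Densitometry: target/GAPDH ratio normalized to the date-matched male's ratio."""
    if band_gapdh <= 0:
        raise ValidationError("GAPDH loading-control band must be positive")
    if paired_male_ratio <= 0:
        raise ValidationError("paired male ratio must be positive")
    if band_target < 0:
        raise ValidationError("band intensity cannot be negative")
    return (band_target / band_gapdh) / paired_male_ratio
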