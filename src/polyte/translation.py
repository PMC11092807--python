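"""Fraction normalization, TR/STR statistics, qualification, group comparison.

The core quantities, per gene X and donor:

* normalized count in class c  =  count(X, c) / total reads in class c;
* occupancy proportion in c    =  normalized(c) / sum over the 4 classes;
* translation rate             TR_X  = (early + late polysome) / (free + monosome);
* strong translation rate      STR_X = late polysome / (free + monosome + early).

Both ratios are computed on occupancy proportions (equivalently on
normalized counts — the per-gene sum cancels).  A gene qualifies for a
reference group when every reference donor has a finite, defined value and
the coefficient of variation (sample SD / mean) across those donors is
strictly below 0.5.  Group differences are assessed per gene with a
two-sided Welch t-test at uncorrected p < 0.05 — the one per-row test
specified for all per-feature comparisons in this pipeline.
"""
from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .core import (
    DifferentialResult,
    FractionClass,
    FractionCountMatrix,
    GradientTrace,
    NormalizationError,
    OccupancyProfile,
    POLYSOME_REGION,
    PolyteError,
    TranslationStat,
    ValidationError,
)
from .stats import welch_t_test

log = logging.getLogger("polyte")

__all__ = [
    "normalize_fractions",
    "translation_rate",
    "strong_translation_rate",
    "statistic_values",
    "compute_translation_stats",
    "qualify",
    "compare_te_groups",
    "fraction_abundance_compare",
    "polysome_region_cv",
]

CV_CUTOFF = 0.5


def normalize_fractions(matrix: FractionCountMatrix) -> OccupancyProfile:
    """Depth-normalize each (donor, class) column and convert to proportions.

    Raises :class:`NormalizationError` naming the donor and class if any
    column total is zero.  Genes with zero counts in all four classes for a
    donor are undefined (NaN row) and excluded downstream.
    """
    totals = matrix.class_totals().astype(float)  # (n_donors, 4)
    if (totals == 0).any():
        j, c = np.argwhere(totals == 0)[0]
        raise NormalizationError(
            f"zero total count for donor {matrix.donors[j].donor_id!r}, "
            f"class {FractionClass(c).name}"
        )
    normalized = matrix.counts / totals[None, :, :]
    gene_sums = normalized.sum(axis=2)  # (n_genes, n_donors)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = normalized / gene_sums[:, :, None]
    proportions[gene_sums == 0] = np.nan
    n_undefined = int((gene_sums == 0).sum())
    if n_undefined:
        log.info("%d (gene, donor) pairs undefined (zero counts in all classes)", n_undefined)
    return OccupancyProfile(
        genes=list(matrix.genes), donors=list(matrix.donors), proportions=proportions
    )


def _ratio(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Elementwise ratio with inf for x/0 (x > 0) and NaN propagation."""
    out = np.full(numerator.shape, np.nan)
    defined = ~(np.isnan(numerator) | np.isnan(denominator))
    num, den = numerator[defined], denominator[defined]
    vals = np.empty(num.shape)
    zero_den = den == 0
    vals[~zero_den] = num[~zero_den] / den[~zero_den]
    vals[zero_den & (num > 0)] = np.inf
    vals[zero_den & (num == 0)] = np.nan
    out[defined] = vals
    return out


def statistic_values(profile: OccupancyProfile, kind: str) -> np.ndarray:
    """TR or STR for every (gene, donor); shape ``(n_genes, n_donors)``.

    NaN marks undefined (gene absent for the donor), inf a zero denominator.
    """
    p = profile.proportions
    if kind == "TR":
        num = p[:, :, 2] + p[:, :, 3]
        den = p[:, :, 0] + p[:, :, 1]
    elif kind == "STR":
        num = p[:, :, 3]
        den = p[:, :, 0] + p[:, :, 1] + p[:, :, 2]
    else:
        raise ValidationError(f"statistic kind must be TR or STR, got {kind!r}")
    return _ratio(num, den)


def translation_rate(profile: OccupancyProfile, gene: str, donor: str) -> float:
    """TR = (early + late polysome) / (free + monosome) for one (gene, donor)."""
    i, j = profile.gene_index(gene), profile.donor_index(donor)
    return float(statistic_values(profile, "TR")[i, j])


def strong_translation_rate(profile: OccupancyProfile, gene: str, donor: str) -> float:
    """STR = late polysome / (free + monosome + early polysome)."""
    i, j = profile.gene_index(gene), profile.donor_index(donor)
    return float(statistic_values(profile, "STR")[i, j])


def compute_translation_stats(
    profile: OccupancyProfile, kind: str, reference_donors: Sequence[str]
) -> list[TranslationStat]:
    """Per-gene :class:`TranslationStat` with reference-group qualification."""
    values = statistic_values(profile, kind)
    donor_ids = profile.donor_ids
    stats = [
        TranslationStat(
            gene=gene,
            statistic_kind=kind,
            per_donor_values={d: float(values[i, j]) for j, d in enumerate(donor_ids)},
        )
        for i, gene in enumerate(profile.genes)
    ]
    return qualify(stats, reference_donors)


def qualify(
    stats: Sequence[TranslationStat], reference_donors: Sequence[str]
) -> list[TranslationStat]:
    """Fill group summaries and the qualification flag, in place.

    A gene qualifies iff every reference donor's value is defined and
    finite AND sample-SD/mean < 0.5 (strict).  Mean/SD/CV are computed over
    the finite reference values only, so disqualified genes still carry an
    auditable summary.
    """
    if not reference_donors:
        raise ValidationError("reference_donors must be non-empty")
    ref = list(reference_donors)
    for s in stats:
        missing = [d for d in ref if d not in s.per_donor_values]
        if missing:
            raise ValidationError(f"gene {s.gene}: no value for reference donors {missing}")
        vals = np.array([s.per_donor_values[d] for d in ref])
        finite = vals[np.isfinite(vals)]
        if finite.size:
            s.group_mean = float(finite.mean())
            s.group_sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
            s.group_cv = s.group_sd / s.group_mean if s.group_mean != 0 else math.nan
        else:
            s.group_mean = s.group_sd = s.group_cv = math.nan
        all_finite = finite.size == len(ref)
        s.qualified = bool(
            all_finite and not math.isnan(s.group_cv) and s.group_cv < CV_CUTOFF
        )
    return list(stats)


def _group_values(stat: TranslationStat, donors: Sequence[str]) -> np.ndarray:
    vals = np.array([stat.per_donor_values.get(d, math.nan) for d in donors])
    return vals[np.isfinite(vals)]


def _log2_fold(mean_a: float, mean_b: float) -> float:
    if mean_a > 0 and mean_b > 0:
        return math.log2(mean_a / mean_b)
    if mean_a > 0 and mean_b == 0:
        return math.inf
    if mean_a == 0 and mean_b > 0:
        return -math.inf
    return math.nan


def compare_te_groups(
    stats_a: Sequence[TranslationStat],
    stats_b: Sequence[TranslationStat],
    qualified_genes: Sequence[str] | None = None,
    p_cutoff: float = 0.05,
) -> list[DifferentialResult]:
    """Per-gene Welch comparison of per-donor TR/STR between two groups.

    ``stats_a`` / ``stats_b`` hold each group's per-donor values (donor keys
    are the group memberships).  Only ``qualified_genes`` are tested (default:
    genes qualified in ``stats_a``, the reference group).  Genes with fewer
    than two finite values in either group get an undefined p and are never
    significant.
    """
    by_gene_b = {s.gene: s for s in stats_b}
    if qualified_genes is None:
        genes = [s.gene for s in stats_a if s.qualified]
    else:
        genes = list(qualified_genes)
    by_gene_a = {s.gene: s for s in stats_a}
    results = []
    for gene in genes:
        sa, sb = by_gene_a.get(gene), by_gene_b.get(gene)
        if sa is None or sb is None:
            log.info("gene %s missing from one group; skipped", gene)
            continue
        a = _group_values(sa, list(sa.per_donor_values))
        b = _group_values(sb, list(sb.per_donor_values))
        if a.size < 2 or b.size < 2:
            results.append(
                DifferentialResult.from_stats(gene, math.nan, math.nan, p_cutoff)
            )
            continue
        _, _, p = welch_t_test(a, b)
        results.append(
            DifferentialResult.from_stats(
                gene, _log2_fold(a.mean(), b.mean()), p, p_cutoff
            )
        )
    return results


def fraction_abundance_compare(
    profile: OccupancyProfile,
    fraction_class: FractionClass,
    males: Sequence[str],
    females: Sequence[str],
    p_cutoff: float = 0.05,
) -> list[DifferentialResult]:
    """Compare per-donor occupancy proportions in one class, male vs female.

    This is the per-class abundance screen (amount of each mRNA in e.g. the
    free fraction relative to that mRNA's total) run once per fraction
    class.  Donors with an undefined profile for a gene are dropped for
    that gene and the drop is logged.
    """
    col = profile.proportions[:, :, fraction_class.value]
    donor_ids = profile.donor_ids
    mi = [donor_ids.index(d) for d in males]
    fi = [donor_ids.index(d) for d in females]
    results = []
    n_dropped = 0
    for g, gene in enumerate(profile.genes):
        a = col[g, mi]
        b = col[g, fi]
        fa, fb = a[~np.isnan(a)], b[~np.isnan(b)]
        n_dropped += int(np.isnan(a).sum() + np.isnan(b).sum())
        if fa.size < 2 or fb.size < 2:
            results.append(DifferentialResult.from_stats(gene, math.nan, math.nan, p_cutoff))
            continue
        _, _, p = welch_t_test(fa, fb)
        results.append(
            DifferentialResult.from_stats(gene, _log2_fold(fa.mean(), fb.mean()), p, p_cutoff)
        )
    if n_dropped:
        log.info(
            "fraction_abundance_compare(%s): dropped %d undefined donor values",
            fraction_class.name,
            n_dropped,
        )
    return results


def polysome_region_cv(trace: GradientTrace, region: tuple[int, int] = POLYSOME_REGION) -> float:
    """Sample CV (SD/mean) of absorbance over the polysome region.

    The region is gradient positions 40-75 inclusive (the early + late
    polysome span plus the trailing edge of the monosome class); the trace
    must cover it and its mean absorbance must be positive.
    """
    lo, hi = region
    if trace.positions.min() > lo or trace.positions.max() < hi:
        raise PolyteError(
            f"trace covers {trace.positions.min():g}-{trace.positions.max():g}; "
            f"polysome region {lo}-{hi} required"
        )
    mask = (trace.positions >= lo) & (trace.positions <= hi)
    values = trace.absorbance[mask]
    mean = values.mean()
    if mean <= 0:
        raise PolyteError("polysome-region mean absorbance is zero; CV undefined")
    return float(values.std(ddof=1) / mean)
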