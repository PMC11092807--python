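"""Core domain types for sucrose-gradient polysome fractionation analysis.

The experiment this package models separates a cell lysate on a sucrose
gradient and collects twelve fractions, grouped into four classes by how
many ribosomes are bound to the mRNA:

* ``FREE`` — fractions 1-3 (gradient positions 1-20), mRNA not bound to
  ribosomes and therefore not being translated;
* ``MONOSOME`` — fractions 4-6 (positions 21-40), mRNA bound by a single
  ribosome;
* ``EARLY_POLYSOME`` — fractions 7-9 (positions 41-55);
* ``LATE_POLYSOME`` — fractions 10-12 (positions 56-75), heavily
  translated mRNA carrying many ribosomes.

Counts are sequenced per donor per fraction class; everything downstream
(occupancy proportions, translation-rate statistics, differential calls)
is expressed in terms of these four classes.

Sentinel conventions
--------------------
Ratios of occupancies can be infinite (all of a gene's signal in the
numerator classes) or undefined (gene not detected in any class for a
donor).  Infinity is represented by ``math.inf`` and undefined values by
``math.nan`` throughout; both survive TSV round trips.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

log = logging.getLogger("polyte")

__all__ = [
    "FractionClass",
    "FRACTION_RANGES",
    "GRADIENT_RANGES",
    "N_CLASSES",
    "SEXES",
    "CONDITIONS",
    "DonorMeta",
    "FractionCountMatrix",
    "OccupancyProfile",
    "TranslationStat",
    "GradientTrace",
    "AbundanceTable",
    "DifferentialResult",
    "EnrichmentResult",
    "PolyteError",
    "FormatError",
    "ValidationError",
    "NormalizationError",
]


class PolyteError(ValueError):
    """Base class for pipeline validation and format errors."""


class FormatError(PolyteError):
    """Malformed input file (bad header, unknown label, unparsable value)."""


class ValidationError(PolyteError):
    """Structurally parsable input violating a domain invariant."""


class NormalizationError(PolyteError):
    """A normalization denominator (column total) is zero."""


class FractionClass(Enum):
    """The four ribosome-occupancy classes of the gradient."""

    FREE = 0
    MONOSOME = 1
    EARLY_POLYSOME = 2
    LATE_POLYSOME = 3

    @property
    def fraction_range(self) -> tuple[int, int]:
        """Inclusive 1-based collected-fraction indices for this class."""
        return FRACTION_RANGES[self]

    @property
    def gradient_range(self) -> tuple[int, int]:
        """Inclusive 1-based gradient positions for this class."""
        return GRADIENT_RANGES[self]


N_CLASSES = len(FractionClass)

FRACTION_RANGES: dict[FractionClass, tuple[int, int]] = {
    FractionClass.FREE: (1, 3),
    FractionClass.MONOSOME: (4, 6),
    FractionClass.EARLY_POLYSOME: (7, 9),
    FractionClass.LATE_POLYSOME: (10, 12),
}

GRADIENT_RANGES: dict[FractionClass, tuple[int, int]] = {
    FractionClass.FREE: (1, 20),
    FractionClass.MONOSOME: (21, 40),
    FractionClass.EARLY_POLYSOME: (41, 55),
    FractionClass.LATE_POLYSOME: (56, 75),
}

# The polysome region of an absorbance trace, used for the profile-quality
# coefficient of variation.  Overlaps the tail of the monosome class because
# the region is defined on the raw gradient, not on the class boundaries.
POLYSOME_REGION: tuple[int, int] = (40, 75)


def _assert_partition(ranges: dict[FractionClass, tuple[int, int]], lo: int, hi: int) -> None:
    covered: list[int] = []
    for a, b in ranges.values():
        if a > b:
            raise AssertionError(f"inverted range {a}-{b}")
        covered.extend(range(a, b + 1))
    if sorted(covered) != list(range(lo, hi + 1)):
        raise AssertionError(f"ranges do not partition {lo}-{hi}")


# Fail fast at import if the class boundaries ever drift.
_assert_partition(FRACTION_RANGES, 1, 12)
_assert_partition(GRADIENT_RANGES, 1, 75)


SEXES = ("male", "female")
CONDITIONS = ("unstimulated", "SLIGKV_5min", "SLIGKV_20min")


@dataclass(frozen=True)
class DonorMeta:
    """One blood donor: opaque id, sex, and stimulation condition.

    ``condition`` distinguishes unstimulated cells from cells exposed to the
    PAR2-agonist chemorepellent SLIGKV for 5 or 20 minutes.
    """

    donor_id: str
    sex: str
    condition: str = "unstimulated"

    def __post_init__(self) -> None:
        if not self.donor_id:
            raise ValidationError("donor_id must be a non-empty string")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


def _check_unique_donors(donors: Sequence[DonorMeta]) -> None:
    ids = [d.donor_id for d in donors]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate donor ids: {dupes}")


@dataclass
class FractionCountMatrix:
    """Raw read counts per (gene, donor, fraction class).

    ``counts`` has shape ``(n_genes, n_donors, 4)`` with the last axis ordered
    by :class:`FractionClass` value.  All cells are present; explicit zeros are
    legitimate (3'-tag RNA-seq routinely yields zero counts).
    """

    genes: list[str]
    donors: list[DonorMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        _check_unique_donors(self.donors)
        expected = (len(self.genes), len(self.donors), N_CLASSES)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts are not allowed")

    @property
    def donor_ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]

    def donor_index(self, donor_id: str) -> int:
        try:
            return self.donor_ids.index(donor_id)
        except ValueError:
            raise KeyError(f"unknown donor {donor_id!r}") from None

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def donors_of_sex(self, sex: str) -> list[str]:
        if sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        return [d.donor_id for d in self.donors if d.sex == sex]

    def class_totals(self) -> np.ndarray:
        """Total read count per (donor, class) column, shape ``(n_donors, 4)``."""
        return self.counts.sum(axis=0)


@dataclass
class OccupancyProfile:
    """Per (gene, donor) proportions of depth-normalized signal per class.

    Rows for a defined (gene, donor) sum to 1 across the four classes; a pair
    is undefined (all-NaN row) iff the gene has zero counts in every class for
    that donor.
    """

    genes: list[str]
    donors: list[DonorMeta]
    proportions: np.ndarray  # (n_genes, n_donors, 4), NaN rows = undefined

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        expected = (len(self.genes), len(self.donors), N_CLASSES)
        if self.proportions.shape != expected:
            raise ValidationError(
                f"proportions shape {self.proportions.shape} != expected {expected}"
            )
        nan = np.isnan(self.proportions)
        if not np.all(nan.all(axis=2) | ~nan.any(axis=2)):
            raise ValidationError("a (gene, donor) row must be fully defined or fully NaN")
        defined = ~nan.all(axis=2)
        sums = self.proportions[defined].sum(axis=1)
        if defined.any() and not np.allclose(sums, 1.0, rtol=0.0, atol=1e-9):
            raise ValidationError("defined occupancy rows must sum to 1")

    @property
    def donor_ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask, shape ``(n_genes, n_donors)``."""
        return ~np.isnan(self.proportions).all(axis=2)

    def donor_index(self, donor_id: str) -> int:
        try:
            return self.donor_ids.index(donor_id)
        except ValueError:
            raise KeyError(f"unknown donor {donor_id!r}") from None

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class TranslationStat:
    """Per-gene translation-rate statistic with reference-group summary.

    ``per_donor_values`` maps donor id to the TR or STR value; ``math.inf``
    marks a ratio with zero denominator and ``math.nan`` an undefined profile.
    Summaries (mean, sample SD with n-1, CV = SD/mean) are computed over the
    reference-group donors only, restricted to finite values; ``qualified`` is
    True iff every reference donor's value is finite and CV < 0.5.
    """

    gene: str
    statistic_kind: str  # "TR" or "STR"
    per_donor_values: dict[str, float]
    group_mean: float = math.nan
    group_sd: float = math.nan
    group_cv: float = math.nan
    qualified: bool = False

    def __post_init__(self) -> None:
        if self.statistic_kind not in ("TR", "STR"):
            raise ValidationError(f"statistic_kind must be TR or STR, got {self.statistic_kind!r}")
        for v in self.per_donor_values.values():
            if not math.isnan(v) and not math.isinf(v) and v < 0:
                raise ValidationError("translation statistics cannot be negative")


@dataclass
class GradientTrace:
    """UV absorbance along a sucrose gradient (positions 1-75 by default)."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise ValidationError("positions and absorbance must be 1-D and equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValidationError("positions must be strictly increasing")
        if (self.absorbance < 0).any():
            raise ValidationError("absorbance must be non-negative")


@dataclass
class AbundanceTable:
    """Per-donor protein or phosphopeptide abundances from one instrument.

    ``dataset`` labels the provenance (e.g. ``LUMOS`` spectral counts or
    ``TMT_ORBITRAP`` reporter intensities); the two are never mixed
    numerically, only their differential calls are merged.
    """

    features: list[str]
    donors: list[DonorMeta]
    dataset: str
    values: np.ndarray  # (n_features, n_donors), non-negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.features)) != len(self.features):
            raise ValidationError("duplicate feature identifiers; aggregate first")
        _check_unique_donors(self.donors)
        expected = (len(self.features), len(self.donors))
        if self.values.shape != expected:
            raise ValidationError(f"values shape {self.values.shape} != expected {expected}")
        if np.isnan(self.values).any() or (self.values < 0).any():
            raise ValidationError("abundances must be non-negative and defined")

    @property
    def donor_ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]

    def donors_of_sex(self, sex: str, condition: str | None = None) -> list[str]:
        out = []
        for d in self.donors:
            if d.sex == sex and (condition is None or d.condition == condition):
                out.append(d.donor_id)
        return out

    def column(self, donor_id: str) -> np.ndarray:
        return self.values[:, self.donor_ids.index(donor_id)]


@dataclass(frozen=True)
class DifferentialResult:
    """One feature's two-group comparison: volcano-plot coordinates + flags.

    significant  <=>  p defined and p < 0.05 (uncorrected, by design);
    two_fold     <=>  log2 fold change defined with |log2FC| > 1 (infinite
    fold changes count as two_fold and carry the infinite sentinel);
    direction is up_in_A / up_in_B for significant calls, none otherwise.
    """

    feature: str
    log2_fc: float
    p_value: float
    significant: bool
    two_fold: bool
    direction: str  # up_in_A | up_in_B | none
    p_cutoff: float = field(default=0.05, compare=False, repr=False)
    log2_fold_cutoff: float = field(default=1.0, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.direction not in ("up_in_A", "up_in_B", "none"):
            raise ValidationError(f"bad direction {self.direction!r}")
        p_ok = not math.isnan(self.p_value)
        if self.significant != (p_ok and self.p_value < self.p_cutoff):
            raise ValidationError("significant flag inconsistent with p_value")
        fc_ok = not math.isnan(self.log2_fc)
        if self.two_fold != (fc_ok and abs(self.log2_fc) > self.log2_fold_cutoff):
            raise ValidationError("two_fold flag inconsistent with log2_fc")

    @classmethod
    def from_stats(
        cls,
        feature: str,
        log2_fc: float,
        p_value: float,
        p_cutoff: float = 0.05,
        log2_fold_cutoff: float = 1.0,
    ) -> "DifferentialResult":
        """Build a result with flags derived from the thresholds.

        The canonical thresholds are p < 0.05 and |log2FC| > 1; the
        phosphoproteomics fold screen passes a different ``log2_fold_cutoff``.
        """
        significant = (not math.isnan(p_value)) and p_value < p_cutoff
        two_fold = (not math.isnan(log2_fc)) and abs(log2_fc) > log2_fold_cutoff
        if significant and log2_fc > 0:
            direction = "up_in_A"
        elif significant and log2_fc < 0:
            direction = "up_in_B"
        else:
            direction = "none"
        return cls(
            feature=feature,
            log2_fc=float(log2_fc),
            p_value=float(p_value),
            significant=significant,
            two_fold=two_fold,
            direction=direction,
            p_cutoff=p_cutoff,
            log2_fold_cutoff=log2_fold_cutoff,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's Fisher-exact enrichment against a background."""

    set_id: str
    overlap_count: int
    foreground_size: int
    background_size: int
    set_size_in_background: int
    fisher_p: float
    fdr_q: float
    enriched: bool

    def __post_init__(self) -> None:
        if self.overlap_count > min(self.foreground_size, self.set_size_in_background):
            raise ValidationError("overlap exceeds foreground or set size")
        if not (0.0 <= self.fisher_p <= 1.0 and 0.0 <= self.fdr_q <= 1.0):
            raise ValidationError("p and q must lie in [0, 1]")
        if self.enriched != (self.fdr_q < 0.05):
            raise ValidationError("enriched flag inconsistent with fdr_q")
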