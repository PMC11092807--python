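"""Seeded generators emulating the study's inputs.

Three generators cover the pipeline's three input families:

* :func:`simulate_fraction_counts` — negative-binomial read counts per
  (gene, donor, fraction class) around an expected value of
  ``depth x relative_expression x occupancy``.  A configurable subset of
  genes carries a sex-specific translation-efficiency shift implemented as
  an occupancy-mass transfer from the untranslated classes (free +
  monosome) to the polysome classes, keeping each gene's total expression
  constant, so that the expected male TR is ``2^shift`` times the female
  TR.
* :func:`simulate_gradient_trace` — a sum-of-Gaussians absorbance profile
  with a monosome peak, optional polysome peaks, a baseline, and additive
  noise.
* :func:`simulate_abundance` — log-normal protein / phosphopeptide
  abundance tables per instrument, with sex-specific shifts and an
  optional "conflict" feature shifted oppositely in two instruments to
  exercise the merge-exclusion rule.

Every generator is driven by a single integer seed; each generator derives
its own named pseudo-random stream from it, so adding draws to one
generator never perturbs another.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AbundanceTable,
    DonorMeta,
    FractionClass,
    FractionCountMatrix,
    GradientTrace,
    N_CLASSES,
    PolyteError,
)

__all__ = [
    "SimulationConfig",
    "simulate_fraction_counts",
    "simulate_gradient_trace",
    "gradient_trace_expectation",
    "simulate_abundance",
]


class ConfigError(PolyteError):
    """Invalid simulation configuration."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named, independent random stream per generator."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# The study's fractionation cohort: 3 male and 4 female healthy donors.
DEFAULT_N_MALE = 3
DEFAULT_N_FEMALE = 4

#: Genome-wide default occupancy across (free, monosome, early, late):
#: modest polysome loading typical of resting neutrophils (TR ~ 0.9).
DEFAULT_BASELINE_OCCUPANCY = (0.30, 0.22, 0.23, 0.25)


@dataclass
class SimulationConfig:
    """Study conditions for the fraction-count generator.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2/size), so larger values mean less overdispersion.
    ``effect_genes`` maps gene id to the log2 shift of male vs female
    translation efficiency; ``donor_noise_sd`` is the SD of a log-scale
    per-donor effect (library-size / input-material variation) multiplying
    every expected count of that donor.  Depth normalization removes it
    exactly, which is what the normalization is for.
    """

    n_genes: int = 2000
    n_male: int = DEFAULT_N_MALE
    n_female: int = DEFAULT_N_FEMALE
    mean_depth_per_class: float = 1_000_000.0
    dispersion: float = 20.0
    baseline_occupancy: tuple[float, float, float, float] = DEFAULT_BASELINE_OCCUPANCY
    effect_genes: dict[str, float] = field(default_factory=dict)
    donor_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_male <= 0 or self.n_female <= 0:
            raise ConfigError("n_genes, n_male, n_female must be positive")
        if self.mean_depth_per_class <= 0 or self.dispersion <= 0:
            raise ConfigError("mean_depth_per_class and dispersion must be positive")
        occ = np.asarray(self.baseline_occupancy, dtype=float)
        if occ.shape != (N_CLASSES,) or (occ < 0).any():
            raise ConfigError("baseline_occupancy must be 4 non-negative reals")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ConfigError("baseline_occupancy must sum to 1")
        if self.donor_noise_sd < 0:
            raise ConfigError("donor_noise_sd must be non-negative")
        if len(self.effect_genes) > self.n_genes:
            raise ConfigError("more effect genes than genes")

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def donors(self) -> list[DonorMeta]:
        males = [DonorMeta(f"M{i + 1}", "male") for i in range(self.n_male)]
        females = [DonorMeta(f"F{i + 1}", "female") for i in range(self.n_female)]
        return males + females


def shifted_occupancy(baseline: np.ndarray, log2_shift: float) -> np.ndarray:
    """Transfer occupancy mass so expected TR is scaled by ``2^log2_shift``.

    With polysome mass p = early + late and r = 2^shift, the new polysome
    mass q solves q/(1-q) = r * p/(1-p); early/late (and free/monosome)
    keep their internal ratios.  Total occupancy stays 1, so expression
    level is untouched and only translation efficiency moves.
    """
    occ = np.asarray(baseline, dtype=float)
    p = occ[2] + occ[3]
    if log2_shift == 0.0 or p == 0.0 or p == 1.0:
        return occ.copy()
    r = 2.0**log2_shift
    q = r * p / (1.0 - p + r * p)
    out = occ.copy()
    out[2:] *= q / p
    out[:2] *= (1.0 - q) / (1.0 - p)
    return out


def simulate_fraction_counts(config: SimulationConfig) -> FractionCountMatrix:
    """Draw a seeded fraction-resolved count matrix under ``config``.

    Expected count(g, d, c) = depth x donor_factor_d x relexpr_g x
    occupancy(g, sex(d), c), with donor_factor_d log-normal
    (``donor_noise_sd``); counts are negative binomial with size
    ``config.dispersion`` around that mean.  Identical configs (including
    seed) give identical matrices.
    """
    rng = _stream(config.seed, "fraction_counts")
    genes = config.gene_names()
    donors = config.donors()
    n_donors = len(donors)

    # per-gene relative expression, log-normal, normalized to sum 1
    relexpr = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    relexpr /= relexpr.sum()

    baseline = np.asarray(config.baseline_occupancy, dtype=float)
    unknown = set(config.effect_genes) - set(genes)
    if unknown:
        raise ConfigError(f"effect genes not in simulated gene list: {sorted(unknown)[:5]}")

    occ = np.empty((config.n_genes, 2, N_CLASSES))  # sex axis: 0=male, 1=female
    occ[:, 0] = baseline
    occ[:, 1] = baseline
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, shift in config.effect_genes.items():
        occ[gene_index[gene], 0] = shifted_occupancy(baseline, shift)

    sex_idx = np.array([0 if d.sex == "male" else 1 for d in donors])
    mu = (
        config.mean_depth_per_class
        * relexpr[:, None, None]
        * occ[:, sex_idx, :]
    )
    if config.donor_noise_sd > 0:
        donor_factor = rng.lognormal(mean=0.0, sigma=config.donor_noise_sd, size=n_donors)
        mu = mu * donor_factor[None, :, None]
    size = config.dispersion
    counts = rng.negative_binomial(n=size, p=size / (size + mu))
    return FractionCountMatrix(genes=genes, donors=donors, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# gradient traces

_MONOSOME_CENTER = 30.0  # inside gradient positions 21-40
_PEAK_SD = 3.0
_BASELINE_ABSORBANCE = 0.05


def _polysome_centers(n_peaks: int) -> np.ndarray:
    if n_peaks == 0:
        return np.empty(0)
    return np.linspace(45.0, 70.0, n_peaks)


def gradient_trace_expectation(
    positions: np.ndarray,
    monosome_height: float,
    polysome_heights: Sequence[float],
    baseline: float = _BASELINE_ABSORBANCE,
) -> np.ndarray:
    """Noise-free absorbance: baseline + Gaussian peaks (closed form)."""
    x = np.asarray(positions, dtype=float)
    y = np.full_like(x, baseline)
    y += monosome_height * np.exp(-0.5 * ((x - _MONOSOME_CENTER) / _PEAK_SD) ** 2)
    for h, c in zip(polysome_heights, _polysome_centers(len(polysome_heights))):
        y += h * np.exp(-0.5 * ((x - c) / _PEAK_SD) ** 2)
    return y


def simulate_gradient_trace(
    monosome_height: float,
    polysome_heights: Sequence[float],
    noise_sd: float,
    seed: int,
    baseline: float = _BASELINE_ABSORBANCE,
) -> GradientTrace:
    """Absorbance trace over gradient positions 1-75 with Gaussian noise."""
    if not math.isfinite(monosome_height) or monosome_height < 0:
        raise ConfigError("monosome_height must be finite and non-negative")
    if any(not math.isfinite(h) or h < 0 for h in polysome_heights):
        raise ConfigError("polysome heights must be finite and non-negative")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    positions = np.arange(1, 76, dtype=float)
    y = gradient_trace_expectation(positions, monosome_height, polysome_heights, baseline)
    if noise_sd > 0:
        rng = _stream(seed, "gradient_trace")
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return GradientTrace(positions=positions, absorbance=np.clip(y, 0.0, None))


# ---------------------------------------------------------------------------
# abundance tables


def simulate_abundance(
    n_features: int,
    n_male: int,
    n_female: int,
    effect_features: Mapping[str, float],
    datasets: Sequence[str],
    seed: int,
    noise_sd: float = 0.25,
    conflict_features: Mapping[str, float] | None = None,
) -> list[AbundanceTable]:
    """Log-normal abundance tables, one per instrument dataset.

    ``effect_features`` maps feature id to the log2 male/female shift
    (applied identically in every dataset).  ``conflict_features`` applies
    ``+shift`` in the first dataset and ``-shift`` in the second, producing
    an opposite-direction call that the dataset merge must exclude.
    Feature ids are ``P00000``, ``P00001``, ...
    """
    if not datasets:
        raise ConfigError("datasets list must be non-empty")
    if n_features <= 0 or n_male <= 0 or n_female <= 0:
        raise ConfigError("n_features, n_male, n_female must be positive")
    features = [f"P{i:05d}" for i in range(n_features)]
    fset = set(features)
    for name, mapping in (("effect", effect_features), ("conflict", conflict_features or {})):
        missing = set(mapping) - fset
        if missing:
            raise ConfigError(f"{name} features not in feature list: {sorted(missing)[:5]}")
    if conflict_features and len(datasets) < 2:
        raise ConfigError("conflict features require at least two datasets")

    donors = [DonorMeta(f"M{i + 1}", "male") for i in range(n_male)] + [
        DonorMeta(f"F{i + 1}", "female") for i in range(n_female)
    ]
    male_mask = np.array([d.sex == "male" for d in donors])
    fidx = {f: i for i, f in enumerate(features)}

    tables = []
    for d_i, dataset in enumerate(datasets):
        rng = _stream(seed, f"abundance:{dataset}")
        base = rng.lognormal(mean=3.0, sigma=1.0, size=n_features)
        log2_shift = np.zeros(n_features)
        for f, s in effect_features.items():
            log2_shift[fidx[f]] += s
        for f, s in (conflict_features or {}).items():
            log2_shift[fidx[f]] += s if d_i == 0 else -s
        mu = base[:, None] * np.where(male_mask[None, :], 2.0 ** log2_shift[:, None], 1.0)
        values = mu * rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_features, len(donors)))
        tables.append(
            AbundanceTable(features=list(features), donors=list(donors), dataset=dataset, values=values)
        )
    return tables
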