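"""Statistical primitives used throughout the pipeline.

The per-feature group comparison everywhere in this package is the
two-sided Welch (unequal-variance) t-test at an uncorrected p < 0.05;
gene-set enrichment is a one-sided Fisher exact test against a background
with Benjamini-Hochberg FDR control; non-parametric two-group comparisons
use the Mann-Whitney U test (exact for small samples); qPCR relative
quantities use the delta-CT method with base-2 amplification.

All functions return ``math.nan`` sentinels for undefined results rather
than raising, so callers can propagate "not testable" through tables.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .core import EnrichmentResult, ValidationError

__all__ = [
    "welch_t_test",
    "mann_whitney",
    "benjamini_hochberg",
    "fisher_enrichment",
    "QpcrResult",
    "delta_ct",
]

#: largest combined sample size for which the Mann-Whitney p is computed by
#: exhaustive enumeration of rank splits; beyond it the tie-corrected normal
#: approximation is used.
MANN_WHITNEY_EXACT_MAX_N = 12


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided unequal-variance t-test (Satterthwaite df).

    Returns ``(t, df, p)``.  With fewer than two observations in either
    group all three are NaN (undefined).  Two constant, equal groups give
    ``p = 1`` by convention; constant groups with different means give an
    infinite statistic and ``p = 0``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2 or np.isnan(a).any() or np.isnan(b).any():
        return (math.nan, math.nan, math.nan)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    if sa + sb == 0.0:
        if ma == mb:
            return (0.0, float(a.size + b.size - 2), 1.0)
        t = math.inf if ma > mb else -math.inf
        return (t, float(a.size + b.size - 2), 0.0)
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return (float(t), float(df), float(min(p, 1.0)))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation p (enumeration of all ``C(n_a+n_b, n_a)`` splits of the
    pooled sample, correct under ties) when the combined sample size is at
    most :data:`MANN_WHITNEY_EXACT_MAX_N`; otherwise the tie-corrected normal
    approximation with continuity correction.  Returns ``(U, p)`` where U is
    the statistic for the first group.  All values tied gives ``p = 1``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney requires non-empty groups")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = na * nb / 2.0

    if na + nb <= MANN_WHITNEY_EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            # tolerance guards half-integer U values against float error
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return (u_obs, hits / total)

    # tie-corrected normal approximation
    pooled = np.concatenate([a, b])
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0.0:  # all values identical
        return (u_obs, 1.0)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * _sps.norm.sf(max(z, 0.0))
    return (u_obs, float(min(p, 1.0)))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def fisher_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    alternative: str = "greater",
    q_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of ``gene_sets`` in ``foreground``.

    Each set is intersected with the background before testing; the 2x2
    table is (in/out foreground) x (in/out set) over the background
    universe.  The default one-sided test asks for over-representation
    (hypergeometric upper tail); ``alternative="two-sided"`` is available.
    q-values are Benjamini-Hochberg over all tested sets; ``enriched``
    means q < 0.05.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValidationError("foreground must be a subset of the background")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    N, n = len(bg), len(fg)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & bg
        K = len(members)
        k = len(members & fg)
        if alternative == "greater":
            p = float(_sps.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(_sps.fisher_exact(table, alternative="two-sided")[1])
        rows.append((set_id, k, K, min(p, 1.0)))
    qs = benjamini_hochberg([r[3] for r in rows])
    return [
        EnrichmentResult(
            set_id=set_id,
            overlap_count=k,
            foreground_size=n,
            background_size=N,
            set_size_in_background=K,
            fisher_p=p,
            fdr_q=q,
            enriched=q < q_cutoff,
        )
        for (set_id, k, K, p), q in zip(rows, qs)
    ]


@dataclass(frozen=True)
class QpcrResult:
    """Relative qPCR quantity by the delta-CT method (base-2 amplification)."""

    ct_target: float
    ct_reference: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference

    @property
    def relative_quantity(self) -> float:
        return 2.0 ** (-self.delta_ct)


def delta_ct(ct_target: float, ct_reference: float) -> QpcrResult:
    """Relative quantity = 2^-(CT_target - CT_reference); halves per extra cycle."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValidationError("CT values must be finite")
    return QpcrResult(float(ct_target), float(ct_reference))
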