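# Methods

## Model and procedure

The pipeline analyzes fraction-resolved RNA-seq from sucrose-gradient
polysome fractionation.  Twelve collected fractions map onto four
ribosome-occupancy classes — free mRNA (fractions 1–3, gradient positions
1–20), monosomes (4–6, positions 21–40), early polysomes (7–9, 41–55),
late polysomes (10–12, 56–75) — and counts within a class are pooled
before any normalization.  The class boundaries are asserted at import to
partition fractions 1–12 and gradient positions 1–75.

For gene *X*, donor *d*, class *c*:

1. depth normalization: `n(X,d,c) = count(X,d,c) / Σ_genes count(·,d,c)`;
2. occupancy proportion: `p(X,d,c) = n(X,d,c) / Σ_c n(X,d,c)`;
3. `TR = (p_early + p_late) / (p_free + p_mono)`,
   `STR = p_late / (p_free + p_mono + p_early)`.

Because the per-gene sum cancels, TR and STR computed from proportions
equal the same ratios computed from depth-normalized counts, and both are
exactly invariant to rescaling any (donor, class) column — sequencing
depth never enters the statistic.

A gene is *undefined* for a donor when it has zero counts in all four
classes; such donors are dropped from that gene's comparisons (and the
drop is logged), never imputed.  A zero denominator with positive
numerator yields an infinite TR/STR, carried as an `inf` sentinel (never
a float overflow): it disqualifies the gene but is preserved in output
for audit.

**Qualification.**  With a chosen reference group (males when building
the male list; the analysis is symmetric for females), a gene qualifies
iff every reference donor's value is defined and finite and the
coefficient of variation across those donors is strictly below 0.5.  CV
uses the sample SD (n−1).  Group mean/SD/CV are reported over the finite
reference values even for disqualified genes, so filters are auditable.

**Group comparison.**  Every per-feature two-group comparison in the
package — TR/STR, per-class occupancy abundance, protein abundance,
phosphopeptide abundance — uses a two-sided Welch *t*-test
(Satterthwaite degrees of freedom) at uncorrected p < 0.05, with
`log2_fc = log2(mean_A / mean_B)`.  One test is specified for all per-row
comparisons deliberately: volcano classification then adds
`two_fold = |log2FC| > 1`.  No multiple-testing correction is applied to
volcano p-values by design; this is stated in output metadata (column
semantics) and should be kept in mind when interpreting counts of
significant features.  Fewer than two finite values in either group gives
an undefined p (never significant, flagged).  Two constant equal groups
give p = 1 by convention; constant unequal groups give p = 0.

**Proteomics.**  Per-donor normalization divides each feature by the
donor's total, so donor columns sum to 1 and loading/depth differences
cancel (scale invariance holds per column).  Fold change is the ratio of
group means of normalized values, without pseudocount: a feature absent
in one group yields an infinite fold-change sentinel and stays in the
volcano (presence/absence is information, not an error).  Instrument
datasets (spectral-count-like vs TMT reporter intensities) are never
mixed numerically; each dataset is tested separately and only the calls
are merged.  In the merge, a feature significant in both datasets with
agreeing direction appears once — the record from the first dataset is
kept, a choice that only affects which p/fold pair is displayed, not
membership; opposite directions exclude the feature and list it in the
conflict report; significance in exactly one dataset keeps the call.

**Phosphoproteomics.**  Phosphopeptides mapping to the same protein+site
across the two enrichment routes (TiO2, Fe-NTA) are summed before
testing (`collapse_duplicates`); distinct sites stay distinct.  The
headline call set is exactly the intersection of the significant set and
the >2-fold set.  The stimulated-time-course cross comparison
(`cross_condition_compare`) restricts to the features significant in the
reference group's stimulated-vs-unstimulated comparison and then runs
the group-A-vs-group-B Welch test on the timepoint table; normalization
uses the full table's donor totals before restriction so the restricted
test is on the same scale as any other call.

**Gradient traces.**  Profile quality is summarized by the CV (sample
SD / mean) of absorbance over the polysome region, gradient positions
40–75 inclusive; the trace must cover the region and its mean must be
positive.

**Statistical primitives.**  Welch *t* is the textbook formula (scipy is
used only for the *t* CDF).  Mann–Whitney computes U by pair counting
with 0.5 per tie and a two-sided permutation p by exhaustive enumeration
of all C(n_a+n_b, n_a) splits when the combined n ≤ 12 (exact under
ties), switching to the tie-corrected normal approximation with
continuity correction above that.  "FDR correction" is
Benjamini–Hochberg step-up (the default of the common enrichment tools);
q-values are monotone, order-preserving, capped at 1.  Fisher enrichment
is one-sided toward over-representation (the convention of GO tools),
computed as the hypergeometric upper tail after intersecting each set
with the background; a two-sided variant is available behind a flag.
qPCR relative quantity is `2^-(CT_target − CT_reference)` (ideal base-2
amplification; efficiency correction is out of scope).  Densitometry for
western confirmation normalizes the target band to the same lane's GAPDH
and then to the date-matched reference donor's ratio, rejecting
non-positive denominators.

## Synthetic data: what it emulates and what it does not

`simulate_fraction_counts` draws counts as negative binomial with
expected value `depth × donor_factor × relative_expression × occupancy`:

- cohort defaults: 3 male and 4 female donors, the fractionation study
  design; total-mRNA style designs (2M/4F) are a parameter change;
- `mean_depth_per_class` (default 1e6 reads) — per (donor, class)
  sequencing depth of a 3'-tag library on the simulated gene universe;
- `dispersion` (default 20) — NB size parameter; variance =
  μ + μ²/size, so larger is less overdispersed.  20 gives per-cell CVs
  around 0.22 for well-covered genes, typical bulk RNA-seq overdispersion;
- `baseline_occupancy` default (0.30, 0.22, 0.23, 0.25) across
  (free, mono, early, late): modest polysome loading (TR ≈ 0.9,
  STR ≈ 0.33) consistent with resting cells that show low polysome
  peaks.  Chosen once as the package's study condition; per-gene
  occupancies in real data vary far more widely;
- `donor_noise_sd` (default 0.15, log scale) — one log-normal factor per
  donor multiplying all of that donor's expected counts: library-size /
  input-material variation.  Depth normalization removes it exactly;
- relative expression is log-normal (σ = 1.2) normalized to sum 1.

Translation-efficiency effects are occupancy-mass transfers: for an
effect gene with log2 shift *s*, the male polysome mass q solves
`q/(1−q) = 2^s · p/(1−p)` with internal free:mono and early:late ratios
preserved, so expected male TR is `2^s ×` female TR while total
expression is unchanged — TE effects are disentangled from expression
effects by construction, because TR is a ratio of occupancies.

What the generator does **not** model: biological donor-to-donor
variation in translation efficiency itself (the donor effect cancels in
TR, so between-donor TR spread is counting noise only), cycloheximide or
heparin artifacts, UMI structure, gene length or GC bias, correlated
gene programs, and batch effects.  Consequently, passing null
calibration here shows the statistical chain is honest under the stated
noise model — not that the Welch test is calibrated against every real
biological noise structure; on real data the CV filter will remove more
genes than it does in simulation.

`simulate_gradient_trace` is a baseline plus Gaussian peaks (monosome at
position 30, σ = 3; polysome peaks spaced over 45–70) with additive
Gaussian noise, clipped at zero — enough structure to exercise the
region-CV computation, not a physical model of UV absorbance.
`simulate_abundance` draws log-normal abundances per instrument with
multiplicative male shifts; the optional conflict feature is shifted
oppositely in the first two datasets to exercise merge exclusion.  Each
generator derives a named, independent random stream from the single
seed, so outputs are stable when another generator's draw count changes.

## Numerical conventions

- Undefined values are `nan`, infinite ratios `inf`; both serialize as
  `nan`/`inf`/`-inf` in TSV and round-trip exactly (floats are written
  with `%.17g`).
- Strict inequalities throughout: CV < 0.5, p < 0.05, |log2FC| > 1 — a
  gene at CV exactly 0.5 or a feature at exactly two-fold does not pass.
- Occupancy rows are validated to sum to 1 within 1e−9 at construction;
  normalization itself is accurate to ~1e−15.
- TSV is the single on-disk dialect (tab-separated, UTF-8, '.' decimal,
  header row).  Missing (gene, donor, class) cells read as 0 with a
  logged warning, since 3'-tag RNA-seq legitimately yields zeros;
  negative counts, duplicate rows, and unknown class labels are errors.
- Identifiers are opaque strings; no gene-symbol/accession mapping is
  performed.

## Problem sizes used in the test and acceptance runs

The packaged checks run the simulation at 1000–2000 genes with the
3M/4F design, 50 effect genes at log2 shift 2 with NB size 50 for effect
recovery, 500 abundance features per instrument, and 200-instance
brute-force sweeps for the statistical oracles.  These sizes give stable
Monte-Carlo estimates (binomial SE on the null fraction ≈ 0.7% at
n ≈ 1000) while keeping a full run in seconds on one core.

## Known limitations

- The per-row Welch test at uncorrected p < 0.05 is a screening
  statistic; with thousands of features the significant list contains
  the expected ~5% false positives, and downstream enrichment inherits
  them.
- With n = 3 vs 4 donors the Welch test has few degrees of freedom;
  heavy-tailed per-donor TR distributions (not present under the
  generator's noise model) would make it conservative.
- `mann_whitney`'s approximate regime emulates the common
  continuity-corrected normal approximation; exact agreement with any
  particular GUI statistics package is not promised.
- Ribosome-profiling (footprint) data, codon-level occupancy, spline
  fitting or peak calling on gradient traces, and phosphosite
  localization scoring are out of scope.
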