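import math

import numpy as np
import pytest
from scipy import stats as sps

import oracle_toy
from conftest import TOY_GENES, build_toy_matrix
from polyte.core import (
    DonorMeta,
    FractionClass,
    FractionCountMatrix,
    NormalizationError,
    OccupancyProfile,
    PolyteError,
    ValidationError,
)
from polyte.core import TranslationStat
from polyte.simulate import simulate_gradient_trace
from polyte.translation import (
    compare_te_groups,
    compute_translation_stats,
    fraction_abundance_compare,
    normalize_fractions,
    polysome_region_cv,
    qualify,
    statistic_values,
    strong_translation_rate,
    translation_rate,
)


def _profile(rows):
    """Single-donor OccupancyProfile from a list of 4-vectors."""
    donors = [DonorMeta("d1", "male")]
    return OccupancyProfile(
        genes=[f"g{i}" for i in range(len(rows))],
        donors=donors,
        proportions=np.array(rows, dtype=float)[:, None, :],
    )


class TestNormalizeFractions:
    def test_stated_formula_hand_case(self):
        # gene A: free 10/100, mono 5/50, early 20/100, late 30/50
        donors = [DonorMeta("d1", "male")]
        counts = np.array([[[10, 5, 20, 30]], [[90, 45, 80, 20]]])
        m = FractionCountMatrix(["gA", "gB"], donors, counts)
        prof = normalize_fractions(m)
        np.testing.assert_allclose(prof.proportions[0, 0], [0.1, 0.1, 0.2, 0.6], atol=1e-15)

    def test_equal_counts_equal_totals_give_quarter_each(self):
        donors = [DonorMeta("d1", "male")]
        m = FractionCountMatrix(["gA"], donors, np.full((1, 1, 4), 7))
        np.testing.assert_allclose(
            normalize_fractions(m).proportions[0, 0], [0.25] * 4, atol=1e-15
        )

    def test_all_zero_gene_is_undefined(self):
        donors = [DonorMeta("d1", "male")]
        counts = np.array([[[0, 0, 0, 0]], [[5, 5, 5, 5]]])
        prof = normalize_fractions(FractionCountMatrix(["gA", "gB"], donors, counts))
        assert not prof.defined[0, 0] and prof.defined[1, 0]

    def test_zero_column_total_names_donor_and_class(self):
        donors = [DonorMeta("dX", "male")]
        counts = np.array([[[1, 0, 1, 1]]])
        with pytest.raises(NormalizationError, match="dX.*MONOSOME"):
            normalize_fractions(FractionCountMatrix(["gA"], donors, counts))


class TestRatios:
    @pytest.mark.parametrize(
        "row,tr",
        [((0.25, 0.25, 0.25, 0.25), 1.0), ((0.2, 0.2, 0.3, 0.3), 1.5), ((0, 0, 0.4, 0.6), math.inf)],
    )
    def test_translation_rate_hand_cases(self, row, tr):
        assert translation_rate(_profile([row]), "g0", "d1") == pytest.approx(tr, abs=1e-12)

    @pytest.mark.parametrize(
        "row,s",
        [((0.25, 0.25, 0.25, 0.25), 1 / 3), ((0.1, 0.1, 0.2, 0.6), 1.5), ((0, 0, 0, 1), math.inf)],
    )
    def test_strong_translation_rate_hand_cases(self, row, s):
        assert strong_translation_rate(_profile([row]), "g0", "d1") == pytest.approx(s, abs=1e-12)

    def test_undefined_profile_gives_nan(self):
        prof = _profile([(0.25, 0.25, 0.25, 0.25)])
        prof.proportions[0, 0, :] = np.nan
        assert math.isnan(translation_rate(prof, "g0", "d1"))


def _stat(values: dict[str, float]) -> TranslationStat:
    return TranslationStat(gene="g", statistic_kind="TR", per_donor_values=values)


class TestQualify:
    def test_zero_variance_qualifies(self):
        s = qualify([_stat({"a": 2.0, "b": 2.0, "c": 2.0})], ["a", "b", "c"])[0]
        assert (s.group_mean, s.group_sd, s.group_cv, s.qualified) == (2.0, 0.0, 0.0, True)

    def test_cv_exactly_half_fails_strict_threshold(self):
        s = qualify([_stat({"a": 1.0, "b": 2.0, "c": 3.0})], ["a", "b", "c"])[0]
        assert s.group_mean == 2.0 and s.group_sd == pytest.approx(1.0)
        assert s.group_cv == pytest.approx(0.5) and not s.qualified

    def test_infinite_value_disqualifies(self):
        s = qualify([_stat({"a": 2.0, "b": 2.0, "c": math.inf})], ["a", "b", "c"])[0]
        assert not s.qualified
        assert s.group_mean == 2.0  # summary over the finite values only

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            qualify([_stat({"a": 1.0})], [])

    def test_brute_force_agreement_on_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            vals = rng.lognormal(0, 1, n)
            kind = rng.integers(0, 4)
            if kind == 1:
                vals[rng.integers(0, n)] = math.inf
            elif kind == 2:
                vals[rng.integers(0, n)] = math.nan
            donors = [f"d{i}" for i in range(n)]
            got = qualify([_stat(dict(zip(donors, vals)))], donors)[0]
            finite = [v for v in vals if math.isfinite(v)]
            expect = len(finite) == n and (
                np.std(finite, ddof=1) if n > 1 else 0.0
            ) / np.mean(finite) < 0.5
            assert got.qualified == expect


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        a = [_stat({"m1": 2.0, "m2": 2.1, "m3": 1.9})]
        b = [_stat({"f1": 2.0, "f2": 2.1, "f3": 1.9})]
        r = compare_te_groups(a, b, ["g"])[0]
        assert r.log2_fc == 0.0 and not r.significant

    def test_separated_groups_up_in_reference(self):
        a = [_stat({"m1": 4.0, "m2": 4.0, "m3": 4.2})]
        b = [_stat({"f1": 1.0, "f2": 1.1, "f3": 0.9, "f4": 1.0})]
        r = compare_te_groups(a, b, ["g"])[0]
        _, p_ref = sps.ttest_ind([4.0, 4.0, 4.2], [1.0, 1.1, 0.9, 1.0], equal_var=False)
        assert r.significant and r.direction == "up_in_A"
        assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_single_finite_value_gives_undefined_p(self):
        a = [_stat({"m1": 4.0, "m2": math.inf})]
        b = [_stat({"f1": 1.0, "f2": 1.1})]
        r = compare_te_groups(a, b, ["g"])[0]
        assert math.isnan(r.p_value) and not r.significant


class TestFractionAbundanceCompare:
    def test_shared_profile_nothing_significant(self):
        donors = [DonorMeta(f"d{i}", "male" if i < 3 else "female") for i in range(7)]
        counts = np.tile(np.array([[3, 4, 5, 6]]), (2, 7, 1)).reshape(2, 7, 4)
        m = FractionCountMatrix(["gA", "gB"], donors, counts)
        prof = normalize_fractions(m)
        res = fraction_abundance_compare(
            prof, FractionClass.FREE, [d.donor_id for d in donors[:3]],
            [d.donor_id for d in donors[3:]],
        )
        assert all(not r.significant for r in res)

    def test_constructed_free_enrichment_up_in_males(self):
        donors = [DonorMeta(f"m{i}", "male") for i in range(3)] + [
            DonorMeta(f"f{i}", "female") for i in range(4)
        ]
        male_rows = [(0.8, 0.1, 0.05, 0.05), (0.8, 0.1, 0.05, 0.05), (0.75, 0.1, 0.1, 0.05)]
        female_rows = [(0.2, 0.3, 0.25, 0.25), (0.25, 0.3, 0.25, 0.2),
                       (0.2, 0.3, 0.25, 0.25), (0.22, 0.28, 0.25, 0.25)]
        props = np.array(male_rows + female_rows)[None, :, :]
        prof = OccupancyProfile(["gA"], donors, props)
        r = fraction_abundance_compare(
            prof, FractionClass.FREE, [d.donor_id for d in donors[:3]],
            [d.donor_id for d in donors[3:]],
        )[0]
        assert r.significant and r.direction == "up_in_A"

    def test_undefined_donor_dropped(self):
        donors = [DonorMeta(f"m{i}", "male") for i in range(3)] + [
            DonorMeta(f"f{i}", "female") for i in range(2)
        ]
        props = np.tile(np.array([0.4, 0.3, 0.2, 0.1]), (1, 5, 1))
        props[0, 4, :] = np.nan
        prof = OccupancyProfile(["gA"], donors, props)
        r = fraction_abundance_compare(
            prof, FractionClass.FREE, ["m0", "m1", "m2"], ["f0", "f1"]
        )[0]
        assert math.isnan(r.p_value)  # only one defined female left


class TestPolysomeRegionCv:
    def test_constant_region_cv_zero(self):
        trace = simulate_gradient_trace(0.0, [], noise_sd=0.0, seed=0)
        assert polysome_region_cv(trace) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_values_closed_form(self):
        positions = np.arange(1, 76)
        absorbance = np.where(positions % 2 == 0, 3.0, 1.0)
        from polyte.core import GradientTrace

        cv = polysome_region_cv(GradientTrace(positions, absorbance))
        region = absorbance[(positions >= 40) & (positions <= 75)]
        assert cv == pytest.approx(np.std(region, ddof=1) / region.mean(), abs=1e-15)

    def test_truncated_trace_rejected(self):
        from polyte.core import GradientTrace

        trace = GradientTrace(np.arange(1, 61), np.ones(60))
        with pytest.raises(PolyteError, match="polysome region"):
            polysome_region_cv(trace)


class TestInvariantsOnToyMatrix:
    def test_occupancy_conservation(self, toy_matrix):
        prof = normalize_fractions(toy_matrix)
        sums = np.nansum(prof.proportions, axis=2)[prof.defined]
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_depth_invariance(self, toy_matrix):
        prof = normalize_fractions(toy_matrix)
        scaled = toy_matrix.counts.copy()
        scaled[:, 1, 2] *= 37  # one (donor, class) column
        m2 = FractionCountMatrix(toy_matrix.genes, toy_matrix.donors, scaled)
        prof2 = normalize_fractions(m2)
        np.testing.assert_allclose(
            prof2.proportions, prof.proportions, atol=1e-10, equal_nan=True
        )

    def test_mass_transfer_to_late_polysome_increases_tr_and_str(self):
        base = np.array([0.3, 0.3, 0.2, 0.2])
        prev_tr, prev_str = 0.0, 0.0
        for delta in (0.05, 0.1, 0.15, 0.2):
            row = base + np.array([-delta, 0, 0, delta])
            prof = _profile([row])
            tr = translation_rate(prof, "g0", "d1")
            s = strong_translation_rate(prof, "g0", "d1")
            assert tr > prev_tr and s > prev_str
            prev_tr, prev_str = tr, s

    def test_full_chain_matches_rational_oracle(self, toy_matrix):
        prof = normalize_fractions(toy_matrix)
        oracle_props = oracle_toy.proportions()
        for i, g in enumerate(TOY_GENES):
            for j, d in enumerate(oracle_toy.DONOR_IDS):
                expect = oracle_props[(g, d)]
                if expect is None:
                    assert not prof.defined[i, j]
                else:
                    np.testing.assert_allclose(
                        prof.proportions[i, j], [float(x) for x in expect], atol=1e-14
                    )
                got_tr = statistic_values(prof, "TR")[i, j]
                want_tr = oracle_toy.tr(g, d)
                assert (math.isnan(got_tr) and math.isnan(want_tr)) or got_tr == pytest.approx(
                    want_tr, abs=1e-12
                )
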