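"""Replication statistics: chi-squared, Mann-Whitney, population-SD CI,
and the group-comparison table builder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hlhscreen import (
    Cohort,
    GeneratorConfig,
    TwoByTwo,
    build_table3,
    chi_squared_2x2,
    generate_cohort,
    mann_whitney_u,
    percent_difference,
    population_z_ci,
    population_z_ci_display,
)
from hlhscreen.stats import SmallExpectedCountWarning


class TestChiSquared:
    @pytest.mark.parametrize(
        "table,expected",
        [((38, 68, 12, 2), 12.6515), ((6, 100, 10, 4), 46.2907), ((10, 10, 10, 10), 0.0)],
    )
    def test_known_statistics(self, table, expected):
        with pytest.warns() if expected > 20 else _nullcontext():
            stat, _ = chi_squared_2x2(TwoByTwo(*table))
        assert stat == pytest.approx(expected, abs=5e-5)

    def test_matches_scipy_uncorrected(self):
        import warnings

        for table in [(38, 68, 12, 2), (44, 62, 12, 2), (12, 94, 8, 6), (5, 7, 3, 11)]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SmallExpectedCountWarning)
                stat, p = chi_squared_2x2(TwoByTwo(*table))
            ref_stat, ref_p, _, _ = sps.chi2_contingency(
                np.array(table).reshape(2, 2), correction=False
            )
            assert stat == pytest.approx(ref_stat)
            assert p == pytest.approx(ref_p)

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40), c=st.integers(0, 40), d=st.integers(0, 40)
    )
    @settings(max_examples=200, deadline=None)
    def test_closed_form_and_symmetries(self, a, b, c, d):
        import warnings

        if min(a + b, c + d, a + c, b + d) == 0 or a + b + c + d == 0:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            stat, _ = chi_squared_2x2(TwoByTwo(a, b, c, d))
            n = a + b + c + d
            closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(closed)
            row_swapped, _ = chi_squared_2x2(TwoByTwo(c, d, a, b))
            col_swapped, _ = chi_squared_2x2(TwoByTwo(b, a, d, c))
        assert stat == pytest.approx(row_swapped)
        assert stat == pytest.approx(col_swapped)

    def test_small_expected_counts_warn_but_compute(self):
        with pytest.warns(SmallExpectedCountWarning):
            stat, _ = chi_squared_2x2(TwoByTwo(1, 105, 3, 11))
        assert stat == pytest.approx(16.1056, abs=5e-5)

    def test_degenerate_marginal_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared_2x2(TwoByTwo(0, 0, 5, 5))
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared_2x2(TwoByTwo(0, 5, 0, 5))


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


def _pairwise_u(x, y):
    """Exhaustive oracle: wins plus half-ties for the first sample."""
    return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, z, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert z < 0  # first group smaller -> negative z
        assert _pairwise_u([1, 2, 3], [4, 5, 6]) == 0

    def test_identical_samples_give_zero_z(self):
        u, z, p = mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_identical_pooled_is_flagged(self):
        with pytest.warns(UserWarning, match="identical"):
            u, z, p = mann_whitney_u([3, 3], [3, 3, 3])
        assert math.isnan(z) and math.isnan(p)

    def test_u_matches_pairwise_oracle_all_small_sizes(self):
        """U equals the brute-force discordant-pair count (plus half-ties)
        for every sample-size pair up to 8x8, with tied values present."""
        import warnings

        rng = np.random.default_rng(7)
        for n in range(1, 9):
            for m in range(1, 9):
                for _ in range(3):
                    x = rng.integers(0, 5, size=n).astype(float)
                    y = rng.integers(0, 5, size=m).astype(float)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)  # all-tied pools
                        u, _, _ = mann_whitney_u(x, y)
                    assert u == pytest.approx(_pairwise_u(x, y)), (x, y)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        u, z, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_sign_convention_negative_for_smaller_first_group(self):
        rng = np.random.default_rng(3)
        low = rng.normal(0, 1, 40)
        high = rng.normal(2, 1, 40)
        _, z, _ = mann_whitney_u(low, high)
        assert z < 0
        _, z2, _ = mann_whitney_u(high, low)
        assert z2 > 0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPopulationCI:
    def test_closed_form_two_points(self):
        mean, lo, hi = population_z_ci([0.0, 2.0])
        half = 1.959963984540054 * 1.0 / math.sqrt(2)
        assert mean == 1.0
        assert hi - mean == pytest.approx(half)
        assert mean - lo == pytest.approx(half)

    def test_constant_list_zero_width(self):
        mean, lo, hi = population_z_ci([5.0, 5.0, 5.0])
        assert mean == lo == hi == 5.0

    def test_symmetric_and_narrows_as_sqrt_n(self):
        base = [1.0, 2.0, 3.0, 4.0]
        m1, lo1, hi1 = population_z_ci(base)
        m4, lo4, hi4 = population_z_ci(base * 4)  # same SD, 4x the n
        assert hi1 - m1 == pytest.approx(m1 - lo1)
        assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            population_z_ci([1.0])

    def test_display_rounds_mean_and_margin_first(self):
        # mean 10.4 -> 10, margin ~3.46 -> 3: endpoints from the rounded pair
        mean, lo, hi = population_z_ci_display([7.0, 10.0, 14.2])
        assert (lo + hi) / 2 == mean
        assert isinstance(mean, int)


class TestTypeIError:
    def test_null_rejection_rate_near_nominal(self):
        """Under independence (two Bernoulli(0.3) groups of 60, 10,000
        replicate tables) the fraction of p < 0.05 sits within 3 SE of
        0.05."""
        import warnings

        rng = np.random.default_rng(20260929)
        reps, n1, n2, rate = 10_000, 60, 60, 0.3
        a = rng.binomial(n1, rate, reps)
        c = rng.binomial(n2, rate, reps)
        rejected = 0
        valid = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            for ai, ci in zip(a, c):
                try:
                    _, p = chi_squared_2x2(TwoByTwo(int(ai), n1 - int(ai), int(ci), n2 - int(ci)))
                except ValueError:
                    continue
                valid += 1
                rejected += p < 0.05
        frac = rejected / valid
        se = math.sqrt(0.05 * 0.95 / valid)
        assert abs(frac - 0.05) <= 3 * se


class TestPercentDifference:
    def test_published_group_means(self):
        assert percent_difference(14706, 9260) == pytest.approx(58.8, abs=0.05)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


@pytest.fixture(scope="module")
def synthetic():
    return generate_cohort(GeneratorConfig(n=400, seed=5))


class TestBuildTable3:

    def test_row_structure(self, synthetic):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            rows = build_table3(synthetic)
        assert len(rows) == 12
        assert rows[0].test_name == "mann-whitney"
        assert all(r.test_name == "chi-squared" for r in rows[1:])

    def test_counts_match_direct_tallies(self, synthetic):
        import warnings

        from hlhscreen import hscore

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            rows = build_table3(synthetic)
        low = [p for p in synthetic if not hscore(p).positive]
        high = [p for p in synthetic if hscore(p).positive]
        fever_row = next(r for r in rows if "fever" in r.label)
        assert fever_row.group1_count == sum(bool(p.has_fever()) for p in low)
        assert fever_row.group2_count == sum(bool(p.has_fever()) for p in high)

    def test_percent_formatting(self, synthetic):
        from hlhscreen.screening import percent_display

        assert percent_display(38 / 106) == "35.8"

    def test_mann_whitney_z_negative_when_low_group_smaller(self, synthetic):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            rows = build_table3(synthetic)
        # the below-cutoff group has systematically lower ferritins by design
        assert rows[0].statistic < 0

    def test_single_group_errors(self):
        from conftest import make_record
        from hlhscreen import CensoredValue

        cohort = Cohort([make_record(patient_id=f"q{i}", ferritin_ugL=CensoredValue(6000))
                         for i in range(5)])
        with pytest.raises(ValueError, match="both HScore groups"):
            build_table3(cohort)
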