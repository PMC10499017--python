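"""Tests for the exact contingency statistics.

The Fisher implementation (rational arithmetic) is cross-checked against
two independent routes: an exact factorial-based enumeration oracle and
scipy's floating-point implementation.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.special import erfc
from scipy.stats import fisher_exact as scipy_fisher

from mirkit.model import ClassDistribution, DonorClass, RecombinantClass
from mirkit.stats import (
    ContingencyTable,
    chi_square_gof,
    compare_cohort_to_model,
    expected_independent,
    fisher_exact_2x2,
    round_half_away,
)


def oracle_two_sided(a, b, c, d):
    """Independent exact Fisher oracle: factorial enumeration in rationals."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def pmf(k):
        f = math.factorial
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(n - c1),
            f(n) * f(k) * f(r1 - k) * f(c1 - k) * f(r2 - c1 + k),
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cutoff)


class TestFisherExact:
    def test_pol32_shift(self):
        """MIR2-signature shift 55/93 vs 8/24 reproduces the published 0.037."""
        p = fisher_exact_2x2([[55, 38], [8, 16]])
        assert round(p, 3) == 0.037

    def test_flank_homology_table(self):
        """9/48 vs 0/46 recomputes to 2.61e-3 (enumeration-oracle value)."""
        p = fisher_exact_2x2([[9, 39], [0, 46]])
        assert p == pytest.approx(2.6124681178760177e-3, rel=1e-9)
        assert p == pytest.approx(float(oracle_two_sided(9, 39, 0, 46)))

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 5], [0, 7]]) == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle_and_scipy_small_tables(self, seed):
        """Exact-rational agreement with the factorial oracle, and float
        agreement with scipy, over random tables with N <= 40."""
        rng = np.random.default_rng(seed)
        for _ in range(60):
            cells = rng.multinomial(int(rng.integers(1, 41)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            table = [[a, b], [c, d]]
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            p = fisher_exact_2x2(table)
            assert p == pytest.approx(float(oracle_two_sided(a, b, c, d)),
                                      rel=1e-12)
            assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-9)

    def test_one_sided_bounds_two_sided(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            cells = [int(x) for x in rng.integers(0, 15, size=4)]
            table = [[cells[0], cells[1]], [cells[2], cells[3]]]
            if sum(cells) == 0 or 0 in (
                cells[0] + cells[1], cells[2] + cells[3],
                cells[0] + cells[2], cells[1] + cells[3],
            ):
                continue
            two = fisher_exact_2x2(table)
            less = fisher_exact_2x2(table, alternative="less")
            greater = fisher_exact_2x2(table, alternative="greater")
            assert 0 < two <= 1
            assert two >= min(less, greater) - 1e-12

    def test_doubling_variant(self):
        p_sum = fisher_exact_2x2([[55, 38], [8, 16]])
        p_dbl = fisher_exact_2x2(
            [[55, 38], [8, 16]], two_sided_method="double_one_tail"
        )
        assert p_dbl >= p_sum  # doubling is conservative here
        assert p_dbl <= 1.0


class TestChiSquareGof:
    def test_b1_exclusion_p(self):
        """Observed 0 vs expected 5.14 B1 events gives p = 0.02 (2 d.p.)."""
        e = expected_independent(16, 27, 84)
        stat, p = chi_square_gof([0.0], [e], df=1)
        assert stat == pytest.approx(e)
        assert round(p, 2) == 0.02

    def test_identity(self):
        stat, p = chi_square_gof([5, 5], [5.0, 5.0], df=1)
        assert stat == 0.0
        assert p == 1.0

    def test_hand_arithmetic(self):
        stat, _ = chi_square_gof([10, 0], [5.0, 5.0], df=1)
        assert stat == pytest.approx(10.0)

    def test_closed_form_df1(self):
        """At df=1 the p-value equals erfc(sqrt(stat/2))."""
        for stat_in in (0.5, 1.0, 3.84, 10.0):
            _, p = chi_square_gof([stat_in**0.5 + 1], [1.0], df=1)
            stat = (stat_in**0.5 + 1 - 1) ** 2
            assert p == pytest.approx(float(erfc(math.sqrt(stat / 2))),
                                      abs=1e-10)

    def test_rejects_nonpositive_expected(self):
        with pytest.raises(ValueError):
            chi_square_gof([1], [0.0], df=1)


class TestExpectedIndependent:
    def test_b1_expectation(self):
        e = expected_independent(16, 27, 84)
        assert e == pytest.approx(5.142857142857143)
        assert round_half_away(e) == 5

    def test_symmetry_and_zero(self):
        assert expected_independent(16, 27, 84) == expected_independent(
            27, 16, 84
        )
        assert expected_independent(0, 27, 84) == 0.0

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            expected_independent(1, 1, 0)


class TestCompareCohortToModel:
    @staticmethod
    def _dist():
        return ClassDistribution(
            {
                RecombinantClass(DonorClass.B, 0): 0.25,
                RecombinantClass(DonorClass.C, 1): 0.5,
                RecombinantClass(DonorClass.D, 0): 0.25,
            }
        )

    def test_exact_expectation_gives_p_one(self):
        observed = {
            RecombinantClass(DonorClass.B, 0): 25,
            RecombinantClass(DonorClass.C, 1): 50,
            RecombinantClass(DonorClass.D, 0): 25,
        }
        report = compare_cohort_to_model(observed, self._dist())
        assert report["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert report["p_value"] == pytest.approx(1.0)

    def test_unsupported_category_rejected(self):
        observed = {RecombinantClass(DonorClass.A, 0): 3}
        with pytest.raises(ValueError):
            compare_cohort_to_model(observed, self._dist())

    def test_small_cells_pooled(self):
        observed = {
            RecombinantClass(DonorClass.B, 0): 2,
            RecombinantClass(DonorClass.C, 1): 5,
            RecombinantClass(DonorClass.D, 0): 3,
        }
        report = compare_cohort_to_model(observed, self._dist())
        assert report["pooled_classes"]  # expected < 5 cells were pooled

    def test_calibration_on_simulated_cohorts(self):
        """p-values are roughly uniform for cohorts drawn from the model."""
        from scipy.stats import kstest

        from mirkit.simulate import gen_cohort

        dist = self._dist()
        pvals = [
            compare_cohort_to_model(
                gen_cohort(dist, 10_000, seed=s), dist
            )["p_value"]
            for s in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01
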