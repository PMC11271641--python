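"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median, OR scale."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr import HarmonizedSet, ivw, mr_egger, to_odds_ratio, wald_ratio, weighted_median
from tsmr.estimators import Z_975, _weighted_median_point
from tsmr.exceptions import AnalysisError, ConfigurationError, InsufficientInstrumentsError


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,ratio,se",
        [(0.1, 0.05, 0.02, 0.5, 0.2), (0.1, 0.0, 0.02, 0.0, 0.2), (-0.1, 0.05, 0.02, -0.5, 0.2)],
    )
    def test_arithmetic(self, bx, by, sy, ratio, se):
        r, s = wald_ratio(bx, by, sy)
        assert r == pytest.approx(ratio) and s == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(AnalysisError):
            wald_ratio(0.0, 0.1, 0.02)


class TestIvw:
    def test_two_snp_worked_example(self, hset_factory):
        # ratios {0.5, 1.0} with ratio-SEs {0.1, 0.2} -> weights {100, 25}
        h = hset_factory([1.0, 1.0], [0.5, 1.0], [0.1, 0.2])
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.6)
        assert est.se == pytest.approx(1 / math.sqrt(125))
        assert est.method == "ivw_fixed" and est.n_snps == 2

    def test_homogeneous_ratios_fixed_equals_random(self, hset_factory):
        h = hset_factory([1.0, 2.0, 0.5], [0.3, 0.6, 0.15], [0.1, 0.1, 0.1])
        fixed, random = ivw(h, model="fixed"), ivw(h, model="random")
        assert fixed.beta == pytest.approx(0.3) == pytest.approx(random.beta)
        assert random.se == pytest.approx(fixed.se)  # Q = 0 -> scale floored at 1

    def test_matches_weighted_regression_through_origin(self, hset_factory):
        """IVW beta equals the slope of a 1/se_out^2-weighted origin regression."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            k = rng.integers(3, 12)
            bx = rng.uniform(0.05, 0.3, k)
            by = rng.normal(0.2 * bx, 0.05)
            sy = rng.uniform(0.01, 0.1, k)
            h = hset_factory(bx, by, sy)
            w = 1.0 / sy**2
            slope = np.sum(w * bx * by) / np.sum(w * bx**2)  # weighted normal equations
            assert ivw(h, model="fixed").beta == pytest.approx(slope, rel=1e-10)

    def test_auto_switches_on_heterogeneity(self, hset_factory):
        hom = hset_factory([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        assert ivw(hom, model="auto").method == "ivw_fixed"
        het = hset_factory([1.0, 1.0, 1.0], [2.0, -2.0, 0.0], [0.1, 0.1, 0.1])
        est = ivw(het, model="auto")
        assert est.method == "ivw_random"
        assert est.overdispersion_scale > 1
        assert est.se > ivw(het, model="fixed").se

    def test_single_snp_degenerates_to_wald(self, hset_factory):
        est = ivw(hset_factory([0.1], [0.05], [0.02]))
        assert est.method == "wald"
        assert est.beta == pytest.approx(0.5) and est.se == pytest.approx(0.2)

    def test_all_zero_exposure_effects_error(self, hset_factory):
        with pytest.raises(AnalysisError):
            ivw(hset_factory([0.0, 0.0], [0.1, 0.1], [0.1, 0.1]))


class TestEgger:
    def test_recovers_exact_linear_data(self, hset_factory):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = hset_factory(bx, 0.1 + 0.3 * bx, [0.05, 0.04, 0.03, 0.05])
        est = mr_egger(h)
        assert est.intercept == pytest.approx(0.1, abs=1e-10)
        assert est.beta == pytest.approx(0.3, abs=1e-10)

    def test_zero_intercept_without_pleiotropy(self, hset_factory):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(hset_factory(bx, 0.3 * bx, [0.05] * 4))
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_normal_equations(self, hset_factory):
        """Slope/intercept agree with an independent normal-equations solve to 1e-10."""
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.05, 0.4, 5)
        by = rng.normal(0.05 + 0.25 * bx, 0.03)
        sy = rng.uniform(0.02, 0.08, 5)
        est = mr_egger(hset_factory(bx, by, sy))
        W = np.diag(1.0 / sy**2)
        X = np.column_stack([np.ones(5), bx])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert est.intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_orientation_makes_result_invariant_to_exposure_sign(self, hset_factory):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.4, 6)
        by = 0.05 + 0.25 * bx + rng.normal(0, 0.02, 6)
        sy = np.full(6, 0.05)
        flip = np.array([1, -1, 1, -1, 1, -1.0])
        a = mr_egger(hset_factory(bx, by, sy))
        b = mr_egger(hset_factory(bx * flip, by * flip, sy))
        assert b.beta == pytest.approx(a.beta) and b.intercept == pytest.approx(a.intercept)

    def test_needs_three_snps(self, hset_factory):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset_factory([0.1, 0.2], [0.03, 0.06], [0.05, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_three_ratios(self, hset_factory):
        h = hset_factory([1.0, 1.0, 1.0], [0.4, 0.5, 0.9], [0.1, 0.1, 0.1])
        assert weighted_median(h, n_boot=200, seed=1).beta == pytest.approx(0.5)

    def test_interpolation_between_midpoints(self):
        # equal weights, midpoints {1/6, 1/2, 5/6}: p = 2/3 interpolates linearly
        assert _weighted_median_point(np.array([0.4, 0.5, 0.9]), np.ones(3)) == pytest.approx(0.5)

    def test_dominant_snp_with_balanced_flanks_returns_its_ratio(self, hset_factory):
        # weights 0.2/0.6/0.2: the dominant SNP's cumulative midpoint is exactly 0.5
        w = np.array([0.2, 0.6, 0.2])
        se_ratio = 1.0 / np.sqrt(w)
        h = hset_factory([1.0, 1.0, 1.0], [0.1, 0.45, 0.9], se_ratio)
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.45)

    def test_degenerate_distribution_and_vanishing_se(self, hset_factory):
        h = hset_factory([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], [1e-8, 1e-8, 1e-8],
                         se_exp=[1e-8] * 3)
        est = weighted_median(h, n_boot=200, seed=5)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-6

    def test_seeded_determinism(self, hset_factory):
        h = hset_factory([0.1, 0.2, 0.3], [0.03, 0.08, 0.06], [0.02, 0.02, 0.02],
                         se_exp=[0.01, 0.01, 0.01])
        a = weighted_median(h, n_boot=300, seed=42)
        b = weighted_median(h, n_boot=300, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_invalid_n_boot(self, hset_factory):
        h = hset_factory([1.0] * 3, [0.1] * 3, [0.1] * 3)
        with pytest.raises(ConfigurationError):
            weighted_median(h, n_boot=0)


class TestOddsRatioScale:
    @pytest.mark.parametrize(
        "beta,se,or_,lo,hi",
        [
            (0.0, 0.0, 1.0, 1.0, 1.0),
            (math.log(2), 0.0, 2.0, 2.0, 2.0),
            (-0.2485, 0.0857, 0.78, 0.66, 0.92),
        ],
    )
    def test_examples(self, beta, se, or_, lo, hi):
        o, l, h = to_odds_ratio(beta, se)
        assert round(o, 2) == or_ and round(l, 2) == lo and round(h, 2) == hi

    def test_estimates_expose_consistent_or_and_ci(self, hset_factory):
        est = ivw(hset_factory([1.0, 1.0], [0.5, 1.0], [0.1, 0.2]), model="fixed")
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.ci_low == pytest.approx(math.exp(est.beta - Z_975 * est.se))
        assert est.ci_low <= est.or_ <= est.ci_high


@given(c=st.floats(0.2, 5.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_scale_equivariance_in_exposure_units(c):
    """Multiplying every beta_exp by c > 0 divides every causal estimate by c."""
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.25])
    by = np.array([0.04, 0.05, 0.10, 0.13, 0.06])
    sy = np.array([0.02, 0.03, 0.02, 0.04, 0.03])
    base = HarmonizedSet.from_arrays(bx, [1e-9] * 5, by, sy)
    scaled = HarmonizedSet.from_arrays(bx * c, [1e-9] * 5, by, sy)
    assert ivw(scaled, model="fixed").beta == pytest.approx(ivw(base, model="fixed").beta / c)
    assert mr_egger(scaled).beta == pytest.approx(mr_egger(base).beta / c)
    assert weighted_median(scaled, n_boot=100, seed=2).beta == pytest.approx(
        weighted_median(base, n_boot=100, seed=2).beta / c
    )


def test_outcome_sign_symmetry(hset_factory):
    """Negating all beta_out negates every method's estimate."""
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.25])
    by = np.array([0.04, 0.05, 0.10, 0.13, 0.06])
    sy = np.array([0.02, 0.03, 0.02, 0.04, 0.03])
    pos = HarmonizedSet.from_arrays(bx, [1e-9] * 5, by, sy)
    neg = HarmonizedSet.from_arrays(bx, [1e-9] * 5, -by, sy)
    assert ivw(neg, model="fixed").beta == pytest.approx(-ivw(pos, model="fixed").beta)
    assert mr_egger(neg).beta == pytest.approx(-mr_egger(pos).beta)
    assert weighted_median(neg, n_boot=100, seed=3).beta == pytest.approx(
        -weighted_median(pos, n_boot=100, seed=3).beta
    )
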