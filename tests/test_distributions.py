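"""Extended beta-binomial kernel: pmf, log-pmf, gradient, variance, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from ebbase.distributions import (
    AllelicCount,
    EBBInvalidParameters,
    EBBLimitCase,
    EBBNatural,
    EBBShape,
    ebb_dlogpmf_dq,
    ebb_logpmf,
    ebb_pmf_natural,
    ebb_pmf_shape,
    ebb_pmf_vector,
    ebb_sample,
    ebb_variance,
    shape_to_natural,
)
from oracle import params_valid, pmf_exact, shape_to_rational


class TestPmfNatural:
    @pytest.mark.parametrize(
        "m, n, alpha, beta, d, expected",
        [
            (1, 2, 1, 1, 0, 0.5),        # binomial(2, 1/2)
            (1, 2, 1, 1, 1, 1 / 3),      # uniform beta-binomial
            (1, 2, 2, 2, -1, 2 / 3),     # hypergeometric C(2,1)C(2,1)/C(4,2)
        ],
    )
    def test_family_members(self, m, n, alpha, beta, d, expected):
        assert ebb_pmf_natural(m, n, EBBNatural(alpha, beta, d)) == pytest.approx(expected)

    def test_scale_invariance(self):
        base = ebb_pmf_natural(3, 7, EBBNatural(0.4, 0.6, 0.2))
        for x in (2.0, 0.5, 17.3):
            scaled = ebb_pmf_natural(3, 7, EBBNatural(0.4 * x, 0.6 * x, 0.2 * x))
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_out_of_support_raises(self):
        with pytest.raises(ValueError):
            ebb_pmf_natural(-1, 5, EBBNatural(1, 1, 0))
        with pytest.raises(ValueError):
            ebb_pmf_natural(6, 5, EBBNatural(1, 1, 0))

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(EBBInvalidParameters):
            ebb_pmf_natural(1, 10, EBBNatural(1, 1, -0.5))

    def test_hypergeometric_tail_is_exact_zero(self):
        # drawing more type-1 balls than the urn holds is impossible
        assert ebb_pmf_natural(4, 6, EBBNatural(3, 10, -1)) == 0.0

    def test_matches_exact_rational_oracle(self, rng):
        checked = 0
        while checked < 60:
            n = int(rng.integers(2, 40))
            m = int(rng.integers(0, n + 1))
            from fractions import Fraction

            alpha = Fraction(int(rng.integers(1, 30)), int(rng.integers(1, 10)))
            beta = Fraction(int(rng.integers(1, 30)), int(rng.integers(1, 10)))
            d = Fraction(int(rng.integers(-2, 6)), int(rng.integers(1, 4)))
            if not params_valid(n, alpha, beta, d):
                continue
            expected = float(pmf_exact(m, n, alpha, beta, d))
            got = ebb_pmf_natural(m, n, EBBNatural(float(alpha), float(beta), float(d)))
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)
            checked += 1


class TestShapeParameterisation:
    def test_binomial_point(self):
        assert shape_to_natural(EBBShape(0.5, 1, 100)) == EBBNatural(0.5, 0.5, 0.0)

    def test_direct_substitution(self):
        nat = shape_to_natural(EBBShape(0.3, 2, 10))
        assert (nat.alpha, nat.beta, nat.d) == pytest.approx((0.3, 0.7, 0.125))

    def test_q_equals_n_is_limit_case(self):
        with pytest.raises(EBBLimitCase):
            shape_to_natural(EBBShape(0.5, 10, 10))

    def test_two_point_limit_distribution(self):
        shape = EBBShape(0.3, 2, 2)
        assert ebb_pmf_shape(1, shape) == 0.0
        assert ebb_pmf_shape(0, shape) == pytest.approx(0.7)
        assert ebb_pmf_shape(2, shape) == pytest.approx(0.3)

    def test_q1_equals_binomial(self):
        assert ebb_pmf_shape(5, EBBShape(0.5, 1, 10)) == pytest.approx(0.24609375)
        for m in range(11):
            assert ebb_pmf_shape(m, EBBShape(0.3, 1, 10)) == pytest.approx(
                stats.binom.pmf(m, 10, 0.3), rel=1e-12
            )

    def test_shape_pmf_matches_rational_oracle(self):
        a, b, d = shape_to_rational("3/5", 2, 10)
        expected = float(pmf_exact(3, 10, a, b, d))
        assert ebb_pmf_shape(3, EBBShape(0.6, 2, 10)) == pytest.approx(expected, rel=1e-12)


class TestFamilyContainment:
    """d in {-1, 0, 1} recovers hypergeometric, binomial, beta-binomial."""

    @pytest.mark.parametrize("n", [5, 20, 100])
    @pytest.mark.parametrize("ai", [0.2, 0.5, 0.7])
    def test_binomial(self, n, ai):
        pmf = [ebb_pmf_natural(m, n, EBBNatural(ai, 1 - ai, 0.0)) for m in range(n + 1)]
        np.testing.assert_allclose(pmf, stats.binom.pmf(np.arange(n + 1), n, ai), rtol=1e-10)

    @pytest.mark.parametrize("n, a, b", [(10, 2.0, 3.0), (50, 0.7, 1.3), (100, 5.0, 5.0)])
    def test_beta_binomial_loggamma_closed_form(self, n, a, b):
        m = np.arange(n + 1)
        logpmf = (
            gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
            + gammaln(m + a) + gammaln(n - m + b) - gammaln(n + a + b)
            + gammaln(a + b) - gammaln(a) - gammaln(b)
        )
        got = [ebb_pmf_natural(int(mm), n, EBBNatural(a, b, 1.0)) for mm in m]
        np.testing.assert_allclose(got, np.exp(logpmf), rtol=1e-10)

    @pytest.mark.parametrize("M, P, n", [(5, 5, 5), (12, 8, 10), (30, 70, 25)])
    def test_hypergeometric(self, M, P, n):
        m = np.arange(n + 1)
        expected = stats.hypergeom.pmf(m, M + P, M, n)
        got = [ebb_pmf_natural(int(mm), n, EBBNatural(M, P, -1.0)) for mm in m]
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-300)


class TestNormalizationAndSymmetry:
    @pytest.mark.parametrize("n", [2, 10, 100, 1000])
    @pytest.mark.parametrize("ai", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_normalization_grid(self, n, ai):
        for q in (0.5, 1.0, 2.0, n / 2):
            if not 0 < q <= n:
                continue
            try:
                pmf = ebb_pmf_vector(EBBShape(ai, q, n))
            except EBBInvalidParameters:
                assert q < 1  # only underdispersed combos may be infeasible
                continue
            assert abs(pmf.sum() - 1.0) < 1e-10

    def test_mirror_symmetry(self):
        for m in range(11):
            left = ebb_pmf_shape(m, EBBShape(0.3, 2.5, 10))
            right = ebb_pmf_shape(10 - m, EBBShape(0.7, 2.5, 10))
            assert left == pytest.approx(right, rel=1e-12)

    def test_continuity_through_q1(self):
        """Total variation to binomial vanishes as q -> 1 from both sides."""
        n, ai = 50, 0.4
        binom = stats.binom.pmf(np.arange(n + 1), n, ai)
        for q in (1 - 1e-6, 1 + 1e-6):
            pmf = ebb_pmf_vector(EBBShape(ai, q, n))
            assert 0.5 * np.abs(pmf - binom).sum() < 1e-4

    def test_pmf_vector_agrees_with_scalar(self):
        shape = EBBShape(0.6, 3.0, 40)
        vec = ebb_pmf_vector(shape)
        scal = [ebb_pmf_shape(m, shape) for m in range(41)]
        np.testing.assert_allclose(vec, scal, rtol=1e-10)


class TestLogPmf:
    def test_binomial_case(self):
        assert ebb_logpmf(1, 2, EBBNatural(1, 1, 0)) == pytest.approx(math.log(0.5))

    def test_matches_log_of_product(self):
        val = ebb_logpmf(3, 10, EBBNatural(0.6, 0.4, 0.125))
        direct = math.log(ebb_pmf_natural(3, 10, EBBNatural(0.6, 0.4, 0.125)))
        assert val == pytest.approx(direct, rel=1e-10)

    def test_matches_rational_oracle_randomised(self, rng):
        from fractions import Fraction

        checked = 0
        while checked < 40:
            n = int(rng.integers(2, 200))
            m = int(rng.integers(0, n + 1))
            ai = Fraction(int(rng.integers(1, 10)), 10)
            q = Fraction(int(rng.integers(1, 4 * n)), 4)
            if not 0 < q < n:
                continue
            a, b, d = shape_to_rational(ai, q, n)
            if not params_valid(n, a, b, d):
                continue
            expected = pmf_exact(m, n, a, b, d)
            if expected <= 0:
                continue
            got = ebb_logpmf(m, n, EBBNatural(float(a), float(b), float(d)))
            # exact log via integer arithmetic: log(num) - log(den)
            log_expected = math.log(expected.numerator) - math.log(expected.denominator)
            assert got == pytest.approx(log_expected, rel=1e-10)
            checked += 1

    def test_zero_probability_returns_minus_inf(self):
        assert ebb_logpmf(4, 6, EBBNatural(3, 10, -1)) == -np.inf

    def test_large_n_finite_and_normalized(self):
        n = 10**6
        nat = shape_to_natural(EBBShape(0.5, 2, n))
        lp = ebb_logpmf(n // 2, n, nat)
        assert np.isfinite(lp)
        pmf = ebb_pmf_vector(EBBShape(0.5, 2, n))
        assert abs(pmf.sum() - 1.0) < 1e-8
        # spot-check the paired formula against the vector evaluation where
        # the pmf is representable in float (sd ~ 707 around the centre)
        for m in (498_000, 499_500, 500_000, 501_234):
            assert ebb_logpmf(m, n, nat) == pytest.approx(math.log(pmf[m]), rel=1e-9)
        # far-tail log-pmf stays finite even where the pmf underflows
        assert np.isfinite(ebb_logpmf(1, n, nat))
        assert ebb_logpmf(1, n, nat) < -1e5


class TestGradient:
    @pytest.mark.parametrize(
        "m, n, ai, q",
        [(3, 10, 0.6, 2.0), (5, 10, 0.5, 1.5), (7, 10, 0.5, 1.0), (0, 25, 0.2, 3.0)],
    )
    def test_matches_central_finite_differences(self, m, n, ai, q):
        h = 1e-6 * q
        fd = (
            ebb_logpmf(m, n, shape_to_natural(EBBShape(ai, q + h, n)))
            - ebb_logpmf(m, n, shape_to_natural(EBBShape(ai, q - h, n)))
        ) / (2 * h)
        assert ebb_dlogpmf_dq(m, EBBShape(ai, q, n)) == pytest.approx(fd, rel=1e-5)

    def test_randomised_against_finite_differences(self, rng):
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 300))
            m = int(rng.integers(0, n + 1))
            ai = float(rng.uniform(0.05, 0.95))
            q = float(rng.uniform(0.8, min(n * 0.8, 20.0)))
            shape = EBBShape(ai, q, n)
            try:
                grad = ebb_dlogpmf_dq(m, shape)
            except EBBInvalidParameters:
                continue
            h = 1e-6 * q
            fd = (
                ebb_logpmf(m, n, shape_to_natural(EBBShape(ai, q + h, n)))
                - ebb_logpmf(m, n, shape_to_natural(EBBShape(ai, q - h, n)))
            ) / (2 * h)
            assert grad == pytest.approx(fd, rel=1e-4, abs=1e-8)
            checked += 1

    def test_finite_at_binomial_point(self):
        # the family is smooth through q = 1
        assert np.isfinite(ebb_dlogpmf_dq(4, EBBShape(0.4, 1.0, 12)))


class TestVariance:
    def test_closed_form_values(self):
        assert ebb_variance(EBBShape(0.5, 1, 100)) == pytest.approx(25.0)
        assert ebb_variance(EBBShape(0.5, 100, 100)) == pytest.approx(2500.0)
        assert ebb_variance(EBBShape(0.3, 2, 50)) == pytest.approx(21.0)

    def test_monotone_in_q(self):
        qs = np.linspace(0.5, 40, 30)
        vs = [ebb_variance(EBBShape(0.3, q, 50)) for q in qs]
        assert np.all(np.diff(vs) > 0)

    def test_natural_form_variance_identity(self):
        # (a+b+n)/(a+b+1) * n*a*b/(a+b)^2 at d=1 equals q*n*ai*(1-ai)
        a, b, n = 2.0, 3.0, 40
        q = (a + b + n) / (a + b + 1)
        ai = a / (a + b)
        assert ebb_variance(EBBShape(ai, q, n)) == pytest.approx(
            (a + b + n) / (a + b + 1) * n * a * b / (a + b) ** 2
        )

    def test_sample_variance_matches(self, rng):
        shape = EBBShape(0.3, 2, 50)
        draws = ebb_sample(shape, 100_000, rng)
        var = draws.var()
        se = math.sqrt(2.0 / len(draws)) * ebb_variance(shape)  # rough normal SE
        assert abs(var - 21.0) < 3 * max(se, 0.5)


class TestSampler:
    def test_reproducible(self):
        a = ebb_sample(EBBShape(0.4, 3, 30), 100, np.random.default_rng(5))
        b = ebb_sample(EBBShape(0.4, 3, 30), 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_binomial_goodness_of_fit(self, rng):
        draws = ebb_sample(EBBShape(0.5, 1, 20), 100_000, rng)
        observed = np.bincount(draws, minlength=21)
        expected = stats.binom.pmf(np.arange(21), 20, 0.5) * len(draws)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01

    def test_hypergeometric_goodness_of_fit(self, rng):
        # alpha=beta=5, d=-1, n=5 <-> drawing without replacement from 10 balls
        q = (5 + 5 + 5 * -1) / (5 + 5 + -1)  # variance ratio of HG(10,5,5)
        shape = EBBShape(0.5, q, 5)
        draws = ebb_sample(shape, 100_000, rng)
        observed = np.bincount(draws, minlength=6)
        expected = stats.hypergeom.pmf(np.arange(6), 10, 5, 5) * len(draws)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01

    def test_overdispersed_sample_variance(self, rng):
        shape = EBBShape(0.3, 4, 100)
        draws = ebb_sample(shape, 100_000, rng)
        target = ebb_variance(shape)  # 84
        se = math.sqrt(2.0 / len(draws)) * target
        assert abs(draws.var() - target) < 3 * max(se, 1.0)

    def test_two_point_limit_sampling(self, rng):
        draws = ebb_sample(EBBShape(0.3, 10, 10), 20_000, rng)
        assert set(np.unique(draws)) <= {0, 10}
        assert abs((draws == 10).mean() - 0.3) < 0.01


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 80),
    ai=st.floats(0.05, 0.95),
    q=st.floats(1.0, 10.0),
)
def test_property_normalization_and_mirror(n, ai, q):
    """Any overdispersed shape yields a normalised, mirror-symmetric pmf."""
    q = min(q, n * 0.9)
    pmf = ebb_pmf_vector(EBBShape(ai, q, n))
    mirrored = ebb_pmf_vector(EBBShape(1 - ai, q, n))
    assert abs(pmf.sum() - 1) < 1e-10
    np.testing.assert_allclose(pmf, mirrored[::-1], rtol=1e-9, atol=1e-14)


def test_allelic_count_basics():
    c = AllelicCount(3, 7)
    assert (c.n, c.ai_hat) == (10, 0.3)
    with pytest.raises(ValueError):
        AllelicCount(-1, 2)
    assert math.isnan(AllelicCount(0, 0).ai_hat)
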