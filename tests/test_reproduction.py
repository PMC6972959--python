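"""Unit and property tests for the overdispersed reproduction model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibsize import (
    PHI_POISSON,
    LambdaDistribution,
    drift_based_ne,
    effective_mother_size,
    mhs_probability,
    nb_offspring_pmf,
    ne_census_ratio,
    overdispersion_c,
)


class TestOffspringPmf:
    @pytest.mark.parametrize(
        "k, lam, phi, expected",
        [
            (0, 1.0, 1.0, 0.5),  # geometric: (phi/(phi+lam))^phi
            (2, 1.0, 1.0, 0.125),  # geometric: (1/2)^2 * (1/2)
            (3, 2.0, PHI_POISSON, math.exp(-2) * 8 / 6),  # Poisson limit
        ],
    )
    def test_known_values(self, k, lam, phi, expected):
        assert nb_offspring_pmf(k, lam, phi) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 4.5])
    @pytest.mark.parametrize("phi", [0.1302, 1.0, 10.0, PHI_POISSON])
    def test_normalization_and_moments(self, lam, phi):
        k = np.arange(0, 4000)
        pmf = nb_offspring_pmf(k, lam, phi)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        mean = (k * pmf).sum()
        var = (k**2 * pmf).sum() - mean**2
        assert mean == pytest.approx(lam, rel=1e-8)
        expected_var = lam if math.isinf(phi) else lam + lam**2 / phi
        assert var == pytest.approx(expected_var, rel=1e-7)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 4.5])
    def test_poisson_limit_of_large_phi(self, lam):
        k = np.arange(0, 60)
        nb = nb_offspring_pmf(k, lam, 1e8)
        pois = nb_offspring_pmf(k, lam, PHI_POISSON)
        assert np.max(np.abs(nb - pois)) < 1e-6

    def test_zero_potential_is_point_mass_at_zero(self):
        assert nb_offspring_pmf(0, 0.0, 1.0) == 1.0
        assert nb_offspring_pmf(3, 0.0, 1.0) == 0.0

    def test_monte_carlo_moments(self, rng):
        lam, phi, m = 4.5, 0.1302, 200_000
        draws = rng.negative_binomial(phi, phi / (phi + lam), size=m)
        se_mean = math.sqrt((lam + lam**2 / phi) / m)
        assert abs(draws.mean() - lam) < 3 * se_mean

    @pytest.mark.parametrize("k, lam, phi", [(-1, 1, 1), (0, -1, 1), (0, 1, 0), (0, 1, -2)])
    def test_domain_errors(self, k, lam, phi):
        with pytest.raises(ValueError):
            nb_offspring_pmf(k, lam, phi)


class TestOverdispersion:
    def test_printed_calibration_pair(self):
        # the two regimes used throughout: c = 10 and c = 1
        assert overdispersion_c(0.1302, 1.1519) == pytest.approx(10.0, abs=1e-3)
        assert round(overdispersion_c(1000.0, 1.0000)) == 1

    @pytest.mark.parametrize(
        "phi, ratio, expected",
        [(PHI_POISSON, 1.0, 1.0), (1.0, 1.0, 2.0)],
    )
    def test_simple_values(self, phi, ratio, expected):
        assert overdispersion_c(phi, ratio) == pytest.approx(expected)

    def test_impossible_moment_ratio(self):
        with pytest.raises(ValueError):
            overdispersion_c(1.0, 0.9)


class TestSibshipProbability:
    @pytest.mark.parametrize(
        "N, c, pi",
        [(100, 1.0, 0.01), (100, 10.0, 10 / 109), (2, 1.0, 0.5)],
    )
    def test_values(self, N, c, pi):
        assert mhs_probability(N, c) == pytest.approx(pi, rel=1e-12)

    @given(
        N=st.integers(min_value=2, max_value=10**6),
        c=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_reciprocal_relation_and_bounds(self, N, c):
        pi = mhs_probability(N, c)
        ne = effective_mother_size(N, c)
        assert 0 < pi <= 1
        assert ne == pytest.approx(1.0 / pi, rel=1e-12)
        assert ne <= N + 1e-9

    def test_monotone_in_c_and_N(self):
        cs = np.linspace(1, 50, 25)
        pis = [mhs_probability(500, c) for c in cs]
        assert np.all(np.diff(pis) > 0)
        Ns = np.arange(2, 400)
        pis_n = [mhs_probability(int(N), 3.0) for N in Ns]
        assert np.all(np.diff(pis_n) < 0)
        nes = [effective_mother_size(500, c) for c in cs]
        assert np.all(np.diff(nes) < 0)

    @pytest.mark.parametrize(
        "N, c, ne",
        [(100, 1.0, 100.0), (991, 10.0, 100.0), (10000, 10.0, 1000.9)],
    )
    def test_effective_size_values(self, N, c, ne):
        assert effective_mother_size(N, c) == pytest.approx(ne, rel=1e-12)

    def test_pooled_pair_fraction_matches_theory(self, rng, skewed_lambda):
        # Monte-Carlo cohorts: fraction of same-mother pairs vs c/(N+c-1)
        N, phi, reps = 100, 0.1302, 20_000
        lam = skewed_lambda.draw(N * reps, rng).reshape(reps, N)
        k = np.zeros_like(lam, dtype=np.int64)
        pos = lam > 0
        k[pos] = rng.negative_binomial(phi, phi / (phi + lam[pos]))
        h = (k * (k - 1) // 2).sum(axis=1).astype(float)
        K = k.sum(axis=1)
        pairs = (K * (K - 1) // 2).astype(float)
        ratio = h.sum() / pairs.sum()
        c = (1 + 1 / phi) * skewed_lambda.moment_ratio
        pi = mhs_probability(N, c)
        resid = h - ratio * pairs
        se = math.sqrt(resid.var(ddof=1) / reps) / pairs.mean()
        assert abs(ratio - pi) < 3 * se


class TestDriftAndCensus:
    @pytest.mark.parametrize(
        "N, lam, phi, expected",
        [
            (100, 1.0, PHI_POISSON, 100.0),
            (100, 2.0, 1.0, 100 / 1.5),
            (100, 1.0, 1.0, 50.0),
        ],
    )
    def test_drift_based(self, N, lam, phi, expected):
        assert drift_based_ne(N, lam, phi) == pytest.approx(expected, rel=1e-12)

    def test_drift_based_matches_sibship_definition_only_at_unit_lambda(self):
        # at lambda = 1 the two definitions agree asymptotically in N
        phi = 2.0
        c = 1 + 1 / phi
        assert drift_based_ne(10_000, 1.0, phi) == pytest.approx(
            effective_mother_size(10_000, c), rel=1e-3
        )
        assert drift_based_ne(10_000, 4.5, phi) != pytest.approx(
            effective_mother_size(10_000, c), rel=0.05
        )

    def test_census_ratio(self):
        r = ne_census_ratio(100, 10.0)
        assert r.exact == pytest.approx(0.109, rel=1e-12)
        assert r.approx == pytest.approx(0.1)
        assert ne_census_ratio(100, 1.0).exact == 1.0
        assert ne_census_ratio(10**7, 10.0).exact == pytest.approx(0.1, abs=1e-6)


class TestLambdaDistribution:
    def test_moment_ratio_bounds(self):
        d = LambdaDistribution([1.0, 3.0], [0.5, 0.5])
        assert d.moment_ratio == pytest.approx((0.5 * 1 + 0.5 * 9) / 4.0)
        assert d.moment_ratio >= 1
        assert LambdaDistribution.constant(4.5).moment_ratio == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            LambdaDistribution([1.0, 2.0], [0.6, 0.6])
        with pytest.raises(ValueError):
            LambdaDistribution([-1.0], [1.0])
        with pytest.raises(ValueError):
            LambdaDistribution([0.0], [1.0])  # mean must be positive

    @given(
        vals=st.lists(
            st.floats(min_value=0.1, max_value=50.0), min_size=1, max_size=8
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_cauchy_schwarz(self, vals):
        w = np.full(len(vals), 1.0 / len(vals))
        d = LambdaDistribution(vals, w / w.sum())
        assert d.moment_ratio >= 1.0 - 1e-12
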