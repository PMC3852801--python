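"""Geometric / truncated-Zipf fitting and Pearson chi-square comparison.

The MLE routines are checked against brute-force likelihood grids, and the
chi-square statistic against straightforward re-summation — oracles that
share no code with the fitting path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyroerr.gapfit import (
    SIGMA_MAX,
    GapLengthSample,
    GeometricParams,
    ZipfParams,
    chi_square,
    compare_models,
    fit_geometric,
    fit_zipf,
    geometric_pmf,
    zipf_pmf,
)


# ---------------------------------------------------------------------------
# oracles


def geometric_loglik(beta, lengths):
    if beta == 0.0:
        return 0.0 if all(x == 1 for x in lengths) else -math.inf
    if beta == 1.0:
        return -math.inf
    return sum((x - 1) * math.log(beta) + math.log(1 - beta) for x in lengths)


def grid_fit_geometric(lengths, step=1e-4):
    grid = np.arange(0.0, 1.0, step)
    logliks = [geometric_loglik(b, lengths) for b in grid]
    return float(grid[int(np.argmax(logliks))])


def zipf_loglik(sigma, lengths, L):
    norm = sum(j ** -sigma for j in range(1, L + 1))
    return sum(-sigma * math.log(x) - math.log(norm) for x in lengths)


def grid_fit_zipf(lengths, L, step=1e-3):
    grid = np.arange(step, SIGMA_MAX + step, step)
    logliks = [zipf_loglik(s, lengths, L) for s in grid]
    return float(grid[int(np.argmax(logliks))])


def chi_square_by_summation(observed, expected):
    total = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            total += (o - e) ** 2 / e
    return total


def draw_zipf(rng, sigma, L, n):
    k = np.arange(1, L + 1)
    pmf = k ** -float(sigma)
    pmf /= pmf.sum()
    return rng.choice(k, size=n, p=pmf)


# ---------------------------------------------------------------------------


class TestPmfs:
    def test_geometric_point_mass_at_one(self):
        assert geometric_pmf(1, 0.0) == 1.0

    def test_geometric_simple_value(self):
        assert geometric_pmf(2, 0.5) == pytest.approx(0.25)

    def test_geometric_normalizes(self):
        total = sum(geometric_pmf(k, 0.9) for k in range(1, 201))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_geometric_domain(self):
        with pytest.raises(ValueError):
            geometric_pmf(0, 0.5)

    def test_zipf_L2_sigma1(self):
        params = ZipfParams(sigma=1.0, L=2)
        assert zipf_pmf(1, params) == pytest.approx(2 / 3)
        assert zipf_pmf(2, params) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("sigma,L", [(0.5, 3), (1.6, 10), (3.0, 25)])
    def test_zipf_normalizes(self, sigma, L):
        params = ZipfParams(sigma=sigma, L=L)
        assert sum(zipf_pmf(k, params) for k in range(1, L + 1)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_zipf_large_sigma_is_point_mass(self):
        assert zipf_pmf(1, ZipfParams(sigma=SIGMA_MAX, L=10)) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_zipf_domain(self):
        with pytest.raises(ValueError):
            zipf_pmf(3, ZipfParams(sigma=1.0, L=2))


class TestFitGeometric:
    def test_all_ones_boundary(self):
        fit = fit_geometric([1, 1, 1, 1])
        assert fit.params.beta == 0.0
        assert fit.log_likelihood == 0.0

    @pytest.mark.parametrize("lengths", [(2, 2, 2), (1, 3)])
    def test_closed_form_mean_two(self, lengths):
        fit = fit_geometric(lengths)
        assert fit.params.beta == pytest.approx(0.5)
        assert fit.params.beta == pytest.approx(grid_fit_geometric(lengths), abs=1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_geometric([])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=12), min_size=1, max_size=50))
    def test_matches_grid_oracle(self, lengths):
        fit = fit_geometric(lengths)
        assert fit.params.beta == pytest.approx(grid_fit_geometric(lengths), abs=1e-3)


class TestFitZipf:
    def test_analytic_stationary_point(self):
        # stationarity of (1,1,1,2) with L=2: 3 * 2^-sigma = 1, sigma = ln3/ln2
        fit = fit_zipf([1, 1, 1, 2], L=2)
        assert fit.params.sigma == pytest.approx(math.log(3) / math.log(2), abs=1e-4)

    def test_all_ones_hits_sigma_max_boundary(self):
        fit = fit_zipf([1, 1, 1])
        assert fit.params.sigma == SIGMA_MAX
        assert not fit.converged

    def test_default_L_is_max_length(self):
        assert fit_zipf([1, 2, 5]).params.L == 5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_zipf([])

    def test_parameter_recovery(self, rng):
        lengths = draw_zipf(rng, sigma=1.6, L=10, n=10_000)
        fit = fit_zipf(lengths)
        assert abs(fit.params.sigma - 1.6) < 0.05

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=10), min_size=2, max_size=40).filter(
            lambda xs: any(x > 1 for x in xs)
        )
    )
    def test_matches_grid_oracle(self, lengths):
        fit = fit_zipf(lengths)
        oracle = grid_fit_zipf(lengths, L=max(lengths))
        assert fit.params.sigma == pytest.approx(oracle, abs=5e-3)


class TestChiSquare:
    def test_zero_when_observed_equals_expected(self):
        # 3 ones and 1 two has beta_hat = 1/4... use an exactly-matching case:
        # beta = 0.5 over lengths {1,2}: E = (2, 1) for N = 4? E1=2, E2=1 and
        # the remaining mass is beyond L; choose observed equal to E on bins.
        sample = GapLengthSample((1, 1, 2))
        result = chi_square(sample, GeometricParams(1 / 3))
        # E1 = 3 * 2/3 = 2 = O1, E2 = 3 * (1/3)(2/3) = 2/3 != O2; not zero.
        # The genuinely exact case is the degenerate all-ones sample:
        exact = chi_square(GapLengthSample((1, 1, 1)), GeometricParams(0.0))
        assert exact.statistic == 0.0
        assert result.statistic > 0.0

    def test_hand_arithmetic_example(self):
        # O = (8, 2); geometric MLE beta = 1/6: E = (8.3333, 1.3889)
        sample = GapLengthSample((1,) * 8 + (2,) * 2)
        fit = fit_geometric(sample)
        assert fit.params.beta == pytest.approx(1 / 6)
        result = chi_square(sample, fit.params)
        assert result.expected == pytest.approx([25 / 3, 25 / 18], abs=1e-4)
        assert result.statistic == pytest.approx(0.28222, abs=1e-4)

    def test_statistic_matches_summation_oracle(self, rng):
        lengths = tuple(int(x) for x in rng.geometric(0.6, size=500))
        sample = GapLengthSample(lengths)
        fit = fit_geometric(sample)
        result = chi_square(sample, fit.params)
        assert result.statistic == pytest.approx(
            chi_square_by_summation(result.observed, result.expected)
        )

    def test_pooling_merges_to_min_expected_five(self, rng):
        lengths = tuple(int(x) for x in rng.geometric(0.7, size=300))
        sample = GapLengthSample(lengths)
        fit = fit_geometric(sample)
        pooled = chi_square(sample, fit.params, pool_small=True)
        assert (pooled.expected >= 5.0).all()
        assert pooled.statistic == pytest.approx(
            chi_square_by_summation(pooled.observed, pooled.expected)
        )
        assert pooled.df <= chi_square(sample, fit.params).df

    def test_permutation_invariance(self, rng):
        lengths = [1, 5, 2, 2, 3, 1, 1, 4]
        sample_a = GapLengthSample(tuple(lengths))
        sample_b = GapLengthSample(tuple(reversed(lengths)))
        fit = fit_geometric(sample_a)
        assert chi_square(sample_a, fit.params).statistic == pytest.approx(
            chi_square(sample_b, fit.params).statistic
        )


class TestCompareModels:
    def test_zipf_data_prefers_zipf(self, rng):
        lengths = draw_zipf(rng, sigma=1.6, L=10, n=10_000)
        table = compare_models({"any": GapLengthSample(tuple(int(x) for x in lengths))})
        row = table.loc["*"]
        assert row["chi2_zipf"] < row["chi2_geom"]

    def test_single_context_adds_pooled_row(self):
        table = compare_models({("A", 2): GapLengthSample((1, 1, 2, 3))})
        assert list(table.index) == [("A", 2), "*"]
        assert (table["low_n"] == [True, True]).all()

    def test_geometric_data_fits_geometric(self, rng):
        lengths = tuple(int(x) for x in rng.geometric(1 - 0.3, size=10_000))
        table = compare_models({"any": GapLengthSample(lengths)})
        row = table.loc["*"]
        assert abs(row["beta_hat"] - 0.3) < 0.02
        # the statistic should sit inside its own simulated null distribution
        null_rng = np.random.default_rng(777)
        null_stats = []
        for _ in range(100):
            draws = GapLengthSample(
                tuple(int(x) for x in null_rng.geometric(1 - 0.3, size=10_000))
            )
            null_stats.append(chi_square(draws, fit_geometric(draws).params).statistic)
        assert row["chi2_geom"] <= np.percentile(null_stats, 99)
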