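"""Gap-length distribution models: geometric vs. truncated Zipf.

The geometric law P(X=k) = beta^(k-1)(1-beta) over k = 1, 2, ... is the
distributional twin of the affine gap penalty used by most read aligners:
every additional gap position contributes an equal factor beta.  The
truncated Zipf (power) law P(X=k) = C k^(-sigma) over k = 1..L corresponds to
a convex, logarithmic penalty.  Both are fitted by maximum likelihood —
geometric in closed form (beta_hat = (mean-1)/mean), Zipf by bounded
one-dimensional search on sigma — and compared through Pearson's chi-square
statistic  sum_k (O_k - E_k)^2 / E_k  with E_k = N * pmf(k) for k = 1..L,
where L is the maximum observed gap length.  The truncated geometric
expectations are deliberately *not* renormalized over 1..L, so their sum
falls slightly short of N; the statistic is a plain sum of squared residuals,
the smaller the better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SIGMA_MAX",
    "GapLengthSample",
    "GeometricParams",
    "ZipfParams",
    "FitResult",
    "ChiSquareResult",
    "geometric_pmf",
    "zipf_pmf",
    "fit_geometric",
    "fit_zipf",
    "chi_square",
    "compare_models",
]

#: Beyond this shape the truncated Zipf is numerically a point mass at 1.
SIGMA_MAX = 20.0


@dataclass(frozen=True)
class GapLengthSample:
    """A vector of positive integer gap lengths, optionally tagged by context."""

    lengths: tuple[int, ...]
    context_key: object = "any"

    def __post_init__(self) -> None:
        lengths = tuple(int(x) for x in self.lengths)
        if any(x < 1 for x in lengths):
            raise ValueError("gap lengths must be >= 1")
        object.__setattr__(self, "lengths", lengths)

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def max_length(self) -> int:
        return max(self.lengths)


@dataclass(frozen=True)
class GeometricParams:
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")


@dataclass(frozen=True)
class ZipfParams:
    sigma: float
    L: int

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= SIGMA_MAX):
            raise ValueError(f"sigma must be in (0, {SIGMA_MAX}]")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: Union[GeometricParams, ZipfParams]
    log_likelihood: float
    converged: bool = True


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray = field(compare=False, default=None)
    expected: np.ndarray = field(compare=False, default=None)


# ---------------------------------------------------------------------------
# pmfs


def geometric_pmf(k, beta: float):
    """P(X=k) = beta^(k-1) (1-beta) for k >= 1."""
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("geometric support is k >= 1")
    if beta == 1.0:  # degenerate: all mass escapes to infinity
        return np.zeros_like(k, dtype=float) if k.ndim else 0.0
    out = stats.geom.pmf(k, 1.0 - beta)
    return float(out) if np.ndim(out) == 0 else out


def zipf_pmf(k, params: ZipfParams):
    """P(X=k) = k^(-sigma) / sum_{j<=L} j^(-sigma) for 1 <= k <= L."""
    k = np.asarray(k)
    if np.any((k < 1) | (k > params.L)):
        raise ValueError(f"truncated Zipf support is 1 <= k <= L={params.L}")
    out = stats.zipfian.pmf(k, params.sigma, params.L)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# maximum likelihood


def _as_sample(sample) -> GapLengthSample:
    if isinstance(sample, GapLengthSample):
        return sample
    return GapLengthSample(tuple(sample))


def fit_geometric(sample) -> FitResult:
    """Closed-form MLE: beta_hat = (mean - 1) / mean.

    Log-likelihood is evaluated in the log domain; a sample of all ones sits
    on the boundary beta = 0 (point mass at 1).
    """
    sample = _as_sample(sample)
    if sample.n == 0:
        raise ValueError("cannot fit an empty sample")
    x = np.asarray(sample.lengths, dtype=float)
    mean = x.mean()
    beta = (mean - 1.0) / mean
    if beta <= 0.0:
        loglik = 0.0  # point mass at 1: every pmf value is 1
        beta = 0.0
    else:
        loglik = float(np.sum(stats.geom.logpmf(x, 1.0 - beta)))
    return FitResult(GeometricParams(beta), loglik, converged=True)


def _zipf_negloglik(sigma: float, sum_log_x: float, n: int, L: int) -> float:
    # -loglik = sigma * sum(log x_i) + n * log(sum_{j<=L} j^-sigma)
    j = np.arange(1, L + 1, dtype=float)
    # log-sum-exp of (-sigma * log j) for numerical safety at large sigma
    a = -sigma * np.log(j)
    m = a.max()
    log_norm = m + math.log(np.exp(a - m).sum())
    return sigma * sum_log_x + n * log_norm


def fit_zipf(sample, L: int | None = None) -> FitResult:
    """MLE of the truncated-Zipf shape by bounded scalar minimization.

    ``L`` defaults to the maximum observed gap length.  The likelihood
    depends on the data only through ``sum(log x_i)``, so the search is cheap
    at any sample size.  A sample of all ones has a likelihood increasing in
    sigma; the estimate is then reported at ``SIGMA_MAX`` with the converged
    flag lowered to mark the boundary.
    """
    sample = _as_sample(sample)
    if sample.n == 0:
        raise ValueError("cannot fit an empty sample")
    if L is None:
        L = sample.max_length
    elif L < sample.max_length:
        raise ValueError(f"L={L} below the maximum observed length {sample.max_length}")
    x = np.asarray(sample.lengths, dtype=float)
    sum_log_x = float(np.log(x).sum())

    if sum_log_x == 0.0 or L == 1:
        # all-ones sample: likelihood is increasing in sigma (boundary MLE)
        sigma = SIGMA_MAX
        loglik = -_zipf_negloglik(sigma, sum_log_x, sample.n, L)
        return FitResult(ZipfParams(sigma, L), loglik, converged=False)

    res = optimize.minimize_scalar(
        _zipf_negloglik,
        bounds=(1e-6, SIGMA_MAX),
        args=(sum_log_x, sample.n, L),
        method="bounded",
        options={"xatol": 1e-8},
    )
    sigma = float(np.clip(res.x, 1e-6, SIGMA_MAX))
    return FitResult(ZipfParams(sigma, L), -float(res.fun), converged=bool(res.success))


# ---------------------------------------------------------------------------
# goodness of fit


def chi_square(
    sample,
    model: Union[GeometricParams, ZipfParams],
    pool_small: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square of a fitted gap-length model over bins k = 1..L.

    ``E_k = N * pmf(k)``; for the geometric model the truncated expectations
    are not renormalized, so ``sum(E) < N`` slightly.  ``df = bins - 2`` (one
    parameter estimated).  With ``pool_small`` adjacent bins are merged left
    to right until each pooled expectation reaches 5 (the classical validity
    rule); the default leaves the raw one-bin-per-length statistic.
    """
    sample = _as_sample(sample)
    if sample.n == 0:
        raise ValueError("empty sample")
    L = sample.max_length
    k = np.arange(1, L + 1)
    observed = np.bincount(sample.lengths, minlength=L + 1)[1:].astype(float)
    if isinstance(model, GeometricParams):
        expected = sample.n * np.asarray(geometric_pmf(k, model.beta), dtype=float)
    else:
        if model.L < L:
            raise ValueError("model truncation below the observed maximum length")
        expected = sample.n * stats.zipfian.pmf(k, model.sigma, model.L)

    if pool_small:
        observed, expected = _pool_bins(observed, expected, min_expected=5.0)

    mask = expected > 0
    if not mask.any():
        raise ValueError("all expected counts are zero")
    statistic = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    n_bins = int(mask.sum())
    df = n_bins - 2
    p_value = float(stats.chi2.sf(statistic, df)) if df >= 1 else float("nan")
    return ChiSquareResult(statistic, df, p_value, observed=observed, expected=expected)


def _pool_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float):
    """Merge adjacent bins left to right until every pooled E >= min_expected."""
    obs_out: list[float] = []
    exp_out: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:  # fold a short tail into the last bin
        if obs_out:
            obs_out[-1] += acc_o
            exp_out[-1] += acc_e
        else:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
    return np.asarray(obs_out), np.asarray(exp_out)


# ---------------------------------------------------------------------------
# per-context model comparison


def compare_models(
    samples: Mapping[object, Union[GapLengthSample, Sequence[int]]],
    pool_small: bool = False,
    min_n: int = 8,
) -> pd.DataFrame:
    """Fit both models per context plus pooled over all contexts.

    Returns one row per context key and a final ``*`` row for the pooled
    sample, with columns ``n, beta_hat, sigma_hat, L, loglik_geom,
    loglik_zipf, chi2_geom, chi2_zipf, p_geom, p_zipf, low_n`` — contexts
    with fewer than ``min_n`` gaps are flagged, never dropped.
    """
    rows = []
    pooled: list[int] = []
    for key, sample in samples.items():
        sample = _as_sample(sample)
        if sample.n == 0:
            raise ValueError(f"context {key!r}: empty sample")
        pooled.extend(sample.lengths)
        rows.append((key, sample))
    if not rows:
        raise ValueError("no samples given")
    rows.append(("*", GapLengthSample(tuple(pooled), context_key="*")))

    out = []
    for key, sample in rows:
        geo = fit_geometric(sample)
        zpf = fit_zipf(sample)
        c_geo = chi_square(sample, geo.params, pool_small=pool_small)
        c_zpf = chi_square(sample, zpf.params, pool_small=pool_small)
        out.append(
            {
                "context": key,
                "n": sample.n,
                "beta_hat": geo.params.beta,
                "sigma_hat": zpf.params.sigma,
                "L": zpf.params.L,
                "loglik_geom": geo.log_likelihood,
                "loglik_zipf": zpf.log_likelihood,
                "chi2_geom": c_geo.statistic,
                "chi2_zipf": c_zpf.statistic,
                "p_geom": c_geo.p_value,
                "p_zipf": c_zpf.p_value,
                "low_n": sample.n < min_n,
            }
        )
    return pd.DataFrame(out).set_index("context")
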