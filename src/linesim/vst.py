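"""Blind variance-stabilizing transformation for negative-binomial counts.

The transform assumes counts K_ij with mean mu_ij and variance
mu + alpha(mu) * mu^2, where the dispersion follows the parametric trend
alpha(mu) = a0 + a1 / mu (a0: asymptotic dispersion at high expression,
a1: extra-Poisson spread dominating at low expression).  The pipeline is

1. median-of-ratios size factors against the per-gene geometric mean,
2. per-gene method-of-moments dispersion estimates on normalized counts,
3. gamma-family identity-link regression of dispersion on 1/mean with
   iterative outlier exclusion, yielding (a0, a1),
4. a closed-form monotone transform of normalized counts whose derivative
   is 1/sqrt(v(q)) with v(q) = q*(1 + a1) + a0*q^2, rescaled so that
   vst(q) approaches log2(q) + const for large q.

"Blind" means no design information is used anywhere: dispersions come
from intercept-only moments, never per-condition fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

DISPERSION_FLOOR = 1e-8
#: genes whose dispersion/trend ratio leaves this band are dropped and the fit repeated
OUTLIER_RATIO_BAND = (1e-4, 15.0)
MAX_TREND_ITERATIONS = 20
TREND_RTOL = 1e-6


@dataclass(frozen=True)
class DispersionTrend:
    """Coefficients of the parametric mean-dispersion trend alpha(mu) = a0 + a1/mu."""

    asymptotic_dispersion: float  # a0, dimensionless
    extra_poisson: float  # a1, dimensionless
    n_iterations: int = 0
    n_genes_used: int = 0

    def __post_init__(self):
        if not self.asymptotic_dispersion > 0:
            raise ValidationError("asymptotic dispersion a0 must be > 0")
        if self.extra_poisson < 0:
            raise ValidationError("extra-Poisson term a1 must be >= 0")

    def __call__(self, mu: np.ndarray | float) -> np.ndarray | float:
        return self.asymptotic_dispersion + self.extra_poisson / np.asarray(mu, dtype=float)


class TrendFitError(ValidationError):
    """Parametric trend fit failed; carries the last coefficients seen."""

    def __init__(self, message: str, last_coefficients=None):
        self.last_coefficients = last_coefficients
        super().__init__(message)


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the per-gene geometric mean.

    Only genes whose geometric mean across samples is strictly positive
    (i.e. no zero counts) are eligible.
    """
    values = np.asarray(matrix, dtype=float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    log_geomeans = log_values.mean(axis=1)
    eligible = np.isfinite(log_geomeans)
    if not eligible.any():
        raise ValidationError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios size factors are undefined "
            "(pseudo-reference fallback is disabled)"
        )
    geomeans = np.exp(log_geomeans[eligible])
    factors = np.median(values[eligible] / geomeans[:, None], axis=0)
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def genewise_dispersions(matrix: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Method-of-moments dispersion per gene on normalized counts.

    For gene i with normalized counts z_ij = K_ij / s_j, mean m_i and sample
    variance s2_i, the estimate is (s2_i - m_i * xi) / m_i^2 with
    xi = mean_j(1/s_j), floored at 1e-8.  Genes with zero mean are NaN.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("dispersion estimation needs at least 2 samples")
    s = factors.loc[matrix.columns].to_numpy(dtype=float)
    z = np.asarray(matrix, dtype=float) / s
    m = z.mean(axis=1)
    s2 = z.var(axis=1, ddof=1)
    xi = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m * xi) / m**2
    alpha = np.where(m > 0, np.maximum(alpha, DISPERSION_FLOOR), np.nan)
    return pd.Series(alpha, index=matrix.index, name="dispersion")


def _gamma_identity_fit(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One gamma-GLM fit of y on [1, x] with identity link; returns (a0, a1)."""
    exog = np.column_stack([np.ones_like(x), x])
    # start from a positive least-squares guess so identity-link IRLS stays feasible
    start, *_ = np.linalg.lstsq(exog, y, rcond=None)
    start = np.maximum(start, [1e-8, 0.0])
    if not np.all(exog @ start > 0):
        start = np.array([max(np.median(y), 1e-8), 0.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=sm.families.Gamma(link=sm.families.links.Identity()))
        result = model.fit(start_params=start, maxiter=100)
    return np.asarray(result.params, dtype=float)


def fit_parametric_trend(means: np.ndarray, dispersions: np.ndarray) -> DispersionTrend:
    """Fit alpha = a0 + a1/mu by gamma regression with iterative outlier exclusion.

    After each fit, genes whose ratio of observed to fitted dispersion falls
    outside ``OUTLIER_RATIO_BAND`` are excluded and the fit repeated, until
    the coefficients change by less than 1e-6 relative or 20 iterations pass.
    """
    means = np.asarray(means, dtype=float)
    dispersions = np.asarray(dispersions, dtype=float)
    usable = np.isfinite(means) & np.isfinite(dispersions) & (means > 0) & (dispersions > 0)
    if usable.sum() < 10:
        raise TrendFitError(f"only {int(usable.sum())} usable genes; need at least 10")
    mu = means[usable]
    disp = dispersions[usable]
    coeffs = np.array([0.1, 1.0])  # prior trend seeding the first outlier screen
    lo, hi = OUTLIER_RATIO_BAND
    for iteration in range(1, MAX_TREND_ITERATIONS + 1):
        fitted = coeffs[0] + coeffs[1] / mu
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = disp / fitted
        keep = (ratio >= lo) & (ratio <= hi) & (fitted > 0)
        if keep.sum() < 10:
            raise TrendFitError(
                f"only {int(keep.sum())} genes left after outlier exclusion; need at least 10",
                last_coefficients=coeffs,
            )
        new = _gamma_identity_fit(disp[keep], 1.0 / mu[keep])
        converged = iteration > 1 and np.all(
            np.abs(new - coeffs) <= TREND_RTOL * np.maximum(np.abs(coeffs), 1e-12)
        )
        coeffs = new
        if converged:
            a0 = max(float(coeffs[0]), 1e-8)
            a1 = max(float(coeffs[1]), 0.0)
            return DispersionTrend(a0, a1, n_iterations=iteration, n_genes_used=int(keep.sum()))
    raise TrendFitError(
        f"parametric trend did not converge in {MAX_TREND_ITERATIONS} iterations",
        last_coefficients=coeffs,
    )


def vst_transform(
    matrix: pd.DataFrame, factors: pd.Series, trend: DispersionTrend
) -> pd.DataFrame:
    """Apply the closed-form variance-stabilizing transform to normalized counts.

    For q = count/size_factor,

        vst(q) = log2( (1 + a1 + 2*a0*q + 2*sqrt(a0*q*(1 + a1 + a0*q))) / (4*a0) )

    the antiderivative of 1/sqrt(v(q)) with v(q) = q*(1+a1) + a0*q^2, scaled
    to approach log2(q) + constant for large q.  Strictly increasing in q
    and defined at q = 0.
    """
    a0 = trend.asymptotic_dispersion
    a1 = trend.extra_poisson
    if a0 <= 0:
        raise ValidationError("a0 must be positive")
    s = factors.loc[matrix.columns].to_numpy(dtype=float)
    q = np.asarray(matrix, dtype=float) / s
    if (q < 0).any():
        raise ValidationError("normalized counts must be non-negative")
    out = np.log2((1 + a1 + 2 * a0 * q + 2 * np.sqrt(a0 * q * (1 + a1 + a0 * q))) / (4 * a0))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def blind_vst(matrix: pd.DataFrame) -> tuple[pd.DataFrame, DispersionTrend, pd.Series]:
    """Full blind pipeline: size factors, dispersions, trend fit, transform.

    Genes with undefined dispersion (zero mean) are excluded from the trend
    fit but still transformed (the closed form is defined at q = 0).
    """
    factors = size_factors(matrix)
    dispersions = genewise_dispersions(matrix, factors)
    z = np.asarray(matrix, dtype=float) / factors.to_numpy(dtype=float)
    means = z.mean(axis=1)
    trend = fit_parametric_trend(means, dispersions.to_numpy())
    return vst_transform(matrix, factors, trend), trend, factors
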