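"""Closed-form interval methods for county-to-parent rate ratios.

Three comparators are implemented:

* **Direct** — delta-method moments of ``R_i / R_(-i)`` (the county versus
  the parent area with the county removed), turned into a log-normal
  interval; the ratio to the *full* parent ``R_i / R_Omega`` is reported as
  the point estimate.
* **Overlap** — maps the Direct interval endpoints through the exact
  relation ``R_i/R_Omega = rho / (p_i rho + 1 - p_i)`` induced by the
  county's population share ``p_i`` (the county's cases also sit in the
  parent total, which correlates numerator and denominator).
* **Spatial** — a log-scale variance decomposition
  ``Var(ln RR) = Var(ln R_i) + Var(ln R_Omega) - 2 Cov(ln R_i, ln R_Omega)``
  where the covariance collects a population-overlap share and
  semivariogram-derived cross-covariances between counties.

Moments are computed on the raw proportion scale; ratios are scale-free.
A county whose total count is zero gets a 0.5-event continuity mass spread
over its strata proportionally to population, so log-scale intervals stay
finite; such estimates are flagged degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import RateRatioEstimate, StratifiedCountTable
from .rates import _weights
from .semivariogram import (
    SemivariogramModel,
    fit_exponential_semivariogram,
    pairwise_distances,
)

__all__ = [
    "MomentPair",
    "direct_ratio_moments",
    "overlap_transform",
    "log_ratio_variance",
    "direct_interval",
    "overlap_interval",
    "spatial_interval",
    "direct_intervals_all",
    "overlap_intervals_all",
    "spatial_intervals_all",
]

#: floor for log-scale variances (keeps intervals well-defined)
_VAR_FLOOR = 1e-12


@dataclass
class MomentPair:
    """Mean and variance of an age-adjusted rate (raw proportion scale)."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def _stabilized_counts(table: StratifiedCountTable) -> tuple[np.ndarray, np.ndarray]:
    """Counts with 0.5 events added (population-proportionally) to zero-count
    regions; returns (counts, degenerate_flags)."""
    counts = table.counts.copy()
    totals = counts.sum(axis=1)
    flags = totals == 0
    if flags.any():
        pop = table.population[flags]
        counts[flags] += 0.5 * pop / pop.sum(axis=1, keepdims=True)
    return counts, flags


def _region_and_complement_moments(table: StratifiedCountTable, w: np.ndarray):
    """Vectorised moments of R_i and R_(-i) for every region (raw scale).

    Var(R_i) = sum_j w_j^2 r_ij / n_ij, the Poisson plug-in for a linear
    combination of independent Poisson counts.
    """
    counts, flags = _stabilized_counts(table)
    n = table.population
    r = counts / n
    mu = r @ w
    var = (w[None, :] ** 2 * r / n).sum(axis=1)

    d_tot = counts.sum(axis=0)
    n_tot = n.sum(axis=0)
    d_c = d_tot[None, :] - counts
    n_c = n_tot[None, :] - n
    if np.any(n_c <= 0):
        raise ValueError("leave-one-out population non-positive (need >= 2 regions)")
    r_c = d_c / n_c
    mu_c = r_c @ w
    var_c = (w[None, :] ** 2 * r_c / n_c).sum(axis=1)
    return mu, var, mu_c, var_c, flags


def direct_ratio_moments(moments_i: MomentPair, moments_rest: MomentPair):
    """Delta-method mean and variance of the ratio R_i / R_(-i).

    mean = mu_i / mu_(-i);
    variance = (sigma_i^2 mu_(-i)^2 + sigma_(-i)^2 mu_i^2) / mu_(-i)^4.
    """
    mu_i, var_i = moments_i.mean, moments_i.variance
    mu_c, var_c = moments_rest.mean, moments_rest.variance
    if mu_c <= 0:
        raise ValueError("complement mean rate must be positive")
    mean = mu_i / mu_c
    variance = (var_i * mu_c**2 + var_c * mu_i**2) / mu_c**4
    return mean, variance


def overlap_transform(rho, p_i):
    """Map rho = R_i/R_(-i) to R_i/R_Omega given population share p_i.

    ``R_i/R_Omega = rho / (p_i rho + (1 - p_i))`` — strictly increasing in
    rho, so interval endpoints map monotonically.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p_i, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("population share must lie in [0, 1)")
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    out = rho / (p * rho + (1.0 - p))
    return float(out) if out.ndim == 0 else out


def log_ratio_variance(var_log_num, var_log_den, cov_log) -> float:
    """Variance of a log ratio:
    Var(ln(X/Y)) = Var(ln X) + Var(ln Y) - 2 Cov(ln X, ln Y).

    Perfect correlation with equal variances cancels exactly.  The result is
    floored at a tiny positive value so intervals stay well defined.
    """
    out = (
        np.asarray(var_log_num, dtype=float)
        + np.asarray(var_log_den, dtype=float)
        - 2.0 * np.asarray(cov_log, dtype=float)
    )
    out = np.maximum(out, _VAR_FLOOR)
    return float(out) if out.ndim == 0 else out


def _direct_frame(table: StratifiedCountTable, weights, level: float) -> pd.DataFrame:
    w = _weights(table, weights)
    mu, var, mu_c, var_c, flags = _region_and_complement_moments(table, w)
    rho = mu / mu_c
    var_ratio = (var * mu_c**2 + var_c * mu**2) / mu_c**4
    cv = np.sqrt(var_ratio) / rho
    z = norm.ppf(0.5 + level / 2.0)
    lower = rho * np.exp(-z * cv)
    upper = rho * np.exp(z * cv)

    pooled = table.counts.sum(axis=0) / table.population.sum(axis=0)
    mu_omega = float(w @ pooled)
    point = mu / mu_omega
    p_i = table.population.sum(axis=1) / table.population.sum()
    # the rho-interval approximates the R_i/R_Omega interval; widen (never
    # narrow) an endpoint in the rare case the point falls outside it
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return pd.DataFrame(
        {
            "region_id": table.region_ids,
            "estimate": point,
            "lower": lower,
            "upper": upper,
            "rho": rho,
            "rho_lower": rho * np.exp(-z * cv),
            "rho_upper": rho * np.exp(z * cv),
            "p_i": p_i,
            "degenerate": flags,
        }
    )


def _finalize(df: pd.DataFrame, method: str) -> pd.DataFrame:
    out = df[["region_id", "estimate", "lower", "upper", "degenerate"]].copy()
    out["ci_length"] = out["upper"] - out["lower"]
    out.insert(1, "method", method)
    return out


def direct_intervals_all(table, weights, level: float = 0.95) -> pd.DataFrame:
    """Direct-method rate-ratio estimates for every region (DataFrame)."""
    return _finalize(_direct_frame(table, weights, level), "direct")


def overlap_intervals_all(table, weights, level: float = 0.95) -> pd.DataFrame:
    """Overlap-method estimates: Direct endpoints mapped through the
    population-share transform; point estimates unchanged."""
    df = _direct_frame(table, weights, level)
    df["lower"] = overlap_transform(df["rho_lower"].to_numpy(), df["p_i"].to_numpy())
    df["upper"] = overlap_transform(df["rho_upper"].to_numpy(), df["p_i"].to_numpy())
    df["lower"] = np.minimum(df["lower"], df["estimate"])
    df["upper"] = np.maximum(df["upper"], df["estimate"])
    return _finalize(df, "overlap")


def spatial_intervals_all(
    table,
    weights,
    coords: np.ndarray,
    level: float = 0.95,
    n_bins: int = 10,
    metric: str = "euclidean",
    model: SemivariogramModel | None = None,
) -> pd.DataFrame:
    """Spatial-method estimates for every region.

    The log-scale variance of the ratio decomposes into four components: the
    variance of the county rate, the variance of the parent rate, their
    covariance due to population overlap, and the autocorrelation between
    counties.  The first three are exactly what the Overlap method accounts
    for, so the Spatial interval is assembled by removing the autocorrelation
    component from the Overlap interval's log-scale variance.  The removable
    fraction is expressed on the correlation scale: with the fitted model,
    the correlation of observed log rates at distance d is
    ``rho(d) = c1 exp(-d/a) / (c0 + c1)`` (the nugget carries the
    uncorrelated noise), and with ``ln R_Omega`` linearised as the
    share-weighted mixture of county log rates the removable fraction for
    county i is ``rho_bar_i = sum_{i' != i} (p_i' mu_i' / mu_Omega)
    rho(d_ii') < 1``.  A zero fitted sill reproduces the Overlap interval
    exactly; a positive one shrinks it, never past zero width.
    """
    coords = np.asarray(coords, dtype=float)
    w = _weights(table, weights)
    if coords.shape[0] != table.n_regions:
        raise ValueError("one centroid per region required")

    mu, var, _, _, flags = _region_and_complement_moments(table, w)
    pooled = table.counts.sum(axis=0) / table.population.sum(axis=0)
    mu_omega = float(w @ pooled)
    p = table.population.sum(axis=1) / table.population.sum()

    if model is None:
        try:
            model = fit_exponential_semivariogram(
                np.log(mu), coords, n_bins=n_bins, metric=metric
            )
        except (ValueError, RuntimeError) as err:
            warnings.warn(
                f"semivariogram fit failed ({err}); falling back to the overlap method"
            )
            df = overlap_intervals_all(table, weights, level)
            df["method"] = "spatial"
            return df

    dmat = pairwise_distances(coords, metric=metric)
    sill = model.nugget + model.partial_sill
    corr = model.covariance(dmat) / sill if sill > 0 else np.zeros_like(dmat)
    np.fill_diagonal(corr, 0.0)
    share = p * mu / mu_omega  # linearisation weights of ln R_Omega
    rho_bar = np.clip(corr @ share, 0.0, 1.0 - 1e-9)

    base = overlap_intervals_all(table, weights, level)
    point = base["estimate"].to_numpy()
    # log-scale offsets of the overlap interval around the point estimate;
    # rho_bar in [0, 1) so the shrink never widens and never collapses
    off_lo = np.log(point) - np.log(base["lower"].to_numpy())
    off_hi = np.log(base["upper"].to_numpy()) - np.log(point)
    shrink = np.sqrt(1.0 - rho_bar)

    df = pd.DataFrame(
        {
            "region_id": table.region_ids,
            "estimate": point,
            "lower": point * np.exp(-shrink * off_lo),
            "upper": point * np.exp(shrink * off_hi),
            "degenerate": base["degenerate"].to_numpy(),
        }
    )
    return _finalize(df, "spatial")


def _single(df: pd.DataFrame, table, region_id: str, method: str) -> RateRatioEstimate:
    i = table.region_index(region_id)
    row = df.iloc[i]
    return RateRatioEstimate(
        value=float(row["estimate"]),
        lower=float(row["lower"]),
        upper=float(row["upper"]),
        method=method,
        degenerate=bool(row["degenerate"]),
    )


def direct_interval(table, weights, region_id: str, level: float = 0.95) -> RateRatioEstimate:
    """Direct-method rate-ratio estimate for one region."""
    return _single(direct_intervals_all(table, weights, level), table, region_id, "direct")


def overlap_interval(table, weights, region_id: str, level: float = 0.95) -> RateRatioEstimate:
    """Overlap-method rate-ratio estimate for one region."""
    return _single(overlap_intervals_all(table, weights, level), table, region_id, "overlap")


def spatial_interval(
    table, weights, coords, region_id: str, level: float = 0.95, **kwargs
) -> RateRatioEstimate:
    """Spatial-method rate-ratio estimate for one region."""
    df = spatial_intervals_all(table, weights, coords, level, **kwargs)
    return _single(df, table, region_id, "spatial")
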