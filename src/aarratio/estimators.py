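"""Estimator classes for county-to-parent rate-ratio intervals.

Each method is an estimator in the scikit-learn idiom: hyper-parameters in
``__init__`` (inspectable via ``get_params`` / ``set_params``), a ``fit``
that consumes a :class:`~aarratio.data.StratifiedCountTable` and standard
weights, and fitted attributes with trailing underscores:

``aar_``
    per-region age-adjusted rates (per 100,000), DataFrame.
``overall_rate_``
    the parent-area age-adjusted rate.
``rate_ratio_``
    per-region DataFrame with ``estimate, lower, upper, ci_length``.

Example
-------
>>> est = DirectRateRatio().fit(table, weights)
>>> est.rate_ratio_.head()
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import intervals as _iv
from .adjacency import AdjacencyStructure
from .data import RateRatioEstimate, StandardWeights, StratifiedCountTable
from .mcmc import MCMCConfig, bcm_intervals, run_mcmc, run_uh_model
from .rates import _weights, age_adjusted_rates, overall_rate

__all__ = [
    "DirectRateRatio",
    "OverlapRateRatio",
    "SpatialRateRatio",
    "BCMRateRatio",
    "UHRateRatio",
]


class _BaseRateRatio(BaseEstimator):
    """Shared fit scaffolding for the rate-ratio estimators."""

    method: str = ""

    def __init__(self, level: float = 0.95):
        self.level = level

    def _validate(self, table, weights):
        if not isinstance(table, StratifiedCountTable):
            raise TypeError("table must be a StratifiedCountTable")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        return _weights(table, weights)

    def _store_rates(self, table, weights):
        aar = age_adjusted_rates(table, weights)
        self.aar_ = pd.DataFrame(
            {"region_id": table.region_ids, "estimate": aar, "method": self.method}
        )
        self.overall_rate_ = overall_rate(table, weights)
        self.region_ids_ = list(table.region_ids)

    def region_estimate(self, region_id: str) -> RateRatioEstimate:
        """Fitted rate-ratio estimate for one region."""
        check_is_fitted(self, "rate_ratio_")
        df = self.rate_ratio_
        row = df[df["region_id"] == str(region_id)]
        if row.empty:
            raise KeyError(f"unknown region id {region_id!r}")
        row = row.iloc[0]
        return RateRatioEstimate(
            value=float(row["estimate"]),
            lower=float(row["lower"]),
            upper=float(row["upper"]),
            method=self.method,
            degenerate=bool(row.get("degenerate", False)),
        )


class DirectRateRatio(_BaseRateRatio):
    """Delta-method interval for R_i versus the parent area without region i.

    The county rate and the leave-one-out parent rate are independent linear
    combinations of Poisson counts; their ratio gets a log-normal interval
    from the delta-method moments.  The reported point estimate is the ratio
    to the full parent area.
    """

    method = "direct"

    def fit(self, table, weights, **ignored):
        self._validate(table, weights)
        self.rate_ratio_ = _iv.direct_intervals_all(table, weights, self.level)
        self._store_rates(table, weights)
        return self


class OverlapRateRatio(_BaseRateRatio):
    """Direct interval corrected for the county's population overlap with the
    parent area (the county's cases also appear in the parent totals)."""

    method = "overlap"

    def fit(self, table, weights, **ignored):
        self._validate(table, weights)
        self.rate_ratio_ = _iv.overlap_intervals_all(table, weights, self.level)
        self._store_rates(table, weights)
        return self


class SpatialRateRatio(_BaseRateRatio):
    """Overlap-style interval further tightened by spatial autocorrelation
    between counties, estimated with an exponential semivariogram."""

    method = "spatial"

    def __init__(
        self,
        level: float = 0.95,
        n_bins: int = 10,
        metric: str = "euclidean",
    ):
        super().__init__(level=level)
        self.n_bins = n_bins
        self.metric = metric

    def fit(self, table, weights, coords=None, **ignored):
        self._validate(table, weights)
        if coords is None:
            raise ValueError("the spatial method needs region centroids (coords)")
        self.rate_ratio_ = _iv.spatial_intervals_all(
            table, weights, coords, self.level, n_bins=self.n_bins, metric=self.metric
        )
        self._store_rates(table, weights)
        return self


class BCMRateRatio(_BaseRateRatio):
    """Bayesian convolution model: posterior-predictive credible intervals.

    Fits the hierarchical Poisson log-linear model with exchangeable and
    intrinsic-CAR county effects by MCMC, then simulates counts from the
    fitted model and summarises the induced age-adjusted rates and ratios
    with equal-tailed percentile intervals.
    """

    method = "bcm"

    def __init__(
        self,
        level: float = 0.95,
        n_iter: int = 10_000,
        n_burn: int = 5_000,
        thin: int = 5,
        seed: int = 0,
        gamma_shape: float = 2.0,
        gamma_rate: float = 0.5,
    ):
        super().__init__(level=level)
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed
        self.gamma_shape = gamma_shape
        self.gamma_rate = gamma_rate

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            thin=self.thin,
            seed=self.seed,
            gamma_shape=self.gamma_shape,
            gamma_rate=self.gamma_rate,
        )

    def fit(self, table, weights, adjacency=None, expected=None, **ignored):
        self._validate(table, weights)
        if not isinstance(adjacency, AdjacencyStructure):
            raise ValueError("the convolution model needs an AdjacencyStructure")
        self.sample_ = run_mcmc(table, adjacency, self._config(), expected=expected)
        rates_df, ratios_df = bcm_intervals(
            self.sample_, table, weights, level=self.level, seed=self.seed
        )
        self.rate_ratio_ = ratios_df
        self.aar_ = rates_df[rates_df["region_id"] != "__overall__"].reset_index(drop=True)
        overall = rates_df[rates_df["region_id"] == "__overall__"].iloc[0]
        self.overall_rate_ = float(overall["estimate"])
        self.acceptance_rates_ = dict(self.sample_.acceptance_rates)
        self.region_ids_ = list(table.region_ids)
        return self


class UHRateRatio(BCMRateRatio):
    """Uncorrelated-heterogeneity-only variant (no CAR term)."""

    method = "uh"

    def fit(self, table, weights, adjacency=None, expected=None, **ignored):
        self._validate(table, weights)
        self.sample_ = run_uh_model(table, self._config(), expected=expected)
        rates_df, ratios_df = bcm_intervals(
            self.sample_, table, weights, level=self.level, seed=self.seed
        )
        self.rate_ratio_ = ratios_df
        self.aar_ = rates_df[rates_df["region_id"] != "__overall__"].reset_index(drop=True)
        overall = rates_df[rates_df["region_id"] == "__overall__"].iloc[0]
        self.overall_rate_ = float(overall["estimate"])
        self.acceptance_rates_ = dict(self.sample_.acceptance_rates)
        self.region_ids_ = list(table.region_ids)
        return self
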