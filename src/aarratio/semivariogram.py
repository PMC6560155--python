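"""Exponential semivariogram estimation for spatially correlated rates.

The semivariogram ``gamma(d)`` is half the expected squared difference of a
field observed at two sites separated by distance ``d``.  The exponential
family ``gamma(d) = c0 + c1 (1 - exp(-d/a))`` has nugget ``c0`` (measurement
noise / micro-scale variance), partial sill ``c1`` and range parameter ``a``;
the implied spatial covariance between distinct sites is
``C(d) = c1 * exp(-d/a)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SemivariogramModel",
    "empirical_semivariogram",
    "fit_exponential_semivariogram",
    "pairwise_distances",
]


@dataclass
class SemivariogramModel:
    """Fitted exponential semivariogram gamma(d) = c0 + c1*(1 - exp(-d/a))."""

    nugget: float
    partial_sill: float
    range_param: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range_param > 0")

    def semivariance(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-d / self.range_param))

    def covariance(self, d) -> np.ndarray:
        """Spatial covariance ``C(d) = c1 * exp(-d/a)`` (nugget excluded)."""
        d = np.asarray(d, dtype=float)
        return self.partial_sill * np.exp(-d / self.range_param)


def pairwise_distances(coords: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Distance matrix between region centroids.

    ``metric='greatcircle'`` treats columns as (longitude, latitude) in
    degrees and returns great-circle distances in kilometres.
    """
    coords = np.asarray(coords, dtype=float)
    if metric == "euclidean":
        return squareform(pdist(coords))
    if metric == "greatcircle":
        lon = np.radians(coords[:, 0])[:, None]
        lat = np.radians(coords[:, 1])[:, None]
        dlon = lon - lon.T
        dlat = lat - lat.T
        h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        h = np.clip(h, 0.0, 1.0)
        return 2 * 6371.0 * np.arcsin(np.sqrt(h))
    raise ValueError(f"unknown metric {metric!r}")


def empirical_semivariogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    metric: str = "euclidean",
):
    """Binned empirical semivariogram.

    Returns ``(bin_centers, gamma_hat, pair_counts)`` where ``gamma_hat`` is
    the mean of half squared differences over pairs falling in each distance
    bin.  Bins are equal-width over (0, max distance]; empty bins are dropped.
    """
    values = np.asarray(values, dtype=float).ravel()
    dmat = pairwise_distances(coords, metric=metric)
    iu = np.triu_indices(values.size, k=1)
    d = dmat[iu]
    g = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            centers.append(d[m].mean())
            gammas.append(g[m].mean())
            counts.append(int(m.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_exponential_semivariogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    metric: str = "euclidean",
) -> SemivariogramModel:
    """Weighted least-squares fit of the exponential semivariogram.

    Bin semivariances are weighted by their pair counts.  A near-constant
    field yields a zero-sill model (with a warning) rather than a failure.
    """
    values = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 regions to estimate a semivariogram")
    centers, gammas, counts = empirical_semivariogram(values, coords, n_bins, metric)

    total_var = float(values.var())
    if total_var < 1e-14 or gammas.max() < 1e-14:
        warnings.warn("near-constant field: returning zero-sill semivariogram")
        return SemivariogramModel(max(total_var, 0.0), 0.0, float(centers.max() or 1.0))

    def model(d, c0, c1, a):
        return c0 + c1 * (1.0 - np.exp(-d / a))

    dmax = float(centers.max())
    # identifiability guards: beyond the observed distance support the range
    # trades off freely against the sill (the ramp only identifies c1/a), and
    # the sill of a stationary field cannot plausibly exceed twice the larger
    # of the field variance and the largest bin semivariance
    sill_cap = 2.0 * max(total_var, float(gammas.max()))
    p0 = (
        min(max(float(gammas[0]) / 2.0, 1e-10), sill_cap),
        min(max(total_var - gammas[0] / 2.0, 1e-10), sill_cap),
        dmax / 3.0,
    )
    try:
        popt, _ = curve_fit(
            model,
            centers,
            gammas,
            p0=p0,
            sigma=1.0 / np.sqrt(counts),
            bounds=([0.0, 0.0, 1e-8], [sill_cap, sill_cap, dmax]),
            maxfev=20000,
        )
        c0, c1, a = map(float, popt)
    except RuntimeError:
        warnings.warn("semivariogram fit did not converge; returning zero-sill model")
        return SemivariogramModel(total_var, 0.0, dmax / 3.0)
    return SemivariogramModel(c0, c1, a)
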