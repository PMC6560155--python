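"""Age-specific and age-adjusted rate arithmetic.

All four interval methods share this arithmetic.  Rates are *reported* per
100,000 person-years; moment computations elsewhere work on the raw
proportion scale (rate ratios are scale-free).

Notation: for region ``i`` and age stratum ``j``, ``D_ij`` is the event
count, ``n_ij`` the person-years, ``r_ij = D_ij / n_ij`` the age-specific
rate, and the age-adjusted rate (AAR) is ``R_i = sum_j w_j r_ij`` with
standard-population weights ``w_j`` summing to one.  The parent-area rate
``R_Omega`` is the AAR of the pooled counts.
"""

from __future__ import annotations

import numpy as np

from .data import PER, StandardWeights, StratifiedCountTable

__all__ = [
    "age_specific_rates",
    "age_adjusted_rate",
    "age_adjusted_rates",
    "overall_rate",
    "leave_one_out_rate",
    "expected_counts",
    "population_share",
    "rate_ratio_point",
]


def _weights(table: StratifiedCountTable, weights) -> np.ndarray:
    if isinstance(weights, StandardWeights):
        return weights.aligned_to(table.age_labels)
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != table.n_ages:
        raise ValueError(
            f"expected {table.n_ages} weights, got {w.size}"
        )
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return w


def age_specific_rates(table: StratifiedCountTable, per: float = PER) -> np.ndarray:
    """Rates ``r_ij = D_ij / n_ij`` per ``per`` person-years, shape (I, J)."""
    return table.counts / table.population * per


def age_adjusted_rate(counts, population, weights, per: float = PER) -> float:
    """AAR for a single region given 1-D count/population vectors."""
    counts = np.asarray(counts, dtype=float).ravel()
    population = np.asarray(population, dtype=float).ravel()
    w = np.asarray(getattr(weights, "w", weights), dtype=float).ravel()
    if not (counts.size == population.size == w.size):
        raise ValueError("counts, population and weights must have equal length")
    return float(np.sum(w * counts / population) * per)


def age_adjusted_rates(table: StratifiedCountTable, weights, per: float = PER) -> np.ndarray:
    """AARs ``R_i`` for every region, shape (I,)."""
    w = _weights(table, weights)
    return (table.counts / table.population) @ w * per


def overall_rate(table: StratifiedCountTable, weights, per: float = PER) -> float:
    """Parent-area AAR ``R_Omega``: pool counts and populations, then adjust."""
    w = _weights(table, weights)
    pooled = table.counts.sum(axis=0) / table.population.sum(axis=0)
    return float(w @ pooled * per)


def leave_one_out_rate(
    table: StratifiedCountTable, weights, region_id: str, per: float = PER
) -> float:
    """AAR of the pooled area after deleting one region (``R_(-i)``)."""
    if table.n_regions < 2:
        raise ValueError("leave-one-out rate needs at least two regions")
    i = table.region_index(region_id)
    w = _weights(table, weights)
    d = table.counts.sum(axis=0) - table.counts[i]
    n = table.population.sum(axis=0) - table.population[i]
    return float(w @ (d / n) * per)


def expected_counts(table: StratifiedCountTable) -> np.ndarray:
    """Expected counts ``e_ij = n_ij * (sum_i D_ij) / (sum_i n_ij)``.

    The pooled stratum rate serves as the internal reference, so stratum
    totals of ``e`` equal stratum totals of the observed counts.
    """
    stratum_rate = table.counts.sum(axis=0) / table.population.sum(axis=0)
    return table.population * stratum_rate[None, :]


def population_share(table: StratifiedCountTable, region_id: str | None = None):
    """Share ``p_i`` of the parent population living in region ``i``.

    With ``region_id=None`` returns the full vector (sums to one).
    """
    totals = table.population.sum(axis=1)
    shares = totals / totals.sum()
    if region_id is None:
        return shares
    return float(shares[table.region_index(region_id)])


def rate_ratio_point(rate_i: float, rate_parent: float) -> float:
    """Point estimate of the rate ratio ``R_i / R_Omega``."""
    if rate_parent <= 0:
        raise ValueError("parent rate must be positive")
    return float(rate_i) / float(rate_parent)
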