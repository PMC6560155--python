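"""Evaluation harness: interval length, coverage, tiers, method comparison.

The comparison criteria are (1) mean 95% interval length, (2) coverage, and
(3) the standard deviation of interval length, tabulated per method and
county-population tier.  Coverage has two readings shipped side by side:

* ``coverage`` — the standard one: the fraction of replicate intervals that
  contain the true per-region rate ratio;
* ``overlap_coverage`` — the mean fractional overlap between each replicate
  interval and a per-region reference interval (the published wording
  "proportion of overlap between 95% intervals" admits this reading; which
  reference interval was meant is not recoverable, so both are reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ci_length",
    "coverage",
    "interval_overlap",
    "tier_assign",
    "summarize",
    "standardized_irls_compare",
    "IRLSComparison",
]


def ci_length(est) -> float:
    """Interval length upper - lower; accepts a RateRatioEstimate or pair."""
    lower = getattr(est, "lower", None)
    upper = getattr(est, "upper", None)
    if lower is None and isinstance(est, (tuple, list)) and len(est) == 2:
        lower, upper = est
    if lower is None or upper is None:
        raise ValueError("estimate has no interval")
    return float(upper) - float(lower)


def coverage(lower, upper, truth) -> float:
    """Fraction of intervals containing the truth.

    ``lower``/``upper`` are arrays over (replicate, region) or any shape;
    ``truth`` broadcasts against them (one true value per region).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    hit = (lower <= truth) & (truth <= upper)
    return float(hit.mean())


def interval_overlap(lower, upper, ref_lower, ref_upper) -> float:
    """Mean fractional overlap of intervals with reference intervals.

    The overlap of [l, u] with [L, U] is the length of their intersection
    divided by the length of [l, u].
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    ref_lower = np.asarray(ref_lower, dtype=float)
    ref_upper = np.asarray(ref_upper, dtype=float)
    inter = np.maximum(
        np.minimum(upper, ref_upper) - np.maximum(lower, ref_lower), 0.0
    )
    width = np.maximum(upper - lower, 1e-300)
    return float((inter / width).mean())


def tier_assign(totals, n_tiers: int = 3, region_ids=None) -> np.ndarray:
    """Tier labels ('large'/'medium'/'small') by population rank.

    Regions are sorted by population descending (ties broken by roster
    order), then split into near-equal thirds: first third large, next
    medium, rest small.
    """
    totals = np.asarray(totals, dtype=float)
    I = totals.size
    order = np.lexsort((np.arange(I), -totals))
    names = ["large", "medium", "small"][:n_tiers]
    sizes = [I // n_tiers + (1 if k < I % n_tiers else 0) for k in range(n_tiers)]
    labels = np.empty(I, dtype=object)
    start = 0
    for name, sz in zip(names, sizes):
        labels[order[start : start + sz]] = name
        start += sz
    return labels.astype(str)


def summarize(
    results: pd.DataFrame,
    truth: np.ndarray | dict | None = None,
    tiers: np.ndarray | dict | None = None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per (method, tier) mean CI length, coverage and SD of CI length.

    ``results`` is a long frame with columns ``replicate, region_id, method,
    estimate, lower, upper`` (extra columns pass through groupby unharmed).
    ``truth`` maps region_id to the true rate ratio (array in roster order or
    dict); ``tiers`` likewise maps region_id to its tier.  ``reference``
    (optional) is a per-(region, method) frame with columns ``region_id,
    method, lower, upper`` used for the overlap-coverage reading.
    """
    df = results.copy()
    df["region_id"] = df["region_id"].astype(str)
    regions = list(dict.fromkeys(df["region_id"]))

    def lookup(mapping, default):
        if mapping is None:
            return {r: default for r in regions}
        if isinstance(mapping, dict):
            return {str(k): v for k, v in mapping.items()}
        arr = np.asarray(mapping)
        return dict(zip(regions, arr))

    truth_map = lookup(truth, np.nan)
    tier_map = lookup(tiers, "all")
    df["truth"] = df["region_id"].map(truth_map)
    df["tier"] = df["region_id"].map(tier_map)
    df["length"] = df["upper"] - df["lower"]
    df["hit"] = (df["lower"] <= df["truth"]) & (df["truth"] <= df["upper"])

    if reference is not None:
        ref = reference.copy()
        ref["region_id"] = ref["region_id"].astype(str)
        ref = ref.rename(columns={"lower": "ref_lower", "upper": "ref_upper"})
        df = df.merge(
            ref[["region_id", "method", "ref_lower", "ref_upper"]],
            on=["region_id", "method"],
            how="left",
        )
        inter = np.maximum(
            np.minimum(df["upper"], df["ref_upper"]) - np.maximum(df["lower"], df["ref_lower"]),
            0.0,
        )
        df["overlap_frac"] = inter / np.maximum(df["length"], 1e-300)

    agg = {
        "mean_ci_length": ("length", "mean"),
        "coverage": ("hit", "mean"),
        "sd_ci_length": ("length", "std"),
        "n": ("length", "size"),
    }
    if "overlap_frac" in df:
        agg["overlap_coverage"] = ("overlap_frac", "mean")
    out = df.groupby(["method", "tier"], as_index=False).agg(**agg)
    out["sd_ci_length"] = out["sd_ci_length"].fillna(0.0)
    if truth is None:
        out["coverage"] = np.nan
    return out


@dataclass
class IRLSComparison:
    """Slopes/correlations between two interval-length vectors, raw and
    after z-score standardisation."""

    raw_slope: float
    raw_correlation: float
    std_slope: float
    std_correlation: float


def _irls_slope(x: np.ndarray, y: np.ndarray, eps: float = 1e-6,
                tol: float = 1e-8, max_iter: int = 100) -> float:
    """Robust regression slope of y on x (with intercept) by iteratively
    reweighted least squares, weights 1/max(|residual|, eps)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ beta
        w = 1.0 / np.maximum(np.abs(resid), eps)
        W = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return float(beta[1])


def standardized_irls_compare(lengths_a, lengths_b) -> IRLSComparison:
    """Compare interval lengths from two methods on raw and z-scored scales.

    z-scoring puts both methods on a common scale; a standardised slope and
    correlation near 1 mean the methods rank counties identically even when
    one produces systematically wider intervals.
    """
    a = np.asarray(lengths_a, dtype=float).ravel()
    b = np.asarray(lengths_b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    corr = float(np.corrcoef(a, b)[0, 1])
    return IRLSComparison(
        raw_slope=_irls_slope(a, b),
        raw_correlation=corr,
        std_slope=_irls_slope(za, zb),
        std_correlation=float(np.corrcoef(za, zb)[0, 1]),
    )
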