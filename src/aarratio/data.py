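"""Containers for age-stratified count data and standard-population weights.

The basic observational unit is a region x age-group table of event counts
``D_ij`` with matching person-year populations ``n_ij``.  Counts in each cell
are modelled as independent Poisson draws whose mean is the population times
an (age-specific) event rate; everything downstream — age adjustment, rate
ratios, the spatial smoothing model — consumes this one structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedCountTable",
    "StandardWeights",
    "RateEstimate",
    "RateRatioEstimate",
]

#: scale on which rates are reported (events per 100,000 person-years)
PER = 100_000.0


@dataclass
class StratifiedCountTable:
    """Region x age-group event counts and person-year populations.

    Parameters
    ----------
    region_ids : sequence of str
        Unique, ordered region identifiers (e.g. FIPS codes).
    age_labels : sequence of str
        Unique, ordered age-stratum labels.
    counts : ndarray of shape (I, J)
        Non-negative integer event counts ``D_ij``.
    population : ndarray of shape (I, J)
        Strictly positive person-years at risk ``n_ij``.
    """

    region_ids: list[str]
    age_labels: list[str]
    counts: np.ndarray
    population: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.region_ids = [str(r) for r in self.region_ids]
        self.age_labels = [str(a) for a in self.age_labels]
        self.counts = np.asarray(self.counts, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        I, J = len(self.region_ids), len(self.age_labels)
        if self.counts.shape != (I, J) or self.population.shape != (I, J):
            raise ValueError(
                f"counts {self.counts.shape} and population "
                f"{self.population.shape} must both have shape {(I, J)}"
            )
        if len(set(self.region_ids)) != I:
            raise ValueError("region_ids must be unique")
        if len(set(self.age_labels)) != J:
            raise ValueError("age_labels must be unique")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if np.any(self.population <= 0) or not np.all(np.isfinite(self.population)):
            raise ValueError("population must be finite and strictly positive")
        self._index = {r: k for k, r in enumerate(self.region_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_ages(self) -> int:
        return len(self.age_labels)

    def region_index(self, region_id: str) -> int:
        """Positional index of ``region_id`` (raises KeyError if unknown)."""
        try:
            return self._index[str(region_id)]
        except KeyError:
            raise KeyError(f"unknown region id {region_id!r}") from None

    def drop_region(self, region_id: str) -> "StratifiedCountTable":
        """Table with one region removed (used for leave-one-out rates)."""
        i = self.region_index(region_id)
        keep = [k for k in range(self.n_regions) if k != i]
        return StratifiedCountTable(
            [self.region_ids[k] for k in keep],
            list(self.age_labels),
            self.counts[keep],
            self.population[keep],
        )

    # -- long-form CSV round-trip ------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "StratifiedCountTable":
        """Build from a long-form frame with columns
        region_id, age_group, count, population."""
        required = {"region_id", "age_group", "count", "population"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["region_id"] = df["region_id"].astype(str)
        df["age_group"] = df["age_group"].astype(str)
        regions = list(dict.fromkeys(df["region_id"]))
        ages = list(dict.fromkeys(df["age_group"]))
        counts = (
            df.pivot(index="region_id", columns="age_group", values="count")
            .reindex(index=regions, columns=ages)
            .to_numpy(dtype=float)
        )
        pop = (
            df.pivot(index="region_id", columns="age_group", values="population")
            .reindex(index=regions, columns=ages)
            .to_numpy(dtype=float)
        )
        if np.any(np.isnan(counts)) or np.any(np.isnan(pop)):
            raise ValueError("incomplete region x age grid in long-form input")
        return cls(regions, ages, counts, pop)

    def to_long(self) -> pd.DataFrame:
        I, J = self.counts.shape
        return pd.DataFrame(
            {
                "region_id": np.repeat(self.region_ids, J),
                "age_group": np.tile(self.age_labels, I),
                "count": self.counts.ravel(),
                "population": self.population.ravel(),
            }
        )

    @classmethod
    def read_csv(cls, path) -> "StratifiedCountTable":
        return cls.from_long(pd.read_csv(path, dtype={"region_id": str, "age_group": str}))

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


@dataclass
class StandardWeights:
    """Standard-population weights ``w_j`` (must sum to one)."""

    w: np.ndarray
    age_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {self.w.sum()!r})")
        if self.age_labels is not None:
            self.age_labels = [str(a) for a in self.age_labels]
            if len(self.age_labels) != self.w.size:
                raise ValueError("age_labels length must match weights")

    def __len__(self) -> int:
        return self.w.size

    @classmethod
    def read_csv(cls, path) -> "StandardWeights":
        df = pd.read_csv(path, dtype={"age_group": str})
        if not {"age_group", "weight"} <= set(df.columns):
            raise ValueError("weights CSV needs columns age_group, weight")
        return cls(df["weight"].to_numpy(), list(df["age_group"]))

    def write_csv(self, path) -> None:
        labels = self.age_labels or [str(j) for j in range(len(self))]
        pd.DataFrame({"age_group": labels, "weight": self.w}).to_csv(path, index=False)

    def aligned_to(self, age_labels: list[str]) -> np.ndarray:
        """Weight vector reordered to match ``age_labels``."""
        if self.age_labels is None:
            if len(self) != len(age_labels):
                raise ValueError("weight length does not match number of age strata")
            return self.w
        lookup = dict(zip(self.age_labels, self.w))
        try:
            return np.array([lookup[str(a)] for a in age_labels])
        except KeyError as err:
            raise ValueError(f"no weight for age stratum {err.args[0]!r}") from None


@dataclass
class RateEstimate:
    """Age-adjusted rate (per 100,000) with an optional interval."""

    value: float
    lower: float | None = None
    upper: float | None = None
    method: str = "direct"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("rate must be non-negative")
        if self.lower is not None and self.upper is not None:
            if not (self.lower - 1e-9 <= self.value <= self.upper + 1e-9):
                raise ValueError("interval must contain the point estimate")


@dataclass
class RateRatioEstimate:
    """Rate ratio R_i / R_parent with an optional interval."""

    value: float
    lower: float | None = None
    upper: float | None = None
    method: str = "direct"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0 and not self.degenerate:
            raise ValueError("rate ratio must be positive")
        if self.lower is not None and self.upper is not None and not self.degenerate:
            if not (self.lower - 1e-9 <= self.value <= self.upper + 1e-9):
                raise ValueError("interval must contain the point estimate")

    @property
    def ci_length(self) -> float | None:
        if self.lower is None or self.upper is None:
            return None
        return self.upper - self.lower
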