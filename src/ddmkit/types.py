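"""Core data structures shared by the estimators, life-table and simulation code.

Counts are always held in 5-year (or otherwise user-chosen) age groups with
integer lower bounds and a single open-ended terminal group, the convention of
intercensal death-distribution work: two census age distributions plus the mean
annual intercensal deaths, one region and sex at a time.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AgeGroupedCounts",
    "IntercensalDataset",
    "GGBPoints",
    "GGBResult",
    "SEGResult",
    "LifeTable",
    "EstimatePanel",
    "EstimationError",
]

SEXES = ("male", "female", "total")
KINDS = ("population", "deaths")
METRICS = ("completeness", "q45_15", "e0")


class EstimationError(RuntimeError):
    """Raised when a death-distribution method is not applicable to the data."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float).copy()


@dataclass
class AgeGroupedCounts:
    """One age distribution (population stock or death flow).

    Parameters
    ----------
    age
        Integer lower bounds of the age groups, strictly increasing; the last
        group is open-ended ("A+").
    counts
        Non-negative count per group.  For ``kind="deaths"`` these are *mean
        annual* counts over the intercensal period.
    sex
        ``male``, ``female`` or ``total``.
    reference_time
        Decimal year of the enumeration (mid-period for deaths).
    kind
        ``population`` or ``deaths``.
    """

    age: np.ndarray
    counts: np.ndarray
    sex: str = "total"
    reference_time: float = 0.0
    kind: str = "population"

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=int).copy()
        self.counts = _as_float_array(self.counts)
        if self.age.ndim != 1 or self.counts.shape != self.age.shape:
            raise ValueError("age and counts must be 1-D arrays of equal length")
        if len(self.age) < 2:
            raise ValueError("need at least two age groups (one closed + open)")
        if not np.all(np.diff(self.age) > 0):
            raise ValueError("age lower bounds must be strictly increasing")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            bad = int(np.nonzero(self.counts < 0)[0][0])
            raise ValueError(
                f"negative count {self.counts[bad]} in age group {self.age[bad]}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    # -- convenience -------------------------------------------------------
    @property
    def open_age(self) -> int:
        """Lower bound of the open-ended terminal group."""
        return int(self.age[-1])

    @property
    def widths(self) -> np.ndarray:
        """Widths of the closed groups (length ``len(age) - 1``)."""
        return np.diff(self.age).astype(float)

    def total(self) -> float:
        return float(self.counts.sum())

    def cumulative_above(self) -> np.ndarray:
        """N(x+): count at or above each group's lower bound."""
        return np.cumsum(self.counts[::-1])[::-1]

    def with_counts(self, counts) -> "AgeGroupedCounts":
        return dataclasses.replace(self, counts=_as_float_array(counts))

    def scaled(self, factor: float) -> "AgeGroupedCounts":
        return self.with_counts(self.counts * float(factor))


@dataclass
class IntercensalDataset:
    """Two census age distributions plus mean annual intercensal deaths.

    The unit every death-distribution estimator consumes.  All three schedules
    must share identical age bounds (use :func:`ddmkit.io.harmonize` first).
    """

    census1: AgeGroupedCounts
    census2: AgeGroupedCounts
    deaths: AgeGroupedCounts
    region: str = "all"
    sex: str = "total"

    def __post_init__(self) -> None:
        if self.census1.kind != "population" or self.census2.kind != "population":
            raise ValueError("census1/census2 must have kind='population'")
        if self.deaths.kind != "deaths":
            raise ValueError("deaths must have kind='deaths'")
        if self.census1.reference_time >= self.census2.reference_time:
            raise ValueError("census1 must precede census2")
        for other in (self.census2, self.deaths):
            if not np.array_equal(self.census1.age, other.age):
                raise ValueError(
                    "census1, census2 and deaths must share identical age bounds"
                )

    @property
    def t(self) -> float:
        """Length of the intercensal interval in years."""
        return float(self.census2.reference_time - self.census1.reference_time)

    @property
    def age(self) -> np.ndarray:
        return self.census1.age

    def replace(self, **kwargs) -> "IntercensalDataset":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GGBPoints:
    """Per-age rates entering the growth-balance regression.

    For each grid age ``x`` the entry rate N(x)/N(x+), the growth rate r(x+)
    of the population aged x and above, and the observed death rate D(x+)/N(x+),
    all per year.  ``t`` is carried along so a fit can convert the intercept
    into a census-coverage ratio.
    """

    age: np.ndarray
    entry_rate: np.ndarray
    growth_rate: np.ndarray
    death_rate: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=int)
        for name in ("entry_rate", "growth_rate", "death_rate"):
            arr = _as_float_array(getattr(self, name))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def lhs(self) -> np.ndarray:
        """Left-hand side of the balance relation: entry rate minus growth rate."""
        return self.entry_rate - self.growth_rate

    def window_mask(self, low: float, high: float) -> np.ndarray:
        return (self.age >= low) & (self.age <= high)


@dataclass
class GGBResult:
    """General-growth-balance fit: coverage ratio and completeness."""

    intercept: float
    slope: float
    relative_census_coverage: float  # k1/k2 = exp(intercept * t)
    completeness: float  # C, uncapped; may exceed 1
    age_window: tuple[float, float]
    fit_rmse: float
    points: GGBPoints
    regression: str = "tls"
    capped: bool = False


@dataclass
class SEGResult:
    """Synthetic-extinct-generations estimate.

    ``c_by_age`` holds the coverage ratio c(a) = N_hat(a+)/N_obs(a+) at each
    age-group lower bound; ``completeness`` is its summary over the age window.
    """

    age: np.ndarray
    c_by_age: np.ndarray
    n_hat_by_age: np.ndarray
    n_obs_by_age: np.ndarray
    completeness: float
    age_window: tuple[float, float]
    e_open: float = float("nan")
    delta: float | None = None
    summary: str = "mean"
    capped: bool = False


@dataclass
class LifeTable:
    """Abridged period life table built from central death rates m(x)."""

    age: np.ndarray  # lower bounds, last open
    mx: np.ndarray
    ax: np.ndarray  # average years lived in group by those dying in it
    qx: np.ndarray
    lx: np.ndarray  # survivors at the group's lower bound, radix 1
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        """Life expectancy at birth, T(0)/l(0)."""
        return float(self.Tx[0] / self.lx[0])

    def survivors_at(self, exact_age: float) -> float:
        """l(x) at an exact age that is one of the table's group bounds."""
        idx = np.nonzero(self.age == exact_age)[0]
        if len(idx) == 0:
            raise ValueError(f"life table has no group bound at age {exact_age}")
        return float(self.lx[idx[0]])

    @property
    def q45_15(self) -> float:
        """Probability of a 15-year-old dying before exact age 60: 1 - l(60)/l(15)."""
        return 1.0 - self.survivors_at(60) / self.survivors_at(15)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age": self.age,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )


class EstimatePanel:
    """Long-format panel of estimates: (region, sex, period, source, metric, value).

    Thin validated wrapper around a pandas DataFrame; sources are free labels
    (e.g. different agencies), metrics are completeness, q45_15 or e0.
    """

    COLUMNS = ("region", "sex", "period", "source", "metric", "value")
    KEY = ["region", "sex", "period", "source", "metric"]

    def __init__(self, frame) -> None:
        import pandas as pd

        frame = pd.DataFrame(frame)
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"estimate panel missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if len(frame):
            frame["value"] = frame["value"].astype(float)
            if not np.all(np.isfinite(frame["value"].to_numpy())):
                raise ValueError("estimate panel contains non-finite values")
            dup = frame.duplicated(subset=self.KEY, keep=False)
            if dup.any():
                dupes = frame.loc[dup, self.KEY].drop_duplicates()
                raise ValueError(
                    "duplicate (region, sex, period, source, metric) keys:\n"
                    + dupes.to_string(index=False)
                )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def for_metric(self, metric: str) -> "EstimatePanel":
        return EstimatePanel(self.frame[self.frame["metric"] == metric])

    @property
    def sources(self) -> list[str]:
        return sorted(self.frame["source"].unique())

    @property
    def periods(self) -> list[str]:
        return sorted(self.frame["period"].unique())
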