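"""Completeness-adjusted mortality rates, abridged life tables, adult mortality
(45q15), life expectancy, and top-down rescaling of subnational death counts."""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np

from .types import AgeGroupedCounts, IntercensalDataset, LifeTable

__all__ = [
    "adjusted_rates",
    "build_life_table",
    "adult_mortality_45q15",
    "top_down_rescale",
    "default_ax",
]


def adjusted_rates(ds: IntercensalDataset, completeness: float) -> np.ndarray:
    """Age-specific central death rates corrected for under-registration.

    m(x) = (D(x)/completeness) / PY(x), with person-years PY(x) the geometric
    mean of the two census counts in the group (annualized exposure).  With
    completeness 1 the rates are the unadjusted observed rates; halving the
    completeness doubles every rate.
    """
    if completeness <= 0:
        raise ValueError("completeness must be positive")
    py = np.sqrt(ds.census1.counts * ds.census2.counts)
    if np.any(py <= 0):
        raise ValueError("cannot form person-years: empty census group")
    return (ds.deaths.counts / float(completeness)) / py


def default_ax(age: np.ndarray) -> np.ndarray:
    """Average years lived in the group by those dying in it.

    Conventional values: 0.3 for age 0, 1.6 for 1-4 when that split is
    present, half the width otherwise; the open group gets NaN (unused).
    """
    age = np.asarray(age)
    n = np.diff(age).astype(float)
    ax = n / 2.0
    if age[0] == 0 and len(age) > 1 and age[1] == 1:
        ax[0] = 0.3
        if len(age) > 2 and age[2] == 5:
            ax[1] = 1.6
    elif age[0] == 0 and len(age) > 1 and age[1] == 5:
        ax[0] = 2.5
    return np.append(ax, np.nan)


def build_life_table(age, mx, ax=None) -> LifeTable:
    """Abridged period life table from central death rates.

    q(x) = n m / (1 + (n - a) m), clipped to 1 with a warning where the rates
    are extreme; the open interval has q = 1 and L = l(A)/m(A+).
    """
    age = np.asarray(age, dtype=int)
    mx = np.asarray(mx, dtype=float)
    if age.shape != mx.shape:
        raise ValueError("age and mx must align")
    if np.any(mx < 0):
        raise ValueError("mx must be non-negative")
    if mx[-1] <= 0:
        raise ValueError("open-interval death rate must be positive")
    ax = default_ax(age) if ax is None else np.asarray(ax, dtype=float)
    n = np.diff(age).astype(float)

    qx = np.empty_like(mx)
    qx[:-1] = n * mx[:-1] / (1.0 + (n - ax[:-1]) * mx[:-1])
    if np.any(qx[:-1] > 1):
        warnings.warn("q(x) > 1 clipped to 1; check the input rates")
        qx[:-1] = np.minimum(qx[:-1], 1.0)
    qx[-1] = 1.0

    lx = np.empty_like(mx)
    lx[0] = 1.0
    for i in range(len(n)):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = np.empty_like(mx)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]

    Lx = np.empty_like(mx)
    Lx[:-1] = n * lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1]
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(age=age, mx=mx, ax=ax, qx=qx, lx=lx, Lx=Lx, Tx=Tx, ex=ex)


def adult_mortality_45q15(lt: LifeTable) -> float:
    """Probability of a 15-year-old dying before exact age 60: 1 - l(60)/l(15)."""
    if 15 not in lt.age or 60 not in lt.age:
        raise ValueError("life table must have group bounds at ages 15 and 60")
    return lt.q45_15


def top_down_rescale(
    state_deaths: Mapping[str, AgeGroupedCounts],
    national_deaths: AgeGroupedCounts,
    exempt: Iterable[str] = (),
) -> dict[str, AgeGroupedCounts]:
    """Proportionally rescale subnational deaths to an independent national total.

    Per age group, non-exempt regions are multiplied by a common factor so the
    grand sum (exempt regions included, unchanged) equals the national total.
    The factor must be non-negative: the national total may not fall short of
    the exempt regions' own sum.
    """
    exempt = set(exempt)
    unknown = exempt - set(state_deaths)
    if unknown:
        raise ValueError(f"exempt regions not present: {sorted(unknown)}")
    regions = list(state_deaths)
    for r in regions:
        if not np.array_equal(state_deaths[r].age, national_deaths.age):
            raise ValueError(f"region {r!r} age bounds differ from the national schedule")
    nat = national_deaths.counts
    exempt_sum = np.zeros_like(nat)
    scale_sum = np.zeros_like(nat)
    for r in regions:
        (exempt_sum if r in exempt else scale_sum).__iadd__(state_deaths[r].counts)
    residual = nat - exempt_sum
    if np.any(residual < -1e-9 * np.maximum(nat, 1.0)):
        raise ValueError(
            "national total is below the exempt regions' sum in some age group"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(scale_sum > 0, residual / np.where(scale_sum > 0, scale_sum, 1.0), 1.0)
    if np.any((scale_sum <= 0) & (residual > 1e-9 * np.maximum(nat, 1.0))):
        raise ValueError("no non-exempt deaths to absorb the national residual")
    out = {}
    for r in regions:
        if r in exempt:
            out[r] = state_deaths[r].with_counts(state_deaths[r].counts)
        else:
            out[r] = state_deaths[r].with_counts(state_deaths[r].counts * factor)
    return out
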