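"""Death distribution methods: general growth balance (GGB), synthetic extinct
generations (SEG), and the two-stage SEG-adj, with age-window selection and
diagnostics.

All three methods compare the age distribution of intercensal deaths with the
change in the population's age distribution between two censuses, and estimate
the completeness C of death registration *relative to census coverage* — C may
legitimately exceed 1 when the censuses undercount while deaths are well
registered, and it is never capped unless explicitly requested.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np

from .types import (
    EstimationError,
    GGBPoints,
    GGBResult,
    IntercensalDataset,
    SEGResult,
)

__all__ = [
    "ggb_points",
    "fit_ggb",
    "seg_completeness",
    "seg_adj",
    "select_age_window",
    "candidate_windows",
    "ggb_diagnostics",
    "seg_diagnostics",
    "DEFAULT_GGB_WINDOW",
    "DEFAULT_SEG_WINDOW",
    "DEFAULT_SEG_ADJ_WINDOWS",
]

# documented generic age ranges: SEG 55-80, GGB 40-70, combined 50-70
DEFAULT_GGB_WINDOW = (40, 70)
DEFAULT_SEG_WINDOW = (55, 80)
DEFAULT_SEG_ADJ_WINDOWS = ((40, 70), (50, 70))


def ggb_points(ds: IntercensalDataset) -> GGBPoints:
    """Entry, growth and death rates over open age intervals x+ for the GGB fit.

    For each grid age x (5, 10, ..., up to the open bound) the rates are built
    from two-census person-year estimates: N(x), persons reaching exact age x
    per year, is (5N_{x-5} + 5N_x)/10 within each census and the two censuses
    are combined by geometric means; r(x+) = ln(N2(x+)/N1(x+))/t.  Grid ages
    where either census has an empty open interval x+ are dropped with a
    warning.
    """
    c1, c2, d = ds.census1.counts, ds.census2.counts, ds.deaths.counts
    t = ds.t
    cum1 = ds.census1.cumulative_above()
    cum2 = ds.census2.cumulative_above()
    cumd = ds.deaths.cumulative_above()

    ages, entry, growth, death = [], [], [], []
    for i in range(1, len(ds.age)):
        x = int(ds.age[i])
        if cum1[i] <= 0 or cum2[i] <= 0:
            warnings.warn(f"dropping GGB point at age {x}: empty x+ interval")
            continue
        # persons reaching exact age x per year; at the open bound the terminal
        # count stands in for a 5-year group (approximation, see docs)
        nx1 = (c1[i - 1] + c1[i]) / 10.0
        nx2 = (c2[i - 1] + c2[i]) / 10.0
        n_plus = np.sqrt(cum1[i] * cum2[i])
        ages.append(x)
        entry.append(np.sqrt(nx1 * nx2) / n_plus)
        growth.append(np.log(cum2[i] / cum1[i]) / t)
        death.append(cumd[i] / n_plus)
    if not ages:
        raise EstimationError("no usable GGB points")
    return GGBPoints(
        age=np.array(ages),
        entry_rate=np.array(entry),
        growth_rate=np.array(growth),
        death_rate=np.array(death),
        t=t,
    )


def _tls_line(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total least squares) straight line y = a + b z."""
    zm, ym = z.mean(), y.mean()
    m = np.column_stack([z - zm, y - ym])
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    vx, vy = vt[0]
    if vx == 0:
        raise EstimationError("degenerate GGB fit: vertical line")
    slope = vy / vx
    return ym - slope * zm, slope


def _ols_line(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(z, y, 1)
    return float(intercept), float(slope)


def fit_ggb(
    points: GGBPoints,
    age_window: tuple[float, float] = DEFAULT_GGB_WINDOW,
    regression: str = "tls",
    cap: bool = False,
) -> GGBResult:
    """Fit the growth-balance line and convert it to coverage and completeness.

    The left-hand side (entry rate minus growth rate) is regressed on the
    observed death rate, by orthogonal regression by default (both axes carry
    error; ``regression="ols"`` for ordinary least squares).  The intercept is
    (1/t) ln(k1/k2); under the identifiability convention k2 = 1 the
    completeness of death registration is C = sqrt(k1/k2) / slope.
    """
    low, high = age_window
    mask = points.window_mask(low, high)
    if mask.sum() < 3:
        raise EstimationError(
            f"method not applicable: fewer than 3 GGB points in window {age_window}"
        )
    z = points.death_rate[mask]
    y = points.lhs[mask]
    intercept, slope = (_tls_line if regression == "tls" else _ols_line)(z, y)
    if slope <= 0:
        raise EstimationError("method not applicable: non-positive GGB slope")
    resid = y - (intercept + slope * z)
    if regression == "tls":
        resid = resid / np.sqrt(1.0 + slope**2)  # orthogonal distances
    fit_rmse = float(np.sqrt(np.mean(resid**2)))
    k_ratio = float(np.exp(intercept * points.t))
    completeness = float(np.sqrt(k_ratio) / slope)
    capped = False
    if cap and completeness > 1.0:
        completeness, capped = 1.0, True
    return GGBResult(
        intercept=float(intercept),
        slope=float(slope),
        relative_census_coverage=k_ratio,
        completeness=completeness,
        age_window=(low, high),
        fit_rmse=fit_rmse,
        points=points,
        regression=regression,
        capped=capped,
    )


def _seg_chat(
    bounds: np.ndarray,
    d: np.ndarray,
    r: np.ndarray,
    n_obs_group: np.ndarray,
    e_open: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One pass of the extinct-generations reconstruction for a given e(A+).

    Backward recursion on per-year flows N(x) of persons reaching exact age x:
    seeded at the open bound by N(A) = D(A+) exp(r(A+) e(A+)), then
    N(x) = N(x+5) exp(5 r_x) + D_x exp(2.5 r_x).  Group person-years integrate
    an exponential (log-linear) interpolation of adjacent flows — exact for
    exponentially declining populations, where the trapezoid overshoots at old
    ages; the open group is N(A) e(A+).
    """
    n = len(bounds)
    w = np.diff(bounds).astype(float)
    flow = np.empty(n)
    flow[-1] = d[-1] * np.exp(r[-1] * e_open)
    for i in range(n - 2, -1, -1):
        flow[i] = flow[i + 1] * np.exp(w[i] * r[i]) + d[i] * np.exp(w[i] / 2.0 * r[i])
    f1, f2 = flow[:-1], flow[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        logmean = np.where(
            (f1 > 0) & (f2 > 0) & (f1 != f2),
            (f1 - f2) / np.log(np.where(f2 > 0, f1 / np.where(f2 > 0, f2, 1.0), 1.0)),
            (f1 + f2) / 2.0,
        )
    n_hat_group = np.empty(n)
    n_hat_group[:-1] = w * logmean
    n_hat_group[-1] = flow[-1] * e_open
    n_hat_plus = np.cumsum(n_hat_group[::-1])[::-1]
    n_obs_plus = np.cumsum(n_obs_group[::-1])[::-1]
    return n_hat_plus / n_obs_plus, n_hat_plus, n_obs_plus


def _summarize(values: np.ndarray, how: str) -> float:
    return float(np.median(values) if how == "median" else np.mean(values))


def seg_completeness(
    ds: IntercensalDataset,
    age_window: tuple[float, float] = DEFAULT_SEG_WINDOW,
    delta: float | None = None,
    summary: str = "mean",
    cap: bool = False,
) -> SEGResult:
    """Synthetic-extinct-generations completeness estimate.

    Observed deaths are expanded with age-specific growth rates into a
    synthetic population N_hat; the coverage ratio c(a) = N_hat(a+)/N_obs(a+)
    (census populations combined by geometric means) is averaged over the age
    window.  ``delta`` pre-divides the first census by an externally estimated
    coverage ratio k1/k2 (this is how SEG-adj reuses the GGB stage).

    The open-interval life expectancy e(A+) needed to seed the recursion is
    solved self-consistently from the observed open-interval death rate:
    e = c_hat(e)/m(A+), by a secant-accelerated fixed point seeded at 1/m(A+).
    This keeps the estimate invariant to the (unknown) level of completeness.
    """
    c1 = ds.census1.counts.copy()
    if delta is not None:
        if delta <= 0:
            raise EstimationError("delta (k1/k2) must be positive")
        c1 = c1 / float(delta)
    c2 = ds.census2.counts
    d = ds.deaths.counts
    if d[-1] <= 0:
        raise EstimationError("open-interval deaths are zero: cannot seed SEG")
    if np.any(c1 <= 0) or np.any(c2 <= 0):
        raise EstimationError("SEG requires strictly positive census counts")
    bounds = ds.age
    r = np.log(c2 / c1) / ds.t
    n_obs_group = np.sqrt(c1 * c2)

    m_open = d[-1] / n_obs_group[-1]
    low, high = age_window
    amask = (bounds >= low) & (bounds <= high)
    if not amask.any():
        raise EstimationError(f"age window {age_window} contains no group bounds")

    def chat_summary(e):
        chat, _, _ = _seg_chat(bounds, d, r, n_obs_group, e)
        return _summarize(chat[amask], summary)

    # Self-consistent open-interval expectancy.  The reconstructed open-group
    # population is N(A) e = D(A+) e exp(r e); requiring its coverage ratio to
    # match the window's summary c gives  e exp(r e) m(A+) = c, solved by a
    # secant iteration seeded at e = 1/m(A+).  Invariant to the (unknown)
    # level of completeness and to uniform census coverage.
    r_open = r[-1]

    def gap(e):
        return chat_summary(e) - e * np.exp(r_open * e) * m_open

    e0 = 1.0 / m_open
    f0 = gap(e0)
    e1 = max(e0 + f0 / m_open, 0.1)
    for _ in range(40):
        f1 = gap(e1)
        if abs(f1) < 1e-12 or f1 == f0:
            break
        step = f1 * (e1 - e0) / (f1 - f0)
        e0, f0 = e1, f1
        e1 = max(e1 - step, 0.1)
    e_open = e1

    chat, n_hat_plus, n_obs_plus = _seg_chat(bounds, d, r, n_obs_group, e_open)
    completeness = _summarize(chat[amask], summary)
    capped = False
    if cap and completeness > 1.0:
        completeness, capped = 1.0, True
    return SEGResult(
        age=bounds.copy(),
        c_by_age=chat,
        n_hat_by_age=n_hat_plus,
        n_obs_by_age=n_obs_plus,
        completeness=completeness,
        age_window=(low, high),
        e_open=float(e_open),
        delta=delta,
        summary=summary,
        capped=capped,
    )


def seg_adj(
    ds: IntercensalDataset,
    age_window_ggb: tuple[float, float] = DEFAULT_SEG_ADJ_WINDOWS[0],
    age_window_seg: tuple[float, float] = DEFAULT_SEG_ADJ_WINDOWS[1],
    regression: str = "tls",
    summary: str = "mean",
    cap: bool = False,
) -> SEGResult:
    """Two-stage adjusted SEG: GGB estimates relative census coverage, the
    first census is rescaled to the second's level, then SEG is applied."""
    ggb = fit_ggb(ggb_points(ds), age_window_ggb, regression=regression)
    return seg_completeness(
        ds,
        age_window=age_window_seg,
        delta=ggb.relative_census_coverage,
        summary=summary,
        cap=cap,
    )


def candidate_windows(
    points: GGBPoints, min_width: int = 30, min_age: int = 5
) -> list[tuple[int, int]]:
    """All [low, high] windows over the point grid with width >= min_width."""
    ages = [int(a) for a in points.age if a >= min_age]
    return [
        (lo, hi)
        for lo, hi in itertools.combinations(ages, 2)
        if hi - lo >= min_width
    ]


def select_age_window(
    points: GGBPoints,
    candidates: Sequence[tuple[int, int]] | None = None,
    regression: str = "tls",
) -> tuple[int, int]:
    """Grid-search the GGB window minimizing the residual RMSE of the fit.

    Ties are broken by the widest window, then by the lowest lower bound.
    """
    if candidates is None:
        candidates = candidate_windows(points)
    candidates = list(candidates)
    if not candidates:
        raise EstimationError("empty candidate window list")
    scored = []
    for lo, hi in candidates:
        if points.window_mask(lo, hi).sum() < 3:
            raise EstimationError(f"candidate window ({lo}, {hi}) holds fewer than 3 points")
        fit = fit_ggb(points, (lo, hi), regression=regression)
        scored.append((round(fit.fit_rmse, 12), -(hi - lo), lo, (lo, hi)))
    scored.sort()
    return scored[0][3]


def ggb_diagnostics(result: GGBResult) -> dict:
    """Residual diagnostics of the growth-balance line.

    A straightness score near 1 (one minus the residual variance normalized by
    the variance of the left-hand side) means the balance relation is close to
    a straight line, i.e. the data are internally consistent.
    """
    p = result.points
    mask = p.window_mask(*result.age_window)
    y = p.lhs[mask]
    z = p.death_rate[mask]
    resid = y - (result.intercept + result.slope * z)
    var_y = float(np.var(y))
    straightness = 1.0 if var_y == 0 else 1.0 - float(np.var(resid)) / var_y
    worst = int(np.argmax(np.abs(resid)))
    return {
        "age": p.age[mask],
        "residuals": resid,
        "fit_rmse": result.fit_rmse,
        "straightness": float(straightness),
        "max_residual_age": int(p.age[mask][worst]),
    }


def seg_diagnostics(result: SEGResult) -> dict:
    """Slope of c(a) against age over the window.

    Under the methods' assumptions completeness is constant by age, so a
    non-zero slope flags varying census coverage or age misreporting.  With a
    single age group in the window the slope is undefined (reported as NaN).
    """
    low, high = result.age_window
    mask = (result.age >= low) & (result.age <= high)
    ages = result.age[mask].astype(float)
    chat = result.c_by_age[mask]
    slope = float(np.polyfit(ages, chat, 1)[0]) if len(ages) >= 2 else float("nan")
    return {"age": result.age[mask], "c_by_age": chat, "slope": slope}
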