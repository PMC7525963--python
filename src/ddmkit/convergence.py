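"""Convergence of estimates across sources: the RMSE dispersion statistic.

For a cell (region, sex, period) with estimates x_1..x_N from N sources,

    RMSE = sqrt( sum_i (x_i - xbar)^2 / N )

with xbar the mean across sources and the population (divide-by-N)
denominator.  A decline in RMSE between two periods indicates that the
sources' estimates are converging.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import EstimatePanel

__all__ = [
    "rmse",
    "convergence_table",
    "national_summary",
    "convergence_change",
]


def rmse(values: Sequence[float]) -> float:
    """Root mean square deviation of estimates about their own mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("rmse needs at least two estimates")
    if not np.all(np.isfinite(x)):
        raise ValueError("rmse requires finite estimates")
    if x.max() == x.min():  # exactly zero when all sources agree
        return 0.0
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def convergence_table(panel: EstimatePanel, metric: str = "completeness") -> pd.DataFrame:
    """Per-(region, sex, period) RMSE across sources for one metric.

    Cells with fewer than two sources are skipped with a warning.
    """
    sub = panel.for_metric(metric).frame
    if sub.empty:
        raise ValueError(f"panel has no records for metric {metric!r}")
    rows = []
    for (region, sex, period), g in sub.groupby(["region", "sex", "period"], sort=True):
        if len(g) < 2:
            warnings.warn(
                f"skipping cell (region={region!r}, sex={sex!r}, period={period!r}): "
                f"only {len(g)} source(s)"
            )
            continue
        rows.append(
            {
                "region": region,
                "sex": sex,
                "period": period,
                "rmse": rmse(g["value"].to_numpy()),
                "n_sources": len(g),
            }
        )
    return pd.DataFrame(rows, columns=["region", "sex", "period", "rmse", "n_sources"])


def national_summary(
    table: pd.DataFrame,
    mode: str = "mean_of_states",
    national_label: str = "Brazil",
) -> pd.DataFrame:
    """Aggregate state-level RMSEs to one national value per period.

    ``mean_of_states``: equal-weight mean of state RMSEs, sexes pooled by
    averaging (the national row, if present, is excluded).  ``national_row``:
    take the RMSE computed on the national-total rows directly.  Both modes
    are provided because published national figures rarely state which
    aggregation was used; outputs are labelled with the mode.
    """
    if mode == "mean_of_states":
        sub = table[table["region"] != national_label]
    elif mode == "national_row":
        sub = table[table["region"] == national_label]
        if sub.empty:
            raise ValueError(f"table has no rows for region {national_label!r}")
    else:
        raise ValueError("mode must be 'mean_of_states' or 'national_row'")
    out = (
        sub.groupby("period", sort=True)["rmse"]
        .mean()
        .reset_index()
        .assign(mode=mode)
    )
    return out


def convergence_change(
    table: pd.DataFrame,
    period_early: str | None = None,
    period_late: str | None = None,
    tol: float = 0.005,
) -> pd.DataFrame:
    """Change in RMSE between two periods per (region, sex), with a verdict.

    delta = rmse(late) - rmse(early); ``converging`` if delta < -tol,
    ``diverging`` if delta > +tol, else ``stable``.  Cells missing one of the
    periods are skipped with a warning.
    """
    periods = sorted(table["period"].unique())
    if period_early is None or period_late is None:
        if len(periods) != 2:
            raise ValueError(
                f"table has periods {periods}; pass period_early/period_late explicitly"
            )
        period_early, period_late = periods
    rows = []
    for (region, sex), g in table.groupby(["region", "sex"], sort=True):
        by_period = dict(zip(g["period"], g["rmse"]))
        if period_early not in by_period or period_late not in by_period:
            warnings.warn(
                f"skipping (region={region!r}, sex={sex!r}): missing period"
            )
            continue
        delta = by_period[period_late] - by_period[period_early]
        verdict = (
            "converging" if delta < -tol else "diverging" if delta > tol else "stable"
        )
        rows.append(
            {"region": region, "sex": sex, "delta_rmse": delta, "verdict": verdict}
        )
    return pd.DataFrame(rows, columns=["region", "sex", "delta_rmse", "verdict"])
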