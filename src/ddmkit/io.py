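"""CSV readers/writers and age-schedule harmonization.

Intercensal CSV layout (one or more region-sex panels, long over age)::

    region,sex,age,pop1,pop2,deaths
    NORTH,male,0,151200,162400,310.5
    ...

Census dates and unit flags travel in a sidecar YAML file (``<stem>.yaml`` next
to the CSV, or passed explicitly) with keys ``census1_time``, ``census2_time``
and optionally ``deaths_are_period_totals`` (defaults false: deaths are mean
annual counts).
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import AgeGroupedCounts, EstimatePanel, IntercensalDataset

__all__ = [
    "harmonize",
    "read_intercensal_csv",
    "read_intercensal_csv_all",
    "write_intercensal_csv",
    "read_estimate_panel_csv",
    "write_estimate_panel_csv",
]

log = logging.getLogger(__name__)

INTERCENSAL_COLUMNS = ("region", "sex", "age", "pop1", "pop2", "deaths")


def harmonize(counts: AgeGroupedCounts, target_bounds: Sequence[int]) -> AgeGroupedCounts:
    """Re-group counts onto coarser age bounds, conserving totals.

    ``target_bounds`` must be a subset of the source bounds (a nested
    coarsening); the last target bound starts the new open interval, which
    absorbs every older source group.
    """
    target = np.asarray(target_bounds, dtype=int)
    src = counts.age
    missing = sorted(set(target.tolist()) - set(src.tolist()))
    if missing:
        raise ValueError(
            f"target bounds {missing} are not bounds of the source schedule; "
            "harmonize only supports nested coarsenings"
        )
    if not np.all(np.diff(target) > 0):
        raise ValueError("target bounds must be strictly increasing")
    idx = np.searchsorted(target, src, side="right") - 1
    out = np.zeros(len(target))
    valid = idx >= 0
    np.add.at(out, idx[valid], counts.counts[valid])
    if not valid.all():
        raise ValueError(
            "source groups below the first target bound cannot be assigned"
        )
    return AgeGroupedCounts(
        age=target,
        counts=out,
        sex=counts.sex,
        reference_time=counts.reference_time,
        kind=counts.kind,
    )


def _load_config(path: Path, config) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    if config is not None:
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    for suffix in (".yaml", ".yml"):
        sidecar = path.with_suffix(suffix)
        if sidecar.exists():
            with open(sidecar) as fh:
                return yaml.safe_load(fh) or {}
    raise ValueError(
        f"no sidecar config found for {path}; pass census dates via `config`"
    )


def _validate_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in INTERCENSAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("pop1", "pop2", "deaths"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if (vals < 0).any():
            row = int(df.index[vals < 0][0])
            raise ValueError(f"{path}: negative count in column {col!r}, row {row}")


def _dataset_from_group(sub: pd.DataFrame, cfg: dict, region: str, sex: str) -> IntercensalDataset:
    sub = sub.sort_values("age")
    ages = sub["age"].to_numpy(dtype=int)
    if len(np.unique(ages)) != len(ages):
        raise ValueError(f"duplicate age bounds for region={region!r} sex={sex!r}")
    t1 = float(cfg["census1_time"])
    t2 = float(cfg["census2_time"])
    t = t2 - t1
    if t <= 0:
        raise ValueError("census2_time must be after census1_time")
    deaths = sub["deaths"].to_numpy(dtype=float)
    if cfg.get("deaths_are_period_totals") or cfg.get("total_deaths"):
        deaths = deaths / t
    mk = lambda counts, time, kind: AgeGroupedCounts(
        ages, counts, sex=sex, reference_time=time, kind=kind
    )
    return IntercensalDataset(
        census1=mk(sub["pop1"].to_numpy(dtype=float), t1, "population"),
        census2=mk(sub["pop2"].to_numpy(dtype=float), t2, "population"),
        deaths=mk(deaths, (t1 + t2) / 2.0, "deaths"),
        region=region,
        sex=sex,
    )


def read_intercensal_csv_all(path, config=None) -> dict[tuple[str, str], IntercensalDataset]:
    """Read every (region, sex) panel of an intercensal CSV into datasets."""
    path = Path(path)
    cfg = _load_config(path, config)
    df = pd.read_csv(path, comment="#")
    _validate_table(df, path)
    out: dict[tuple[str, str], IntercensalDataset] = {}
    for (region, sex), sub in df.groupby(["region", "sex"], sort=True):
        out[(str(region), str(sex))] = _dataset_from_group(sub, cfg, str(region), str(sex))
    if not out:
        raise ValueError(f"{path}: empty file")
    return out


def read_intercensal_csv(path, config=None, region=None, sex=None) -> IntercensalDataset:
    """Read a single (region, sex) panel; error if the file is ambiguous."""
    groups = read_intercensal_csv_all(path, config)
    if region is not None or sex is not None:
        groups = {
            k: v
            for k, v in groups.items()
            if (region is None or k[0] == region) and (sex is None or k[1] == sex)
        }
    if len(groups) != 1:
        raise ValueError(
            f"{path}: expected exactly one (region, sex) panel, found "
            f"{sorted(groups)}; use region=/sex= or read_intercensal_csv_all"
        )
    return next(iter(groups.values()))


def write_intercensal_csv(datasets, path, config_path=None) -> None:
    """Write one or more datasets back to the intercensal CSV + sidecar layout.

    Inverse of :func:`read_intercensal_csv_all` on the data model (deaths are
    written as mean annual counts).
    """
    if isinstance(datasets, IntercensalDataset):
        datasets = [datasets]
    else:
        datasets = list(datasets.values()) if isinstance(datasets, Mapping) else list(datasets)
    path = Path(path)
    rows = []
    ref = datasets[0]
    for ds in datasets:
        if (ds.census1.reference_time, ds.census2.reference_time) != (
            ref.census1.reference_time,
            ref.census2.reference_time,
        ):
            raise ValueError("all datasets in one file must share census dates")
        for i, age in enumerate(ds.age):
            rows.append(
                {
                    "region": ds.region,
                    "sex": ds.sex,
                    "age": int(age),
                    "pop1": ds.census1.counts[i],
                    "pop2": ds.census2.counts[i],
                    "deaths": ds.deaths.counts[i],
                }
            )
    pd.DataFrame(rows, columns=list(INTERCENSAL_COLUMNS)).to_csv(path, index=False)
    cfg = {
        "census1_time": float(ref.census1.reference_time),
        "census2_time": float(ref.census2.reference_time),
        "deaths_are_period_totals": False,
    }
    cfg_path = Path(config_path) if config_path else path.with_suffix(".yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)


def read_estimate_panel_csv(path) -> EstimatePanel:
    """Read a long-format estimate panel (region,sex,period,source,metric,value)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(EstimatePanel.COLUMNS))
    if df.empty:
        warnings.warn(f"{path}: empty estimate panel", stacklevel=2)
        log.warning("%s: empty estimate panel", path)
        df = pd.DataFrame(columns=list(EstimatePanel.COLUMNS))
    return EstimatePanel(df)


def write_estimate_panel_csv(panel: EstimatePanel, path) -> None:
    panel.frame.to_csv(path, index=False)
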