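"""End-to-end orchestration: estimate completeness, adjust rates, build life
tables, and optionally compare estimate panels — from one config mapping.

Config keys (YAML file or dict)::

    input: data.csv              # intercensal CSV (sidecar YAML for dates), or
    scenario: {...}              # inline synthetic-scenario fields instead
    methods: [ggb, seg, seg-adj] # any subset; default all three
    ggb_window: [40, 70]
    seg_window: [55, 80]
    seg_adj_windows: [[40, 70], [50, 70]]
    auto_window: false           # grid-search the GGB window by fit RMSE
    cap: false                   # cap completeness at 1.0
    regression: tls              # or ols
    summary: mean                # or median, for the SEG c(a) series
    lifetable: true              # build adjusted life tables per method
    panel: panel.csv             # optional estimate panel for RMSE comparison
    metric: completeness
    out_dir: results/

Every run writes ``results.csv``, per-method life tables, and ``run_log.json``
recording each default actually used.  Any stage error aborts the run and
removes partial outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import ddm
from .convergence import convergence_change, convergence_table
from .io import read_estimate_panel_csv, read_intercensal_csv_all, write_intercensal_csv
from .lifetable import adjusted_rates, build_life_table
from .simulate import SilerParams, SyntheticScenario, simulate_dataset
from .types import IntercensalDataset

__all__ = ["run_pipeline", "estimate_all_methods"]

log = logging.getLogger(__name__)

METHODS = ("ggb", "seg", "seg-adj")


def _load_config(config) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def _scenario_from_config(spec: Mapping) -> SyntheticScenario:
    spec = dict(spec)
    if "mortality" in spec and isinstance(spec["mortality"], Mapping):
        spec["mortality"] = SilerParams(**spec["mortality"])
    if "misreporting" in spec:
        spec["misreporting"] = tuple(spec["misreporting"])
    if "census_coverage" in spec:
        spec["census_coverage"] = tuple(spec["census_coverage"])
    return SyntheticScenario(**spec)


def estimate_all_methods(
    ds: IntercensalDataset,
    methods=METHODS,
    ggb_window=ddm.DEFAULT_GGB_WINDOW,
    seg_window=ddm.DEFAULT_SEG_WINDOW,
    seg_adj_windows=ddm.DEFAULT_SEG_ADJ_WINDOWS,
    auto_window: bool = False,
    cap: bool = False,
    regression: str = "tls",
    summary: str = "mean",
) -> list[dict]:
    """Run the requested estimators on one dataset; one result record each."""
    records = []
    points = ddm.ggb_points(ds)
    if auto_window:
        ggb_window = ddm.select_age_window(points, regression=regression)
        log.info("auto-selected GGB window %s for %s/%s", ggb_window, ds.region, ds.sex)
    for method in methods:
        rec = {
            "region": ds.region,
            "sex": ds.sex,
            "method": method,
            "completeness": float("nan"),
            "intercept": float("nan"),
            "slope": float("nan"),
            "k_ratio": float("nan"),
            "window_low": float("nan"),
            "window_high": float("nan"),
            "fit_rmse": float("nan"),
        }
        if method == "ggb":
            fit = ddm.fit_ggb(points, ggb_window, regression=regression, cap=cap)
            rec.update(
                completeness=fit.completeness,
                intercept=fit.intercept,
                slope=fit.slope,
                k_ratio=fit.relative_census_coverage,
                window_low=fit.age_window[0],
                window_high=fit.age_window[1],
                fit_rmse=fit.fit_rmse,
            )
        elif method == "seg":
            res = ddm.seg_completeness(ds, seg_window, summary=summary, cap=cap)
            rec.update(
                completeness=res.completeness,
                window_low=res.age_window[0],
                window_high=res.age_window[1],
            )
        elif method == "seg-adj":
            win_ggb, win_seg = seg_adj_windows
            if auto_window:
                win_ggb = ggb_window
            res = ddm.seg_adj(
                ds, tuple(win_ggb), tuple(win_seg),
                regression=regression, summary=summary, cap=cap,
            )
            rec.update(
                completeness=res.completeness,
                k_ratio=res.delta,
                window_low=res.age_window[0],
                window_high=res.age_window[1],
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        records.append(rec)
    return records


def run_pipeline(config) -> dict:
    """Run estimators -> rate adjustment -> life tables -> optional comparison.

    Returns a bundle with the results frame, per-method life tables, and the
    run log (also written to ``out_dir``).
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    run_log: dict = {"stages": [], "decisions": {}}
    try:
        return _run_pipeline_inner(cfg, out_dir, written, run_log)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        stage = run_log["stages"][-1] if run_log["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _run_pipeline_inner(cfg, out_dir, written, run_log) -> dict:
    methods = tuple(cfg.get("methods", METHODS))
    decisions = {
        "methods": list(methods),
        "ggb_window": list(cfg.get("ggb_window", ddm.DEFAULT_GGB_WINDOW)),
        "seg_window": list(cfg.get("seg_window", ddm.DEFAULT_SEG_WINDOW)),
        "seg_adj_windows": [list(w) for w in cfg.get("seg_adj_windows", ddm.DEFAULT_SEG_ADJ_WINDOWS)],
        "auto_window": bool(cfg.get("auto_window", False)),
        "cap": bool(cfg.get("cap", False)),
        "regression": cfg.get("regression", "tls"),
        "summary": cfg.get("summary", "mean"),
    }
    run_log["decisions"] = decisions

    run_log["stages"].append("load")
    if "input" in cfg:
        datasets = read_intercensal_csv_all(cfg["input"], cfg.get("input_config"))
    elif "scenario" in cfg:
        scenario = _scenario_from_config(cfg["scenario"])
        ds, truth = simulate_dataset(scenario)
        datasets = {(ds.region, ds.sex): ds}
        run_log["truth"] = {"q45_15": truth.q45_15, "e0": truth.e0}
        sim_path = out_dir / "simulated_input.csv"
        write_intercensal_csv(ds, sim_path)
        written += [sim_path, sim_path.with_suffix(".yaml")]
    else:
        raise ValueError("config needs either 'input' or 'scenario'")

    run_log["stages"].append("estimate")
    records = []
    for ds in datasets.values():
        records += estimate_all_methods(
            ds,
            methods=methods,
            ggb_window=tuple(decisions["ggb_window"]),
            seg_window=tuple(decisions["seg_window"]),
            seg_adj_windows=tuple(tuple(w) for w in decisions["seg_adj_windows"]),
            auto_window=decisions["auto_window"],
            cap=decisions["cap"],
            regression=decisions["regression"],
            summary=decisions["summary"],
        )
    results = pd.DataFrame(records)
    res_path = out_dir / "results.csv"
    results.to_csv(res_path, index=False, float_format="%.10g")
    written.append(res_path)

    life_tables = {}
    if cfg.get("lifetable", True):
        run_log["stages"].append("lifetable")
        summaries = []
        for ds in datasets.values():
            for rec in records:
                if (rec["region"], rec["sex"]) != (ds.region, ds.sex):
                    continue
                mx = adjusted_rates(ds, rec["completeness"])
                lt = build_life_table(ds.age, mx)
                key = (ds.region, ds.sex, rec["method"])
                life_tables[key] = lt
                frame = lt.to_frame()
                lt_path = out_dir / f"lifetable_{ds.region}_{ds.sex}_{rec['method']}.csv"
                frame.to_csv(lt_path, index=False, float_format="%.10g")
                written.append(lt_path)
                summaries.append(
                    {
                        "region": ds.region,
                        "sex": ds.sex,
                        "method": rec["method"],
                        "completeness": rec["completeness"],
                        "q45_15": lt.q45_15,
                        "e0": lt.e0,
                    }
                )
        summary_path = out_dir / "lifetable_summary.csv"
        pd.DataFrame(summaries).to_csv(summary_path, index=False, float_format="%.10g")
        written.append(summary_path)
        run_log["lifetable_summary"] = summaries

    comparison = None
    if cfg.get("panel"):
        run_log["stages"].append("compare")
        panel = read_estimate_panel_csv(cfg["panel"])
        table = convergence_table(panel, cfg.get("metric", "completeness"))
        comparison = table
        cmp_path = out_dir / "rmse.csv"
        table.to_csv(cmp_path, index=False, float_format="%.10g")
        written.append(cmp_path)
        if table["period"].nunique() == 2:
            change = convergence_change(table)
            chg_path = out_dir / "rmse_change.csv"
            change.to_csv(chg_path, index=False, float_format="%.10g")
            written.append(chg_path)

    run_log["stages"].append("done")
    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return {
        "results": results,
        "life_tables": life_tables,
        "comparison": comparison,
        "run_log": run_log,
        "out_dir": out_dir,
    }
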