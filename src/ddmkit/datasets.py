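"""Bundled reference data.

The package ships one small real panel: published male adult-mortality
probabilities (45q15) for the 26 Brazilian states and the Federal District,
as produced by three independent estimation pipelines — the national
statistics office (IBGE), the Global Burden of Disease study (IHME) and an
academic death-distribution analysis (DDM-R) — for the 1980/1991 and
2000/2010 intercensal periods, plus a Bayesian small-area model and the raw
(uncorrected) Mortality Information System for 2010.  It exercises the
convergence module on real inputs where estimates from different producers
genuinely disagree.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import EstimatePanel

__all__ = ["load_brazil_male_45q15_panel"]


def load_brazil_male_45q15_panel(drop_extra_sources: bool = False) -> EstimatePanel:
    """Published male 45q15 estimates for Brazilian states, by source and period.

    With ``drop_extra_sources=True`` only the three sources available in both
    intercensal periods (DDM-R, IHME, IBGE) are kept, which is the panel used
    for two-period convergence analysis.
    """
    ref = resources.files("ddmkit.data").joinpath("brazil_male_45q15_panel.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh)
    if drop_extra_sources:
        df = df[df["source"].isin(["DDM-R", "IHME", "IBGE"])]
    return EstimatePanel(df.drop(columns=["macro_region"]))
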