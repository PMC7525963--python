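"""Generative model of defective vital registration.

A stable (exponentially growing) population under a Siler mortality schedule is
projected between two census dates; deaths are then thinned by a true
registration completeness c(x), censuses are scaled by coverage factors k1/k2,
and counts can be perturbed by Preston-style age misreporting.  Every scenario
carries its analytic truth (45q15, e0, true completeness), so estimators can be
validated by parameter recovery without any external data.

The Siler hazard is

    mu(x) = a1 * exp(-b1 * x) + c + a2 * exp(b2 * x)

covering infant decline, a background plateau and senescent (Gompertz) rise.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import write_intercensal_csv
from .types import AgeGroupedCounts, IntercensalDataset

__all__ = [
    "SilerParams",
    "SyntheticScenario",
    "SimulatedTruth",
    "simulate_truth",
    "observe",
    "simulate_dataset",
    "misreport_ages",
    "make_fixture_suite",
    "DEFAULT_SILER",
]

_MAX_AGE = 120.0  # upper support of the hazard integration grid
_FINE_STEP = 0.05  # years; fine grid used inside each single-year cell

MISREPORTING_PATTERNS = ("none", "overstate", "understate", "symmetric")


@dataclass(frozen=True)
class SilerParams:
    """Five-parameter Siler hazard; rates per year."""

    a1: float = 0.012
    b1: float = 1.1
    c: float = 0.0010
    a2: float = 3.0e-5
    b2: float = 0.102

    def hazard(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a1 * np.exp(-self.b1 * x) + self.c + self.a2 * np.exp(self.b2 * x)

    def survival(self, x) -> np.ndarray:
        """Closed-form survivorship S(x) from the integrated hazard."""
        x = np.asarray(x, dtype=float)
        h = (
            self.a1 / self.b1 * (1.0 - np.exp(-self.b1 * x))
            + self.c * x
            + self.a2 / self.b2 * (np.exp(self.b2 * x) - 1.0)
        )
        return np.exp(-h)

    def q45_15(self) -> float:
        """Probability of dying between exact ages 15 and 60: 1 - S(60)/S(15)."""
        s = self.survival(np.array([15.0, 60.0]))
        return float(1.0 - s[1] / s[0])

    def e0(self) -> float:
        """Life expectancy at birth by numerical integration of S(x)."""
        x = np.arange(0.0, _MAX_AGE + _FINE_STEP, _FINE_STEP)
        return float(np.trapezoid(self.survival(x), x))

    def life_expectancy_at(self, age: float) -> float:
        x = np.arange(age, _MAX_AGE + _FINE_STEP, _FINE_STEP)
        s = self.survival(x)
        return float(np.trapezoid(s, x) / s[0])


#: Default schedules, calibrated so that e0 is close to 70 years (male) and a
#: few years higher for females.
DEFAULT_SILER = {
    "male": SilerParams(),
    "female": SilerParams(a1=0.010, b1=1.1, c=0.0006, a2=1.8e-5, b2=0.105),
    "total": SilerParams(),
}


@dataclass
class FertilitySchedule:
    """Gaussian-shaped age-specific birth rates used by the cohort-component mode.

    ``rate(x)`` is births per person of age x per year (single-sex model).
    """

    level: float = 2.2  # lifetime births per person surviving the span
    mean_age: float = 27.0
    sd: float = 6.0
    low: float = 12.0
    high: float = 50.0

    def rates(self, ages: np.ndarray) -> np.ndarray:
        w = np.exp(-0.5 * ((ages - self.mean_age) / self.sd) ** 2)
        w[(ages < self.low) | (ages >= self.high)] = 0.0
        total = w.sum()
        return self.level * w / total if total > 0 else w


@dataclass
class SyntheticScenario:
    """Full generative specification of one defective-registration experiment.

    ``true_completeness`` may be a scalar (constant by age) or an array aligned
    with the 5-year output groups.  ``migration`` is a net rate per year on
    single-year ages (array of length ``open_age`` or callable age -> rate).
    Deterministic observation is the default so that recovery tests carry no
    Monte-Carlo noise; ``stochastic=True`` switches death registration to
    seeded binomial thinning.
    """

    mortality: SilerParams = field(default_factory=SilerParams)
    growth_rate: float = 0.01
    migration: np.ndarray | Callable | None = None
    fertility: FertilitySchedule | None = None  # set -> cohort-component mode
    true_completeness: float | np.ndarray = 1.0
    census_coverage: tuple[float, float] = (1.0, 1.0)
    misreporting: tuple[str, float] = ("none", 0.0)
    t: float = 10.0
    census1_time: float = 2000.0
    open_age: int = 80
    radix: float = 1000.0  # births per year at the first census date
    sex: str = "male"
    region: str = "synthetic"
    stochastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.open_age % 5 or self.open_age < 30:
            raise ValueError("open_age must be a multiple of 5, >= 30")
        pattern, intensity = self.misreporting
        if pattern not in MISREPORTING_PATTERNS:
            raise ValueError(f"misreporting pattern must be one of {MISREPORTING_PATTERNS}")
        if not 0.0 <= intensity <= 1.0:
            raise ValueError("misreporting intensity must be in [0, 1]")
        k1, k2 = self.census_coverage
        if k1 <= 0 or k2 <= 0:
            raise ValueError("census coverage factors must be positive")

    @property
    def bounds(self) -> np.ndarray:
        return np.arange(0, self.open_age + 5, 5)

    def completeness_by_group(self) -> np.ndarray:
        c = np.asarray(self.true_completeness, dtype=float)
        if c.ndim == 0:
            c = np.full(len(self.bounds), float(c))
        if c.shape != self.bounds.shape:
            raise ValueError("true_completeness array must match the 5-year groups")
        if np.any(c <= 0):
            raise ValueError("true completeness must be positive")
        return c

    def migration_rates(self, ages: np.ndarray) -> np.ndarray:
        if self.migration is None:
            return np.zeros_like(ages, dtype=float)
        if callable(self.migration):
            return np.asarray([self.migration(a) for a in ages], dtype=float)
        m = np.asarray(self.migration, dtype=float)
        if len(m) != len(ages):
            raise ValueError("migration array must cover single-year ages 0..open_age-1")
        return m


@dataclass
class SimulatedTruth:
    """True (fully registered, fully enumerated) counts plus analytic summaries."""

    census1: AgeGroupedCounts
    census2: AgeGroupedCounts
    deaths: AgeGroupedCounts  # mean annual intercensal deaths
    q45_15: float
    e0: float
    crude_rates: np.ndarray  # true m(x) per 5-year group at mid-period


def _cell_integrals(fn: Callable[[np.ndarray], np.ndarray], edges: np.ndarray) -> np.ndarray:
    """Integrate fn over each [edges[i], edges[i+1]) cell on a fine sub-grid."""
    out = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        x = np.linspace(edges[i], edges[i + 1], max(int((edges[i + 1] - edges[i]) / _FINE_STEP), 2) + 1)
        out[i] = np.trapezoid(fn(x), x)
    return out


def _group_single_years(values: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Sum single-year values (ages 0..len-1) into groups with an open tail."""
    out = np.zeros(len(bounds))
    idx = np.clip(np.searchsorted(bounds, np.arange(len(values)), side="right") - 1, 0, None)
    np.add.at(out, idx, values)
    return out


def _stable_truth(s: SyntheticScenario) -> SimulatedTruth:
    r = s.growth_rate
    edges = np.arange(0.0, _MAX_AGE + 1.0)  # single-year cells to the hazard's support
    dens = _cell_integrals(lambda x: np.exp(-r * x) * s.mortality.survival(x), edges)
    ddens = _cell_integrals(
        lambda x: np.exp(-r * x) * s.mortality.survival(x) * s.mortality.hazard(x), edges
    )
    ages = np.arange(len(dens), dtype=float)

    # net migration accumulated along each cohort present at census2 / mid-period
    mig = s.migration_rates(np.arange(int(_MAX_AGE)))
    def cohort_mig(age_at, span):
        # integral of m over the cohort's ages during the last `span` years
        lo = np.maximum(age_at - span, 0.0)
        cum = np.concatenate([[0.0], np.cumsum(mig)])
        a = np.clip(age_at, 0, len(mig)).astype(int)
        l = np.clip(lo, 0, len(mig)).astype(int)
        return cum[a] - cum[l]

    pop1 = s.radix * dens
    pop2 = pop1 * np.exp(r * s.t) * np.exp(cohort_mig(ages, s.t))
    # mean annual birth flow over the period relative to census1
    bbar = (np.exp(r * s.t) - 1.0) / (r * s.t) if abs(r) > 1e-12 else 1.0
    deaths = s.radix * bbar * ddens * np.exp(0.5 * cohort_mig(ages, s.t))

    bounds = s.bounds
    mk = lambda v, time, kind: AgeGroupedCounts(
        bounds, _group_single_years(v, bounds), sex=s.sex, reference_time=time, kind=kind
    )
    c1 = mk(pop1, s.census1_time, "population")
    c2 = mk(pop2, s.census1_time + s.t, "population")
    dd = mk(deaths, s.census1_time + s.t / 2.0, "deaths")
    mx = dd.counts / np.sqrt(c1.counts * c2.counts)
    return SimulatedTruth(c1, c2, dd, s.mortality.q45_15(), s.mortality.e0(), mx)


def _cohort_component_truth(s: SyntheticScenario) -> SimulatedTruth:
    """Single-year annual projection with births; non-stable test bed."""
    n_ages = int(_MAX_AGE)
    ages = np.arange(n_ages, dtype=float)
    # start from the mortality schedule's stable structure
    surv_to = s.mortality.survival(ages + 0.5)
    pop = s.radix * np.exp(-s.growth_rate * ages) * surv_to
    q1 = 1.0 - s.mortality.survival(ages + 1.0) / s.mortality.survival(ages)
    asfr = s.fertility.rates(ages) if s.fertility else np.zeros(n_ages)
    mig = s.migration_rates(np.arange(n_ages))

    pop1 = pop.copy()
    deaths_total = np.zeros(n_ages)
    steps = int(round(s.t))
    for _ in range(steps):
        deaths = pop * q1
        deaths_total += deaths
        births = float(np.sum(asfr * pop))
        survivors = (pop - deaths) * np.exp(mig)
        newpop = np.empty_like(pop)
        newpop[1:] = survivors[:-1]
        newpop[-1] += survivors[-1]  # terminal cell accumulates
        newpop[0] = births * (1.0 - q1[0] * 0.5)
        pop = newpop
    bounds = s.bounds
    mk = lambda v, time, kind: AgeGroupedCounts(
        bounds, _group_single_years(v, bounds), sex=s.sex, reference_time=time, kind=kind
    )
    c1 = mk(pop1, s.census1_time, "population")
    c2 = mk(pop, s.census1_time + s.t, "population")
    dd = mk(deaths_total / steps, s.census1_time + s.t / 2.0, "deaths")
    mx = dd.counts / np.sqrt(np.maximum(c1.counts * c2.counts, 1e-300))
    return SimulatedTruth(c1, c2, dd, s.mortality.q45_15(), s.mortality.e0(), mx)


def simulate_truth(s: SyntheticScenario) -> SimulatedTruth:
    """True population at both census dates plus true intercensal deaths.

    Stable-population mode unless the scenario carries a fertility schedule,
    in which case a cohort-component projection is run.
    """
    haz = s.mortality.hazard(np.arange(0.0, _MAX_AGE, 1.0))
    if not np.all(np.isfinite(haz)) or np.any(haz < 0):
        raise ValueError("divergent or negative hazard parameters")
    if s.fertility is not None:
        return _cohort_component_truth(s)
    return _stable_truth(s)


def misreport_ages(
    counts: AgeGroupedCounts, pattern: str, intensity: float, seed: int | None = None
) -> AgeGroupedCounts:
    """Transfer a fraction of each group's count to adjacent groups.

    ``overstate`` moves the affected fraction one group up, ``understate`` one
    group down, ``symmetric`` splits it equally both ways.  Boundary groups
    reflect inward (no count can leave the age range), so totals are conserved
    exactly.  Deterministic; ``seed`` is accepted for interface symmetry.
    """
    if pattern not in MISREPORTING_PATTERNS:
        raise ValueError(f"unknown misreporting pattern {pattern!r}")
    if pattern == "none" or intensity == 0:
        return counts.with_counts(counts.counts)
    v = counts.counts
    moved = v * float(intensity)
    up = np.zeros_like(v)
    down = np.zeros_like(v)
    if pattern == "overstate":
        up = moved
    elif pattern == "understate":
        down = moved
    else:  # symmetric
        up = moved / 2.0
        down = moved / 2.0
    out = v - up - down
    out[1:] += up[:-1]
    out[-1] += up[-1]  # top reflects inward
    out[:-1] += down[1:]
    out[0] += down[0]  # bottom reflects inward
    return counts.with_counts(out)


def observe(s: SyntheticScenario, truth: SimulatedTruth) -> IntercensalDataset:
    """Degrade the truth into an observed intercensal dataset.

    Deaths are scaled by c(x) (deterministic) or binomially thinned with
    probability c(x) (stochastic, seeded); census i is scaled by its coverage
    factor k_i; age misreporting is applied last to all three schedules.
    """
    c = s.completeness_by_group()
    k1, k2 = s.census_coverage
    if s.stochastic:
        rng = np.random.default_rng(s.seed)
        n = np.round(truth.deaths.counts * s.t).astype(np.int64)
        d_obs = rng.binomial(n, np.clip(c, 0, 1)) / s.t
    else:
        d_obs = truth.deaths.counts * c
    census1 = truth.census1.scaled(k1)
    census2 = truth.census2.scaled(k2)
    deaths = truth.deaths.with_counts(d_obs)
    pattern, intensity = s.misreporting
    if pattern != "none" and intensity > 0:
        census1 = misreport_ages(census1, pattern, intensity)
        census2 = misreport_ages(census2, pattern, intensity)
        deaths = misreport_ages(deaths, pattern, intensity)
    return IntercensalDataset(
        census1=census1, census2=census2, deaths=deaths, region=s.region, sex=s.sex
    )


def simulate_dataset(s: SyntheticScenario) -> tuple[IntercensalDataset, SimulatedTruth]:
    """Convenience wrapper: truth plus its observed, degraded dataset."""
    truth = simulate_truth(s)
    return observe(s, truth), truth


# ---------------------------------------------------------------------------
# fixture battery
# ---------------------------------------------------------------------------

def standard_scenarios(seed: int = 0) -> dict[str, SyntheticScenario]:
    """The battery of named degradation scenarios used for validation."""
    base = dict(mortality=DEFAULT_SILER["male"], growth_rate=0.01, seed=seed)
    young_out = np.zeros(120)
    young_out[15:35] = -0.005  # net out-migration at labour ages
    rising_c = np.clip(0.5 + 0.02 * np.arange(17), None, 0.95)
    scn = {
        "perfect": SyntheticScenario(**base),
        "c050": SyntheticScenario(true_completeness=0.5, **base),
        "c070": SyntheticScenario(true_completeness=0.7, **base),
        "c090": SyntheticScenario(true_completeness=0.9, **base),
        "coverage_ratio_105": SyntheticScenario(
            true_completeness=0.8, census_coverage=(1.05, 1.0), **base
        ),
        "census_undercount": SyntheticScenario(
            true_completeness=1.0, census_coverage=(0.9, 0.9), **base
        ),
        "age_varying_c": SyntheticScenario(true_completeness=rising_c, **base),
        "migration_young": SyntheticScenario(
            true_completeness=0.9, migration=young_out, **base
        ),
        "misreport_overstate": SyntheticScenario(
            true_completeness=0.9, misreporting=("overstate", 0.1), **base
        ),
        "misreport_understate": SyntheticScenario(
            true_completeness=0.9, misreporting=("understate", 0.1), **base
        ),
        "misreport_symmetric": SyntheticScenario(
            true_completeness=0.9, misreporting=("symmetric", 0.1), **base
        ),
    }
    return scn


def make_fixture_suite(out_dir, seed: int = 0) -> list[Path]:
    """Write the scenario battery as intercensal CSVs plus a truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    written = []
    for name, s in standard_scenarios(seed=seed).items():
        ds, truth = simulate_dataset(s)
        csv_path = out_dir / f"{name}.csv"
        write_intercensal_csv(ds, csv_path)
        written.append(csv_path)
        c = s.completeness_by_group()
        manifest[name] = {
            "true_completeness_mean": float(np.mean(c)),
            "true_completeness_by_age": [float(v) for v in c],
            "census_coverage": [float(k) for k in s.census_coverage],
            "growth_rate": float(s.growth_rate),
            "misreporting": list(s.misreporting),
            "q45_15": round(truth.q45_15, 10),
            "e0": round(truth.e0, 10),
            "seed": int(s.seed),
        }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest_path)
    return written
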