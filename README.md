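# ddmkit

Death distribution methods for populations with defective vital registration:
estimate the **completeness of death registration** from two census age
distributions and intercensal death counts, turn it into corrected **adult
mortality (45q15)** and **life expectancy at birth (e0)**, and measure how far
competing estimate producers agree.  Everything is validated against a
built-in synthetic vital-registration simulator with analytic truth, so no
external data are required.

The package is aimed at demographers and public-health analysts working on
countries or subnational regions where death counts are under-registered and
census coverage is imperfect — settings where official, academic and
international estimates of the same mortality level routinely disagree.

## Methods

**General growth balance (GGB).** In a closed population, for every open age
interval x+, the entry rate minus the growth rate equals the death rate.  With
under-registered deaths and censuses of unequal coverage the observed
quantities obey

```
N(x)/N(x+) − r(x+) = (1/t)·ln(k1/k2) + [(k1·k2)^(1/2)/C] · D(x+)/N(x+)
```

so a straight-line fit (orthogonal regression by default) of the left-hand
side on the observed death rate identifies the relative census coverage k1/k2
from the intercept and the completeness C of death registration from the
slope.

**Synthetic extinct generations (SEG).** Age-specific growth rates expand the
observed deaths above age a into a synthetic population N̂(a+); the ratio
ĉ(a) = N̂(a+)/N⁰(a+) to the census-based population is the completeness at
that age, summarized by its mean over an age window.  **SEG-adj** first runs
GGB, rescales the first census by the estimated k1/k2, then applies SEG —
robust to censuses of unequal coverage.  Default windows: GGB 40–70, SEG
55–80, SEG-adj 50–70, with an RMSE-minimizing grid search available.

Completeness is measured *relative to census coverage* and is deliberately
never capped: values above 100% are a diagnostic of census undercount, not an
error.

**Life tables.** Adjusted central death rates m(x) = (D(x)/C)/PY(x) feed a
conventional abridged life table; 45q15 = 1 − l(60)/l(15) and e0 = T(0)/l(0).
A top-down rescaling operation proportionally adjusts subnational death
counts to an independent national total, with optional exempt regions.

**Convergence.** For each region, sex and period the dispersion of N sources'
estimates is RMSE = sqrt(Σᵢ(xᵢ − x̄)²/N); a decline between periods means the
sources are converging.

**Simulator.** A stable (or cohort-component) population under a Siler hazard
μ(x) = a₁e^(−b₁x) + c + a₂e^(b₂x), degraded by a true completeness c(x)
(deterministic scaling or seeded binomial thinning), census coverage factors
k1/k2, and Preston-style age misreporting (net overstatement, net
understatement, symmetric).  Every scenario carries closed-form 45q15 and
numerically exact e0, enabling parameter-recovery validation of all
estimators.

## Worked example

```python
from ddmkit import (SyntheticScenario, simulate_dataset, ggb_points, fit_ggb,
                    seg_completeness, seg_adj, adjusted_rates, build_life_table)

observed, truth = simulate_dataset(SyntheticScenario(true_completeness=0.70))
print(fit_ggb(ggb_points(observed)).completeness)   # 0.708
print(seg_completeness(observed).completeness)      # 0.692
c_hat = seg_adj(observed).completeness              # 0.697
lt = build_life_table(observed.age, adjusted_rates(observed, c_hat))
print(lt.q45_15, lt.e0)                             # 0.1629, 70.50
```

Only 70% of simulated deaths were registered; all three methods recover the
0.70 within a point, and the completeness-adjusted life table reproduces the
generating schedule's analytic 45q15 = 0.1626 and e0 = 70.57, where taking
the registry at face value would have claimed 45q15 = 0.1165 and e0 = 75.35.
The scripts in `examples/` walk through each capability (estimation, census
coverage problems, life tables, convergence of published Brazilian estimates,
assumption violations) and print annotated output.

A thin CLI mirrors the library: `ddmkit {estimate, lifetable, simulate,
compare, pipeline}` (see `ddmkit --help`).

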