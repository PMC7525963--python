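# Methods notes

This note records the model assumptions, discretizations, defaults and design
choices behind ddmkit, at the level of detail a maintainer or a careful user
needs.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

Counts live in age groups with integer lower bounds, half-open intervals
[x, x+5) and one terminal open interval (default 80+).  Time is in decimal
years; the intercensal length t is computed exactly from the two census
reference times.  Deaths are stored internally as *mean annual* counts;
period totals are accepted at the CSV boundary (flag
`deaths_are_period_totals`) and divided by t on ingestion, so no estimator
ever mixes the two units.  Sexes are processed separately; a "total" label is
accepted but never produced by merging inside estimators.

## GGB discretization

The balance relation holds for flows and stocks the data do not directly
provide, so:

- N(x), persons reaching exact age x per year, is approximated within each
  census by (₅N₍ₓ₋₅₎ + ₅Nₓ)/10, and the two censuses are combined by a
  geometric mean.  At the open bound A the terminal count stands in for a
  5-year group; this point is biased when remaining life expectancy at A is
  far from 5 years, which is why the default window (40–70) excludes it while
  the window grid search may still use it.
- N(x+) is the geometric mean of the two censuses' cumulative counts —
  symmetric treatment of both enumerations, and a mid-period person-year
  estimate under exponential growth.
- r(x+) = ln(N₂(x+)/N₁(x+))/t.

The line is fitted by total least squares (both axes carry sampling and
discretization error); the SVD of the centred 2-column matrix gives the
orthogonal direction, and the fit RMSE is the root mean square of orthogonal
distances.  Ordinary least squares is available (`regression="ols"`) for
comparison with implementations that use it.  Identifiability: only k1/k2 is
estimable, so the convention k2 ≡ 1 is applied, giving k1 = exp(intercept·t)
and C = sqrt(k1)/slope.  A non-positive slope or a window with fewer than
three points raises an "method not applicable" error rather than returning a
number.

## SEG discretization and the open interval

Per-year flows N̂(x) of persons reaching exact age x are reconstructed
backward from the open bound:

    N̂(A)  = D(A+) · exp(r(A+) · ê(A+))
    N̂(x)  = N̂(x+5) · exp(5 r_x) + D_x · exp(2.5 r_x)

with r_x the group-specific intercensal growth rate.  Group person-years
integrate a *log-linear* interpolation of adjacent flows (the log-mean
w·(f₁−f₂)/ln(f₁/f₂)), which is exact for exponentially declining populations;
the trapezoid alternative overshoots by several percent in the oldest groups,
where survivorship falls fastest, and that error would otherwise leak into
the completeness summary.  The open group contributes N̂(A)·ê(A+).

The open-interval life expectancy ê(A+) is the method's one genuinely
underdetermined input.  It is solved from the self-consistency condition

    ê · exp(r(A+)·ê) · m(A+) = ĉ

where m(A+) is the *observed* open-interval death rate and ĉ the window
summary of ĉ(a) implied by ê.  The solution is found by a secant iteration
seeded at ê = 1/m(A+) (at most 40 evaluations, tolerance 1e-12); because the
observed rate and the summary are both scaled by the same unknown
completeness, the solved ê — and hence the estimate — is invariant to the
level of completeness and to uniform census coverage.  A plain two-step
fixed-point iteration was tried first and converges too slowly when the open
interval holds a large share of the population above the window ages; the
secant solve of the same condition is the package's choice.

ĉ(a) = N̂(a+)/N⁰(a+) uses cumulative sums from each lower bound a, with N⁰
per-group geometric means of the censuses.  The completeness summary is the
arithmetic mean of ĉ(a) over the window (median by flag).  SEG-adj divides
the *first* census by the GGB-estimated k1/k2 before everything else; the
choice of which census to adjust only changes the estimate's overall scale
and is fixed for reproducibility.

Default age windows — GGB 40–70, SEG 55–80, SEG-adj 50–70 — are the generic
documented ranges for these methods.  The window grid search
(`select_age_window`) scores all windows of width ≥ 30 years by fit RMSE,
breaking ties toward the widest window and then the lowest lower bound; the
30-year minimum is this package's choice, made to keep at least seven points
under the default 5-year grid.

## Life tables

q(x) = n·m/(1 + (n − a)·m) with a = n/2 for regular groups and the
conventional a₀ = 0.3, a₁₋₄ = 1.6 when the 0/1–4 split is present; the open
interval has q = 1 and L = l(A)/m(A+).  q values above 1 (possible for
extreme rates in wide groups) are clipped with a warning.  45q15 is read off
l(x) at exact ages 15 and 60, so the age grid must include both bounds —
enforced, not interpolated.  Person-years for rate denominators are
geometric means of the two census counts per group; no published source
states its exposure convention, so this symmetric choice is made explicit
here.  Old-age smoothing, relational-model completion and migration-corrected
variants are out of scope.

## Convergence statistic

RMSE uses the population (÷N) denominator exactly as defined above, returns
exactly 0 for identical inputs, and requires N ≥ 2.  National aggregation of
state-level RMSEs is ambiguous in published work; both documented modes are
implemented and labelled — the equal-weight mean of state RMSEs (sexes pooled
by averaging) and direct use of a national-total row when a panel provides
one.  The convergence verdict uses a configurable tolerance (default 0.005 on
the RMSE scale) to separate "stable" from genuine movement.

## Simulator

Stable-population mode (default): N(x) ∝ e^(−rx)·S(x) with the Siler
survivorship S(x) in closed form, integrated on a 0.05-year grid within
single-year cells and grouped to 5-year output; deaths use the hazard
analogously, scaled by the exact mean annual birth flow over the period.
Because the generative model satisfies the methods' assumptions exactly, any
estimator error on noiseless scenarios is attributable to discretization —
measured at roughly ±1% across the default scenarios, which is what makes the
±0.02 recovery checks meaningful rather than circular.

Defaults, chosen once as realistic for a late-20th-century middle-income
population: growth rate 0.01/yr, censuses at 2000.0 and 2010.0 (t = 10),
open age 80+, male Siler schedule (a₁ = 0.012, b₁ = 1.1, c = 0.001,
a₂ = 3.0e−5, b₂ = 0.102) calibrated at design time to e0 ≈ 70.6 years, and a
female schedule about four years higher.  The radix is births per year; the
stochastic calibration runs use radix 20 000, putting the census population
near 10⁶.

Degradation operators: deterministic scaling of deaths by c(x) (default, so
recovery tests carry no Monte-Carlo noise) or seeded binomial thinning;
census coverage factors applied multiplicatively; misreporting transfers a
fraction of every group one group up (net overstatement), down (net
understatement) or half each way (symmetric), with boundary groups reflecting
inward so totals are conserved exactly.  Migration enters the stable mode as
cohort-accumulated net rates applied to the second census and (at half
exposure) to deaths — a first-order treatment adequate for studying the
*direction* and window-dependence of migration bias, not its exact size.  A
cohort-component mode (annual single-year projection with a Gaussian-shaped
fertility schedule) provides a deliberately non-stable test bed.

What the simulator does **not** emulate: digit-preference heaping, cause
structure, household microdata, sub-state geography, age-varying census
coverage within one census, and real enumeration error correlation between
censuses and death registration.  Passing recovery tests therefore show the
estimators are correct *under their own assumptions* and degrade as expected
under the modelled violations — not that any given real registry meets those
assumptions.

## Bundled data

One small real panel ships with the package: published male 45q15 estimates
for the 27 Brazilian states from three producers (IBGE, IHME, DDM-R) in the
1980/1991 and 2000/2010 intercensal periods, plus a Bayesian small-area model
and uncorrected registry values for 2010.  It drives the convergence example
and the national RMSE figures in the acceptance script.  The corresponding
state-level *completeness* panel is published only as a supplementary
spreadsheet and is not redistributable here; the one acceptance test that
asserts its national RMSE values is expected to fail for that reason.

## Problem sizes

Test and acceptance runs use 17 five-year age groups, noiseless scenarios at
radix 1 000, and 200 stochastic replicates at radix 20 000 — sizes at which
every check completes in seconds while the discretization error is already
scale-independent.
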