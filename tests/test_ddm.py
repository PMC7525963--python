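import numpy as np
import pytest

from ddmkit import (
    EstimationError,
    SyntheticScenario,
    candidate_windows,
    fit_ggb,
    ggb_diagnostics,
    ggb_points,
    seg_adj,
    seg_completeness,
    seg_diagnostics,
    select_age_window,
    simulate_dataset,
)
from ddmkit.types import GGBPoints


def _aggregate_rate_oracle(scenario, x):
    """Analytic stable-population death rate over ages x+ by direct quadrature."""
    ages = np.linspace(x, 120.0, 4001)
    w = np.exp(-scenario.growth_rate * ages) * scenario.mortality.survival(ages)
    deaths = np.trapezoid(w * scenario.mortality.hazard(ages), ages)
    pop = np.trapezoid(w, ages)
    return deaths / pop


class TestGGBPoints:
    def test_growth_rate_zero_when_stationary(self, stationary_c060):
        _, ds, _ = stationary_c060
        pts = ggb_points(ds)
        np.testing.assert_allclose(pts.growth_rate, 0.0, atol=1e-10)

    def test_growth_rate_closed_form_under_exponential_growth(self, perfect):
        import dataclasses

        _, ds, _ = perfect
        c2 = dataclasses.replace(
            ds.census1.scaled(np.exp(0.02 * ds.t)),
            reference_time=ds.census2.reference_time,
        )
        pts = ggb_points(ds.replace(census2=c2))
        np.testing.assert_allclose(pts.growth_rate, 0.02, atol=1e-12)

    def test_death_rate_matches_analytic_schedule(self, perfect):
        s, ds, _ = perfect
        pts = ggb_points(ds)
        for x, observed in zip(pts.age[:-1], pts.death_rate[:-1]):
            assert observed == pytest.approx(_aggregate_rate_oracle(s, x), rel=0.02)

    def test_empty_tail_point_dropped_with_warning(self, perfect):
        _, ds, _ = perfect
        c1 = ds.census1.counts.copy()
        c2 = ds.census2.counts.copy()
        c1[-1] = 0.0
        c2[-1] = 0.0
        ds2 = ds.replace(
            census1=ds.census1.with_counts(c1), census2=ds.census2.with_counts(c2)
        )
        with pytest.warns(UserWarning, match="dropping GGB point"):
            pts = ggb_points(ds2)
        assert 80 not in pts.age


class TestFitGGB:
    def test_perfect_data_limit(self, perfect):
        _, ds, _ = perfect
        fit = fit_ggb(ggb_points(ds))
        assert fit.intercept == pytest.approx(0.0, abs=5e-4)
        assert fit.slope == pytest.approx(1.0, rel=0.02)
        assert fit.completeness == pytest.approx(1.0, abs=0.02)

    def test_deaths_scaled_by_point_seven(self, perfect):
        _, ds, _ = perfect
        base = fit_ggb(ggb_points(ds))
        scaled = fit_ggb(ggb_points(ds.replace(deaths=ds.deaths.scaled(0.7))))
        assert scaled.completeness == pytest.approx(0.7, abs=0.02)
        assert scaled.intercept == pytest.approx(base.intercept, abs=1e-4)

    def test_census2_inflation_moves_intercept(self, perfect):
        _, ds, _ = perfect
        infl = ds.census2.scaled(1.05)
        pts = ggb_points(ds.replace(census2=infl))
        fit = fit_ggb(pts)
        assert fit.intercept == pytest.approx(-np.log(1.05) / ds.t, rel=0.10)

    def test_deaths_scaling_property(self, c070):
        """GGB completeness is linear in a uniform rescaling of deaths."""
        _, ds, _ = c070
        base = fit_ggb(ggb_points(ds)).completeness
        for f in (0.5, 1.5):
            scaled = fit_ggb(ggb_points(ds.replace(deaths=ds.deaths.scaled(f))))
            assert scaled.completeness == pytest.approx(f * base, rel=1e-6)

    def test_common_census_scaling_divides_completeness(self, perfect):
        """Completeness is relative to census coverage: scaling both censuses
        by lambda leaves the intercept alone and divides C by lambda."""
        _, ds, _ = perfect
        lam = 1.25
        ds2 = ds.replace(
            census1=ds.census1.scaled(lam), census2=ds.census2.scaled(lam)
        )
        base = fit_ggb(ggb_points(ds))
        scaled = fit_ggb(ggb_points(ds2))
        assert scaled.intercept == pytest.approx(base.intercept, abs=1e-6)
        assert scaled.completeness == pytest.approx(base.completeness / lam, rel=1e-4)

    def test_too_few_points_flagged_not_applicable(self, perfect):
        _, ds, _ = perfect
        with pytest.raises(EstimationError, match="fewer than 3"):
            fit_ggb(ggb_points(ds), age_window=(40, 45))

    def test_ols_option_close_to_tls_on_clean_data(self, perfect):
        _, ds, _ = perfect
        pts = ggb_points(ds)
        tls = fit_ggb(pts, regression="tls")
        ols = fit_ggb(pts, regression="ols")
        assert ols.completeness == pytest.approx(tls.completeness, rel=0.01)


class TestSEG:
    def test_stationary_constant_completeness_recovered(self, stationary_c060):
        _, ds, _ = stationary_c060
        res = seg_completeness(ds)
        mask = (res.age >= 55) & (res.age <= 80)
        np.testing.assert_allclose(res.c_by_age[mask], 0.6, atol=0.02)
        assert res.completeness == pytest.approx(0.6, abs=0.02)

    def test_perfect_data_limit(self, perfect):
        _, ds, _ = perfect
        assert seg_completeness(ds).completeness == pytest.approx(1.0, abs=0.02)

    def test_halving_deaths_halves_every_ratio(self, c070):
        _, ds, _ = c070
        base = seg_completeness(ds)
        half = seg_completeness(ds.replace(deaths=ds.deaths.scaled(0.5)))
        np.testing.assert_allclose(half.c_by_age, 0.5 * base.c_by_age, rtol=1e-6)

    def test_zero_open_interval_deaths_rejected(self, perfect):
        _, ds, _ = perfect
        d = ds.deaths.counts.copy()
        d[-1] = 0.0
        with pytest.raises(EstimationError, match="open-interval"):
            seg_completeness(ds.replace(deaths=ds.deaths.with_counts(d)))

    def test_median_summary_option(self, c070):
        _, ds, _ = c070
        res = seg_completeness(ds, summary="median")
        mask = (res.age >= 55) & (res.age <= 80)
        assert res.completeness == pytest.approx(float(np.median(res.c_by_age[mask])))


class TestSEGAdj:
    def test_unit_delta_equals_plain_seg(self, c070):
        _, ds, _ = c070
        plain = seg_completeness(ds)
        with_delta = seg_completeness(ds, delta=1.0)
        assert with_delta.completeness == pytest.approx(plain.completeness, abs=1e-9)
        np.testing.assert_allclose(with_delta.c_by_age, plain.c_by_age, atol=1e-9)

    def test_corrects_census_coverage_difference(self):
        s = SyntheticScenario(true_completeness=0.8, census_coverage=(1.05, 1.0))
        ds, _ = simulate_dataset(s)
        plain = seg_completeness(ds).completeness
        adjusted = seg_adj(ds).completeness
        assert abs(plain - 0.8) > 0.04  # plain SEG visibly biased
        assert adjusted == pytest.approx(0.8, abs=0.02)

    def test_perfect_data_limit(self, perfect):
        _, ds, _ = perfect
        assert seg_adj(ds).completeness == pytest.approx(1.0, abs=0.02)


class TestRecovery:
    """Core surface: all three methods recover a constant completeness."""

    @pytest.mark.parametrize("c", [0.5, 0.7, 0.9, 1.0])
    def test_all_methods_within_two_points(self, c):
        ds, _ = simulate_dataset(SyntheticScenario(true_completeness=c))
        assert fit_ggb(ggb_points(ds)).completeness == pytest.approx(c, abs=0.02)
        assert seg_completeness(ds).completeness == pytest.approx(c, abs=0.02)
        assert seg_adj(ds).completeness == pytest.approx(c, abs=0.02)

    def test_uncapped_above_one_under_census_undercount(self):
        """Complete death registration with 10% census undercount yields
        completeness estimates above 100% unless capping is requested."""
        ds, _ = simulate_dataset(
            SyntheticScenario(true_completeness=1.0, census_coverage=(0.9, 0.9))
        )
        assert fit_ggb(ggb_points(ds)).completeness > 1.0
        assert seg_completeness(ds).completeness > 1.0
        capped = seg_completeness(ds, cap=True)
        assert capped.completeness == 1.0 and capped.capped

    def test_migration_bias_shrinks_in_older_windows(self, perfect):
        """Net out-migration at ages 15-35 biases GGB; restricting the window
        to ages 40+ reduces the distortion."""
        _, ds0, _ = perfect
        young = np.zeros(120)
        young[15:35] = -0.005
        dsm, _ = simulate_dataset(SyntheticScenario(migration=young))
        bias_wide = fit_ggb(ggb_points(dsm), (5, 75)).completeness - fit_ggb(
            ggb_points(ds0), (5, 75)
        ).completeness
        bias_old = fit_ggb(ggb_points(dsm), (40, 70)).completeness - fit_ggb(
            ggb_points(ds0), (40, 70)
        ).completeness
        assert abs(bias_old) < abs(bias_wide)


class TestWindowSelection:
    @staticmethod
    def _collinear_points():
        age = np.arange(5, 85, 5)
        z = np.linspace(0.001, 0.1, len(age))
        return GGBPoints(
            age=age,
            entry_rate=0.01 + 1.25 * z,
            growth_rate=np.zeros(len(age)),
            death_rate=z,
            t=10.0,
        )

    def test_collinear_ties_break_to_widest_window(self):
        pts = self._collinear_points()
        assert select_age_window(pts) == (5, 80)

    def test_corrupted_old_age_point_excluded(self, perfect):
        _, ds, _ = perfect
        d = ds.deaths.counts.copy()
        d[-1] *= 3.0
        pts = ggb_points(ds.replace(deaths=ds.deaths.with_counts(d)))
        # oracle: brute-force refit over the same candidates
        cands = candidate_windows(pts)
        fits = {w: fit_ggb(pts, w).fit_rmse for w in cands}
        best = min(fits, key=lambda w: (round(fits[w], 12), -(w[1] - w[0]), w[0]))
        chosen = select_age_window(pts)
        assert chosen == best
        assert chosen[1] < 75

    def test_single_candidate_returned_unchanged(self, perfect):
        _, ds, _ = perfect
        assert select_age_window(ggb_points(ds), [(40, 70)]) == (40, 70)

    def test_empty_candidate_list_rejected(self, perfect):
        _, ds, _ = perfect
        with pytest.raises(EstimationError, match="empty candidate"):
            select_age_window(ggb_points(ds), [])


class TestDiagnostics:
    def test_collinear_points_have_unit_straightness(self):
        pts = TestWindowSelection._collinear_points()
        diag = ggb_diagnostics(fit_ggb(pts, (5, 80)))
        assert diag["straightness"] == pytest.approx(1.0, abs=1e-9)

    def test_outlier_point_flagged(self):
        pts = TestWindowSelection._collinear_points()
        pts.entry_rate[pts.age == 45] += 0.01
        diag = ggb_diagnostics(fit_ggb(pts, (5, 80)))
        assert diag["max_residual_age"] == 45

    def test_noiseless_scenario_is_nearly_straight(self, c070):
        _, ds, _ = c070
        diag = ggb_diagnostics(fit_ggb(ggb_points(ds)))
        assert diag["straightness"] >= 0.99

    def test_constant_completeness_gives_flat_seg_slope(self, c070):
        _, ds, _ = c070
        diag = seg_diagnostics(seg_completeness(ds))
        assert diag["slope"] == pytest.approx(0.0, abs=5e-4)

    def test_age_rising_completeness_detected(self):
        rising = np.clip(0.5 + 0.02 * np.arange(17), None, 0.95)
        ds, _ = simulate_dataset(SyntheticScenario(true_completeness=rising))
        diag = seg_diagnostics(seg_completeness(ds))
        assert diag["slope"] > 1e-4

    def test_single_group_window_slope_undefined(self, c070):
        _, ds, _ = c070
        res = seg_completeness(ds, age_window=(60, 60))
        assert np.isnan(seg_diagnostics(res)["slope"])
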