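import numpy as np
import pytest

from ddmkit import (
    AgeGroupedCounts,
    adjusted_rates,
    adult_mortality_45q15,
    build_life_table,
    top_down_rescale,
)
from ddmkit.types import LifeTable


def _table_constant_m(m=0.01, open_age=80):
    age = np.arange(0, open_age + 5, 5)
    return build_life_table(age, np.full(len(age), m))


class TestAdjustedRates:
    def test_completeness_one_is_identity(self, c070):
        _, ds, _ = c070
        mx = adjusted_rates(ds, 1.0)
        py = np.sqrt(ds.census1.counts * ds.census2.counts)
        np.testing.assert_allclose(mx, ds.deaths.counts / py)

    def test_half_completeness_doubles_rates(self, c070):
        _, ds, _ = c070
        np.testing.assert_allclose(adjusted_rates(ds, 0.5), 2.0 * adjusted_rates(ds, 1.0))

    def test_feeding_back_estimate_recovers_true_schedule(self, c070):
        """Adjusting observed rates by the true completeness recovers the
        simulator's true central death rates."""
        s, ds, truth = c070
        mx = adjusted_rates(ds, 0.7)
        np.testing.assert_allclose(mx, truth.crude_rates, rtol=0.02)

    def test_non_positive_completeness_rejected(self, c070):
        _, ds, _ = c070
        with pytest.raises(ValueError, match="positive"):
            adjusted_rates(ds, 0.0)


class TestBuildLifeTable:
    def test_zero_mortality_below_open_age(self):
        age = np.arange(0, 85, 5)
        mx = np.zeros(len(age))
        mx[-1] = 0.2
        lt = build_life_table(age, mx)
        np.testing.assert_allclose(lt.lx, 1.0)
        assert lt.q45_15 == 0.0

    def test_constant_hazard_hand_value(self):
        """Nine 5-year groups at m = 0.01 with a = 2.5 chain to 45q15 = 0.3624."""
        lt = _table_constant_m(0.01)
        q5 = 0.05 / 1.025
        assert lt.q45_15 == pytest.approx(1.0 - (1.0 - q5) ** 9, abs=1e-12)
        assert lt.q45_15 == pytest.approx(0.3624, abs=0.0005)

    def test_e0_approaches_reciprocal_rate_on_fine_grid(self):
        m = 0.01
        age = np.arange(0, 1001)
        lt = build_life_table(age, np.full(len(age), m))
        assert lt.e0 == pytest.approx(1.0 / m, rel=0.01)

    def test_closure_invariants(self, c070):
        _, ds, _ = c070
        lt = build_life_table(ds.age, adjusted_rates(ds, 0.7))
        dx = np.append(lt.lx[:-1] - lt.lx[1:], lt.lx[-1])
        assert dx.sum() == pytest.approx(lt.lx[0], rel=1e-12)
        assert lt.Tx[0] == pytest.approx(lt.Lx.sum(), rel=1e-12)
        assert np.all(np.diff(lt.lx) <= 0)
        assert np.all(lt.ex >= 0)
        assert np.all((lt.qx >= 0) & (lt.qx <= 1)) and lt.qx[-1] == 1.0

    def test_infant_separation_uses_conventional_ax(self):
        age = np.array([0, 1, 5, 10, 15, 60, 80])
        lt = build_life_table(age, np.full(len(age), 0.01))
        assert lt.ax[0] == pytest.approx(0.3)
        assert lt.ax[1] == pytest.approx(1.6)

    def test_extreme_rates_clipped_with_warning(self):
        age = np.arange(0, 85, 5)
        mx = np.full(len(age), 0.9)
        with pytest.warns(UserWarning, match="clipped"):
            lt = build_life_table(age, mx)
        assert np.all(lt.qx <= 1.0)


class TestAdultMortality:
    def test_direct_ratio(self):
        lt = _table_constant_m(0.01)
        lt = LifeTable(
            age=lt.age, mx=lt.mx, ax=lt.ax, qx=lt.qx,
            lx=np.where(lt.age == 60, 0.70, np.where(lt.age >= 15, 0.95, 1.0)),
            Lx=lt.Lx, Tx=lt.Tx, ex=lt.ex,
        )
        assert adult_mortality_45q15(lt) == pytest.approx(1 - 0.70 / 0.95, abs=1e-5)
        assert adult_mortality_45q15(lt) == pytest.approx(0.26316, abs=1e-5)

    def test_simulator_schedule_recovered_end_to_end(self, c070):
        """Rates adjusted by the true completeness reproduce the analytic
        45q15 of the generating hazard within 1%."""
        s, ds, truth = c070
        lt = build_life_table(ds.age, adjusted_rates(ds, 0.7))
        assert lt.q45_15 == pytest.approx(truth.q45_15, rel=0.01)

    def test_strictly_decreasing_in_completeness(self, c070):
        _, ds, _ = c070
        values = [
            build_life_table(ds.age, adjusted_rates(ds, c)).q45_15
            for c in (0.6, 0.8, 1.0)
        ]
        assert values[0] > values[1] > values[2]

    def test_unadjusted_rates_give_highest_life_expectancy(self, c070):
        """Taking registry deaths at face value (completeness 1) always yields
        a higher e0 than any correction for under-registration."""
        _, ds, _ = c070
        e0_raw = build_life_table(ds.age, adjusted_rates(ds, 1.0)).e0
        for c in (0.95, 0.8, 0.6):
            assert build_life_table(ds.age, adjusted_rates(ds, c)).e0 < e0_raw

    def test_missing_bounds_rejected(self):
        age = np.array([0, 20, 40, 65, 80])
        lt = build_life_table(age, np.full(len(age), 0.01))
        with pytest.raises(ValueError, match="15 and 60"):
            adult_mortality_45q15(lt)


class TestTopDownRescale:
    @staticmethod
    def _deaths(values):
        return AgeGroupedCounts([0, 80], [values, values], kind="deaths")

    @staticmethod
    def _states(mapping):
        return {
            k: AgeGroupedCounts([0, 80], v, kind="deaths") for k, v in mapping.items()
        }

    def test_worked_example_no_exemptions(self):
        states = self._states({"A": [100, 0], "B": [200, 0], "C": [300, 0]})
        national = AgeGroupedCounts([0, 80], [540, 0], kind="deaths")
        out = top_down_rescale(states, national)
        assert [out[k].counts[0] for k in "ABC"] == [90.0, 180.0, 270.0]

    def test_identity_when_sum_matches(self):
        states = self._states({"A": [100, 10], "B": [200, 20]})
        national = AgeGroupedCounts([0, 80], [300, 30], kind="deaths")
        out = top_down_rescale(states, national)
        for k in states:
            np.testing.assert_allclose(out[k].counts, states[k].counts)

    def test_exempt_region_untouched(self):
        states = self._states({"A": [100, 0], "B": [200, 0], "C": [300, 0]})
        national = AgeGroupedCounts([0, 80], [540, 0], kind="deaths")
        out = top_down_rescale(states, national, exempt={"A"})
        assert out["A"].counts[0] == 100.0
        assert out["B"].counts[0] == pytest.approx(176.0)
        assert out["C"].counts[0] == pytest.approx(264.0)

    def test_conserves_national_total_per_age(self):
        rng = np.random.default_rng(7)
        ages = np.arange(0, 85, 5)
        states = {
            f"S{i}": AgeGroupedCounts(ages, rng.uniform(10, 100, len(ages)), kind="deaths")
            for i in range(5)
        }
        national = AgeGroupedCounts(ages, rng.uniform(100, 400, len(ages)), kind="deaths")
        out = top_down_rescale(states, national, exempt={"S0"})
        total = sum(out[k].counts for k in out)
        expected = national.counts.copy()
        np.testing.assert_allclose(total, expected, rtol=1e-9)

    def test_national_below_exempt_sum_rejected(self):
        states = self._states({"A": [600, 0], "B": [100, 0]})
        national = AgeGroupedCounts([0, 80], [540, 0], kind="deaths")
        with pytest.raises(ValueError, match="below the exempt"):
            top_down_rescale(states, national, exempt={"A"})
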