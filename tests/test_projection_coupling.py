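import numpy as np
import pytest

from marshrisk.monotone_pspline import ProbabilityCurve
from marshrisk.projection_coupling import (
    NOT_REACHED,
    ProjectionEnsemble,
    cumulative_max,
    read_projection_ensembles,
    retreat_timeline,
    threshold_year_table,
    twenty_year_rates,
    write_projection_ensemble,
)

YEARS = np.arange(2000.0, 2101.0, 10.0)


def logistic_curve(centre=3.0, scale=1.0, lo=-10.0, hi=25.0):
    grid = np.linspace(lo, hi, 1401)
    mean = 1.0 / (1.0 + np.exp(-(grid - centre) / scale))
    return ProbabilityCurve(grid, mean, mean, mean)


def constant_rate_ensemble(rate_mm_yr, years=YEARS, n_samples=1):
    rsl = rate_mm_yr / 10.0 * (years - years[0])  # cm
    return ProjectionEnsemble("site", "RCP8.5", years, np.tile(rsl, (n_samples, 1)))


class TestTwentyYearRates:
    def test_constant_half_cm_per_year(self):
        rsl = 0.5 * (YEARS - 2000.0)
        np.testing.assert_allclose(twenty_year_rates(rsl, YEARS), 5.0)

    def test_flat_trajectory(self):
        np.testing.assert_allclose(twenty_year_rates(np.zeros(YEARS.size), YEARS), 0.0)

    def test_hand_difference_oracle(self):
        years = np.array([2000.0, 2010.0, 2020.0, 2030.0])
        rates = twenty_year_rates(np.array([0.0, 2.0, 6.0, 12.0]), years)
        np.testing.assert_allclose(rates, [3.0, 5.0])  # rates at 2020, 2030

    def test_first_two_decades_yield_no_value(self):
        assert twenty_year_rates(np.zeros(YEARS.size), YEARS).size == YEARS.size - 2

    def test_non_decadal_grid_rejected(self):
        with pytest.raises(ValueError, match="decadal"):
            twenty_year_rates([0.0, 1.0, 2.0], [2000.0, 2005.0, 2010.0])
        with pytest.raises(ValueError, match="decadal"):
            twenty_year_rates([0.0, 1.0], [2000.0, 2010.0])


class TestCumulativeMax:
    def test_monotone_input_is_identity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        np.testing.assert_array_equal(cumulative_max(x), x)

    def test_dip_is_held(self):
        np.testing.assert_array_equal(cumulative_max([1.0, 3.0, 2.0]), [1.0, 3.0, 3.0])

    def test_matches_brute_force_prefix_max(self):
        rng = np.random.default_rng(8)
        series = rng.normal(size=100)
        oracle = np.array([series[: i + 1].max() for i in range(100)])
        np.testing.assert_array_equal(cumulative_max(series), oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_max([])


class TestRetreatTimeline:
    def test_constant_rate_equals_curve_lookup(self):
        curve = logistic_curve()
        tl = retreat_timeline(curve, constant_rate_ensemble(4.0))
        np.testing.assert_allclose(tl.probability, curve.evaluate([4.0])[0])

    def test_flat_curve_below_threshold_never_crosses(self):
        grid = np.linspace(-10, 25, 100)
        flat = ProbabilityCurve(grid, np.full(100, 0.5), np.full(100, 0.5), np.full(100, 0.5))
        tl = retreat_timeline(flat, constant_rate_ensemble(12.0))
        np.testing.assert_allclose(tl.probability, 0.5)
        assert tl.threshold_year == NOT_REACHED

    def test_two_sample_arithmetic_mean(self):
        curve = logistic_curve()
        r1, r2 = 2.0, 6.0
        years = YEARS
        samples = np.vstack(
            [r1 / 10.0 * (years - 2000.0), r2 / 10.0 * (years - 2000.0)]
        )
        ens = ProjectionEnsemble("site", "RCP8.5", years, samples)
        tl = retreat_timeline(curve, ens)
        expected = (curve.evaluate([r1])[0] + curve.evaluate([r2])[0]) / 2.0
        np.testing.assert_allclose(tl.probability, expected)

    def test_timeline_monotone_for_any_ensemble(self):
        rng = np.random.default_rng(9)
        years = np.arange(2000.0, 2201.0, 10.0)
        samples = np.cumsum(rng.normal(1.0, 3.0, (50, years.size)), axis=1)
        tl = retreat_timeline(logistic_curve(), ProjectionEnsemble("s", "x", years, samples))
        assert np.all(np.diff(tl.probability) >= -1e-12)

    def test_duplicating_samples_leaves_timeline_unchanged(self):
        rng = np.random.default_rng(10)
        samples = np.cumsum(rng.normal(1.0, 2.0, (20, YEARS.size)), axis=1)
        ens = ProjectionEnsemble("s", "x", YEARS, samples)
        doubled = ProjectionEnsemble("s", "x", YEARS, np.vstack([samples, samples]))
        curve = logistic_curve()
        np.testing.assert_allclose(
            retreat_timeline(curve, ens).probability,
            retreat_timeline(curve, doubled).probability,
        )

    def test_pointwise_larger_trajectories_never_cross_later(self):
        rng = np.random.default_rng(11)
        years = np.arange(2000.0, 2301.0, 10.0)
        low = np.cumsum(rng.uniform(0.0, 3.0, (30, years.size)), axis=1)
        high = low + np.cumsum(rng.uniform(0.0, 2.0, (30, years.size)), axis=1)
        curve = logistic_curve()
        tl_low = retreat_timeline(curve, ProjectionEnsemble("s", "x", years, low))
        tl_high = retreat_timeline(curve, ProjectionEnsemble("s", "x", years, high))
        y_low = np.inf if tl_low.threshold_year == NOT_REACHED else tl_low.threshold_year
        y_high = np.inf if tl_high.threshold_year == NOT_REACHED else tl_high.threshold_year
        assert y_high <= y_low

    def test_empty_ensemble_rejected(self):
        ens = ProjectionEnsemble("s", "x", YEARS, np.empty((0, YEARS.size)))
        with pytest.raises(ValueError, match="samples"):
            retreat_timeline(logistic_curve(), ens)


class TestThresholdYearTable:
    def test_first_exceedance_on_decadal_grid(self):
        # cross 0.8 between 2030 (0.79) and 2040 (0.83): reported year is 2040
        grid = np.linspace(0, 10, 101)
        mean = np.interp(grid, [0, 3, 4, 10], [0.1, 0.79, 0.83, 0.95])
        curve = ProbabilityCurve(grid, mean, mean, mean)
        years = np.arange(1990.0, 2101.0, 10.0)
        # ensemble whose 20-yr running-max rate is 3.0 mm/yr through 2030
        # and 4.0 mm/yr from 2040 on
        base = np.zeros(years.size)
        for i in range(2, years.size):
            target = 3.0 if years[i] <= 2030 else 4.0
            base[i] = base[i - 2] + target * 2.0  # cm per 20 yr at 10 mm/cm
        ens = ProjectionEnsemble("s", "x", years, base[None, :])
        tl = retreat_timeline(curve, ens, threshold=0.8)
        assert tl.threshold_year == 2040.0
        table = threshold_year_table([tl])
        assert table.iloc[0]["year"] == 2040.0

    def test_not_reached_preserved(self):
        grid = np.linspace(-10, 25, 50)
        flat = ProbabilityCurve(grid, np.full(50, 0.3), np.full(50, 0.3), np.full(50, 0.3))
        tl = retreat_timeline(flat, constant_rate_ensemble(5.0))
        table = threshold_year_table([tl])
        assert table.iloc[0]["year"] == NOT_REACHED

    def test_mixed_thresholds_rejected(self):
        curve = logistic_curve()
        a = retreat_timeline(curve, constant_rate_ensemble(5.0), threshold=0.8)
        b = retreat_timeline(curve, constant_rate_ensemble(5.0), threshold=0.5)
        with pytest.raises(ValueError, match="threshold"):
            threshold_year_table([a, b])

    def test_subsiding_site_crosses_before_uplifting_site(self):
        # identical climate signal; subsidence adds, uplift subtracts
        rng = np.random.default_rng(12)
        years = np.arange(2000.0, 2301.0, 10.0)
        climate = np.cumsum(rng.uniform(0.5, 2.5, (40, years.size)), axis=1)
        subsiding = climate + 0.15 * (years - 2000.0)
        uplifting = climate - 0.15 * (years - 2000.0)
        curve = logistic_curve()
        tl_sub = retreat_timeline(curve, ProjectionEnsemble("sub", "x", years, subsiding))
        tl_up = retreat_timeline(curve, ProjectionEnsemble("up", "x", years, uplifting))
        y_sub = np.inf if tl_sub.threshold_year == NOT_REACHED else tl_sub.threshold_year
        y_up = np.inf if tl_up.threshold_year == NOT_REACHED else tl_up.threshold_year
        assert y_sub <= y_up


class TestEnsembleIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        ens = ProjectionEnsemble("tilbury", "RCP8.5", YEARS, rng.normal(10, 3, (5, YEARS.size)))
        path = tmp_path / "ens.csv"
        write_projection_ensemble(ens, path)
        back = read_projection_ensembles(path)
        assert len(back) == 1
        assert back[0].site_id == "tilbury" and back[0].scenario == "RCP8.5"
        np.testing.assert_allclose(back[0].samples, ens.samples)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="decadal"):
            ProjectionEnsemble("s", "x", [2000.0, 2007.0, 2020.0], np.zeros((1, 3)))
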