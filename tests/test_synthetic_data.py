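import numpy as np
import pytest

from marshrisk.database_io import filter_gradual, read_index_points, write_index_points
from marshrisk.gia_rates import compute_rate
from marshrisk.projection_coupling import twenty_year_rates
from marshrisk.synthetic_data import (
    RegimeParams,
    ScenarioParams,
    TruthCurve,
    default_curve_set,
    default_recovery_dataset,
    gen_index_points,
    gen_projection_ensemble,
    gen_rsl_curve,
)


def segment_slopes(curve):
    """Internal per-millennium rates, young -> old, mm/yr."""
    return -np.diff(curve.rsl)


class TestGenRSLCurve:
    def test_far_field_rates_stay_in_holocene_envelope(self):
        curve = gen_rsl_curve(RegimeParams.default("far_field"), seed=0)
        rates = segment_slopes(curve)
        assert np.all(rates >= 0.0)
        assert rates.max() <= 15.2

    def test_near_field_has_fall_rise_fall_signature(self):
        curve = gen_rsl_curve(RegimeParams.default("near_field"), seed=0)
        rates = segment_slopes(curve)  # young -> old
        assert np.all(rates[:4] < 0)  # late-Holocene fall to present
        assert np.all(rates[4:9] > 0)  # mid-Holocene rise to the highstand
        assert np.all(rates[9:] < 0)  # early deglacial fall
        assert np.all((rates >= -7.7) & (rates <= 6.0))

    def test_near_field_single_highstand_above_present(self):
        curve = gen_rsl_curve(RegimeParams.default("near_field"), seed=5)
        interior = curve.rsl[1:-1]
        peaks = [
            i
            for i in range(1, len(curve.rsl) - 1)
            if curve.rsl[i] > curve.rsl[i - 1] and curve.rsl[i] > curve.rsl[i + 1]
        ]
        assert len(peaks) == 1
        assert curve.rsl[peaks[0]] > 0.0
        assert interior.max() == pytest.approx(
            RegimeParams.default("near_field").highstand_amplitude_m, rel=0.2
        )

    def test_rates_roundtrip_through_centred_differencing(self):
        # compute_rate at a segment midpoint must equal the generator's
        # internal slope for that segment, to machine precision
        for regime in ("near_field", "margin", "far_field"):
            curve = gen_rsl_curve(RegimeParams.default(regime), seed=3)
            slopes = segment_slopes(curve)
            for k, slope in enumerate(slopes):
                mid = 1000.0 * k + 500.0
                assert compute_rate(curve, mid) == pytest.approx(slope, abs=1e-9)

    def test_seed_determinism(self):
        a = gen_rsl_curve(RegimeParams.default("margin"), seed=9)
        b = gen_rsl_curve(RegimeParams.default("margin"), seed=9)
        np.testing.assert_array_equal(a.rsl, b.rsl)

    def test_bad_regime_parameters_rejected(self):
        with pytest.raises(ValueError, match="early rate"):
            RegimeParams("far_field", early_rate_mm_yr=20.0)
        with pytest.raises(ValueError, match="fall"):
            RegimeParams("near_field", early_rate_mm_yr=2.0)
        with pytest.raises(ValueError, match="regime"):
            RegimeParams("mid_field")


class TestTruthCurve:
    def test_default_shape_echoes_holocene_fit(self):
        truth = TruthCurve()
        assert truth(7.0) > 0.85
        assert truth(-2.0) < 0.12
        assert truth.inverse(0.9) == pytest.approx(np.log(9.0) / 0.5 + 3.0)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="monotone"):
            TruthCurve(slope=-1.0)


@pytest.fixture(scope="module")
def curves():
    return default_curve_set(seed=21)


class TestGenIndexPoints:
    def test_flat_truth_gives_half_positive(self, curves):
        truth = TruthCurve(intercept=0.0, slope=0.0)
        db, _ = gen_index_points(curves, truth, n=2000, frac_none=0.0,
                                 frac_erosional=0.0, seed=1)
        share = np.mean([p.tendency == "positive" for p in db])
        assert abs(share - 0.5) <= 3 * 0.5 / np.sqrt(2000)  # binomial 3-sigma

    def test_erosional_fraction_matches_binomial(self, curves):
        db, _ = gen_index_points(curves, TruthCurve(), n=1000, frac_erosional=0.3, seed=2)
        retained = len(filter_gradual(db))
        assert abs(retained - 700) <= 45  # 3 * sqrt(1000 * 0.3 * 0.7)

    def test_steep_truth_separates_rate_bins(self, curves):
        truth = TruthCurve(intercept=-2.0, slope=2.0)
        db, table = gen_index_points(curves, truth, n=4000, frac_none=0.0,
                                     frac_erosional=0.0, seed=3)
        rates = table["rate_mm_yr"].to_numpy()
        pos = np.array([p.tendency == "positive" for p in db])
        low, high = rates < -2.0, rates > 6.0
        assert pos[low].mean() < 0.1
        assert pos[high].mean() > 0.9

    def test_ages_concentrate_in_mid_holocene(self, curves):
        db, _ = gen_index_points(curves, TruthCurve(), n=3000, seed=4)
        ages = db.ages()
        assert np.mean((ages >= 3000) & (ages <= 8000)) > 0.55
        assert ages.min() >= 150.0 and ages.max() <= 11_850.0

    def test_generated_database_passes_validation(self, curves, tmp_path):
        db, _ = gen_index_points(curves, TruthCurve(), n=300, seed=5)
        path = tmp_path / "synthetic_points.csv"
        write_index_points(db, path)
        back, errors = read_index_points(path)
        assert errors == []
        assert len(back) == 300

    def test_truth_table_is_parallel(self, curves):
        db, table = gen_index_points(curves, TruthCurve(), n=100, seed=6)
        assert table["point_id"].tolist() == [p.point_id for p in db]
        assert set(table["y_true"]) <= {0, 1}

    def test_seed_determinism(self, curves):
        a, ta = gen_index_points(curves, TruthCurve(), n=50, seed=7)
        b, tb = gen_index_points(curves, TruthCurve(), n=50, seed=7)
        assert [p.age for p in a] == [p.age for p in b]
        np.testing.assert_array_equal(ta["rate_mm_yr"], tb["rate_mm_yr"])

    def test_empty_curves_rejected(self):
        with pytest.raises(ValueError, match="curve"):
            gen_index_points({}, TruthCurve(), n=10, seed=0)


class TestGenProjectionEnsemble:
    def test_zero_variance_constant_rate(self):
        # 3 mm/yr background, no climate spread: every 20-yr rate is 3.0
        params = ScenarioParams(
            rise_2100_cm=(30.0, 30.0), background_rate_mm_yr=3.0, n_samples=5, seed=0
        )
        ens = gen_projection_ensemble(params)
        for sample in ens.samples:
            np.testing.assert_allclose(twenty_year_rates(sample, ens.years), 3.0, atol=1e-9)

    def test_tilbury_like_calibration(self):
        params = ScenarioParams(rise_2100_cm=(23.0, 123.0), n_samples=1000, seed=1)
        ens = gen_projection_ensemble(params)
        i2100 = int(np.argwhere(ens.years == 2100.0)[0][0])
        q5, q95 = np.percentile(ens.samples[:, i2100], [5.0, 95.0])
        assert abs(q5 - 23.0) <= 0.1 * 23.0
        assert abs(q95 - 123.0) <= 0.1 * 123.0

    def test_shape_matches_params(self):
        params = ScenarioParams(n_samples=64, year_start=2000, year_end=2150, seed=2)
        ens = gen_projection_ensemble(params)
        assert ens.samples.shape == (64, 16)
        assert ens.years[0] == 2000.0 and ens.years[-1] == 2150.0

    def test_seed_determinism(self):
        a = gen_projection_ensemble(ScenarioParams(n_samples=20, seed=3))
        b = gen_projection_ensemble(ScenarioParams(n_samples=20, seed=3))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            ScenarioParams(rise_2100_cm=(50.0, 20.0))


def test_recovery_dataset_is_clean_and_two_class(recovery_fit):
    data = recovery_fit["data"]
    assert data.n == 800
    assert set(np.unique(data.y)) == {0, 1}
    assert np.all(np.isfinite(data.x))


def test_recovery_dataset_seed_determinism():
    a, _, _ = default_recovery_dataset(seed=2, n=60)
    b, _, _ = default_recovery_dataset(seed=2, n=60)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)
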