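"""Tax → price → consumption → sugar → energy conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbtax import (
    BeverageCategory,
    CalibrationError,
    ConfigurationError,
    Elasticity,
    PassThrough,
    TaxScenario,
    calibrate_market,
    consumption_change,
    energy_change,
    market_impact,
    market_impact_by_category,
    retail_price_increase,
    sugar_change,
)
from ssbtax.tax_market import AD_VALOREM, PAPER_SCENARIOS, SPECIFIC_SUGAR, SPECIFIC_VOLUME


class TestRetailPriceIncrease:
    def test_override_wins(self):
        sc = TaxScenario("s1", AD_VALOREM, 0.10, 0.05)
        assert retail_price_increase(sc) == 0.05

    def test_ad_valorem_computed_from_pass_through(self):
        # 10% on the factory price ≈ 5% at retail; 40% ≈ 20%
        assert retail_price_increase(TaxScenario("a", AD_VALOREM, 0.10)) == pytest.approx(0.05)
        assert retail_price_increase(TaxScenario("b", AD_VALOREM, 0.40)) == pytest.approx(0.20)

    def test_zero_rate_gives_zero(self):
        assert retail_price_increase(TaxScenario("z", SPECIFIC_VOLUME, 0.0)) == 0.0

    def test_specific_volume(self):
        cat = BeverageCategory("carbonates", 1000.0, 17_500.0, 11.0)
        sc = TaxScenario("v", SPECIFIC_VOLUME, 7000.0)
        assert retail_price_increase(sc, cat) == pytest.approx(0.20)

    def test_specific_sugar_uses_grams_per_litre(self):
        # 60 VND per gram of sugar: carbonates at 11 g/100ml carry 110 g/L
        # → 6,600 VND/L of tax, half of which reaches the retail price.
        cat = BeverageCategory("carbonates", 1000.0, 17_500.0, 11.0)
        sc = TaxScenario("s", SPECIFIC_SUGAR, 60.0)
        assert retail_price_increase(sc, cat) == pytest.approx(6600 * 0.5 / 17_500)

    def test_specific_needs_category(self):
        with pytest.raises(ConfigurationError):
            retail_price_increase(TaxScenario("v", SPECIFIC_VOLUME, 7000.0))

    def test_unknown_tax_type_rejected(self):
        with pytest.raises(ConfigurationError):
            TaxScenario("x", "poll_tax", 1.0)


class TestConsumptionChange:
    def test_scenario1_decrease(self, calibration):
        dv = consumption_change(0.05, Elasticity(), calibration.baseline_volume_total)
        assert dv == pytest.approx(-171.3, abs=0.05)

    def test_zero_price_change(self):
        assert consumption_change(0.0, Elasticity(), 3005.3) == 0.0

    def test_four_to_one_scaling(self, calibration):
        v = calibration.baseline_volume_total
        assert consumption_change(0.20, Elasticity(), v) == pytest.approx(
            4 * consumption_change(0.05, Elasticity(), v))
        assert consumption_change(0.20, Elasticity(), v) == pytest.approx(-684.9, rel=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(k=st.floats(0.0, 10.0), dp=st.floats(0.0, 0.5))
    def test_linearity_in_price(self, k, dp):
        base = consumption_change(dp, Elasticity(), 1000.0)
        scaled = consumption_change(k * dp, Elasticity(), 1000.0)
        assert scaled == pytest.approx(k * base, abs=1e-9)


class TestCalibrateMarket:
    def test_published_scenario1_inversion(self):
        cal = calibrate_market()
        assert cal.baseline_volume_total == pytest.approx(3005.3, abs=0.05)
        assert cal.population / 1e6 == pytest.approx(65.9, abs=0.05)
        assert cal.mean_sugar_density == pytest.approx(11.2, abs=0.05)

    def test_energy_derived_density(self):
        cal = calibrate_market(energy_decrease_s1=13.7)
        assert cal.mean_sugar_density == pytest.approx(11.52, abs=0.01)

    def test_round_trip_reproduces_printed_decrease(self):
        cal = calibrate_market()
        dv = consumption_change(0.05, Elasticity(), cal.baseline_volume_total)
        assert -dv == pytest.approx(171.3, rel=1e-4)

    def test_zero_price_increase_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_market(price_increase_s1=0.0)


class TestSugarEnergy:
    @pytest.mark.parametrize("dv, dens, expected", [
        (7.12, 11.2, 0.80), (0.0, 11.2, 0.0), (100.0, 16.0, 16.0),
    ])
    def test_sugar_change(self, dv, dens, expected):
        assert sugar_change(dv, dens) == pytest.approx(expected, abs=0.005)

    def test_sugar_change_sums_category_vectors(self):
        assert sugar_change([100.0, 50.0], [10.0, 16.0]) == pytest.approx(18.0)

    @pytest.mark.parametrize("ds, expected", [(1.0, 16.7), (0.0, 0.0), (3.3, 55.11)])
    def test_energy_change(self, ds, expected):
        assert energy_change(ds) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(v=st.floats(0, 1000), d=st.floats(0, 30))
    def test_energy_monotone_in_volume_and_density(self, v, d):
        e = energy_change(sugar_change(v, d))
        assert e >= energy_change(sugar_change(v * 0.9, d)) - 1e-9
        assert e >= energy_change(sugar_change(v, d * 0.9)) - 1e-9


class TestMarketImpact:
    def test_sign_coherence(self, calibration):
        for sc in PAPER_SCENARIOS:
            imp = market_impact(sc, calibration)
            assert imp.dvolume_total <= 0
            assert imp.dsugar_per_capita <= 0
            assert imp.denergy_per_capita <= 0

    def test_energy_sugar_consistency(self, calibration):
        imp = market_impact(PAPER_SCENARIOS[0], calibration)
        assert imp.denergy_per_capita == pytest.approx(16.7 * imp.dsugar_per_capita)

    def test_by_category_matches_aggregate_for_uniform_price_rise(self):
        cats = [BeverageCategory("carbonates", 2000.0, 15_000.0, 11.0),
                BeverageCategory("juices", 1000.0, 20_000.0, 7.0)]
        sc = TaxScenario("a", AD_VALOREM, 0.40)  # uniform 20% retail rise
        imp = market_impact_by_category(sc, cats, 65.9e6)
        assert imp.price_increase == pytest.approx(0.20)
        assert imp.dvolume_total == pytest.approx(-1.14 * 0.20 * 3000.0)

    def test_invalid_category_fields_rejected(self):
        with pytest.raises(Exception):
            BeverageCategory("bad", -1.0, 100.0, 11.0)
        with pytest.raises(Exception):
            BeverageCategory("bad", 1.0, 100.0, 45.0)
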