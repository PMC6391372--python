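"""Vapor-pressure formulas and sowing-relative window aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sowshift import weather_features as wf
from sowshift.errors import MissingDaysError, ValidationError

TEMPS = st.floats(min_value=-55, max_value=55, allow_nan=False)


class TestSaturationVaporPressure:
    def test_zero_celsius_gives_printed_constant(self):
        assert wf.saturation_vapor_pressure(0.0) == pytest.approx(0.6107)

    @given(t1=TEMPS, dt=st.floats(min_value=1e-3, max_value=20))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing(self, t1, dt):
        t2 = min(t1 + dt, 55.0)
        if t2 > t1:
            assert (wf.saturation_vapor_pressure(t1)
                    < wf.saturation_vapor_pressure(t2))

    def test_rejects_nonfinite_and_out_of_range(self):
        with pytest.raises(ValidationError):
            wf.saturation_vapor_pressure(float("nan"))
        with pytest.raises(ValidationError):
            wf.saturation_vapor_pressure(75.0)

    def test_inverse_roundtrip(self):
        t = np.linspace(-40, 50, 40)
        back = wf.invert_saturation_vapor_pressure(
            wf.saturation_vapor_pressure(t)
        )
        np.testing.assert_allclose(back, t, atol=1e-10)


class TestDailyVpdAndRh:
    def test_vpd_zero_when_tmax_equals_tmin(self):
        assert wf.daily_vpd(15.0, 15.0) == 0.0

    def test_vpd_rejects_inverted_temperatures(self):
        with pytest.raises(ValidationError):
            wf.daily_vpd(10.0, 12.0)

    @given(tmin=st.floats(min_value=-40, max_value=20, allow_nan=False),
           delta1=st.floats(0.1, 30), delta2=st.floats(0.1, 5))
    @settings(max_examples=100, derandomize=True)
    def test_vpd_increases_with_tmax(self, tmin, delta1, delta2):
        lo = wf.daily_vpd(tmin + delta1, tmin)
        hi = wf.daily_vpd(tmin + delta1 + delta2, tmin)
        assert hi > lo >= 0

    def test_rh_definition_identity(self):
        es_mean = 0.5 * (wf.saturation_vapor_pressure(25.0)
                         + wf.saturation_vapor_pressure(12.0))
        assert wf.daily_relative_humidity(es_mean, 25.0, 12.0) == pytest.approx(1.0)
        assert wf.daily_relative_humidity(0.0, 25.0, 12.0) == 0.0

    def test_rh_rejects_negative_vp(self):
        with pytest.raises(ValidationError):
            wf.daily_relative_humidity(-0.1, 25.0, 12.0)


class TestWindowOf:
    @pytest.mark.parametrize("offset,expected", [
        (-31, None), (-30, "Wpre"), (-1, "Wpre"),
        (0, "W1"), (29, "W1"), (30, "W2"), (59, "W2"),
        (60, "W3"), (89, "W3"), (90, "W4"), (119, "W4"),
        (120, "W5"), (149, "W5"), (150, None), (365, None),
    ])
    def test_half_open_bins(self, offset, expected):
        assert wf.window_of(offset) == expected


class TestAggregateWindows:
    def test_constant_weather_closed_form(self):
        doy = np.arange(1, 366)
        days = pd.DataFrame({
            "doy": doy, "tmin": 15.0, "tmax": 25.0, "precip": 2.0,
            "srad": 20.0, "vp": 1.0, "dayl": 4e4,
        })
        feats = wf.aggregate_windows(days, 150)
        expected_vpd = (wf.saturation_vapor_pressure(25.0)
                        - wf.saturation_vapor_pressure(15.0))
        for w in wf.WINDOW_NAMES:
            assert feats[f"precip_cum_{w}"] == pytest.approx(60.0)
            assert feats[f"wet_days_{w}"] == 30
            assert feats[f"dry_days_{w}"] == 0
            assert feats[f"vpd_mean_{w}"] == pytest.approx(expected_vpd)
            assert feats[f"ab_zero_b_{w}"] == 1.0  # b = 0 convention flagged
            assert feats[f"ab_ratio_{w}"] == pytest.approx(30.0 / 1.0)
        assert feats["precip_cum_season"] == pytest.approx(360.0)

    def test_all_dry_window_counts(self):
        doy = np.arange(1, 366)
        days = pd.DataFrame({
            "doy": doy, "tmin": 10.0, "tmax": 20.0, "precip": 0.0,
            "srad": 20.0, "vp": 1.0,
        })
        feats = wf.aggregate_windows(days, 120)
        assert feats["wet_days_W1"] == 0
        assert feats["dry_days_W1"] == 30
        assert feats["ab_ratio_W1"] == 0.0
        assert feats["ab_zero_b_W1"] == 0.0

    def test_boundary_precipitation_in_neither_count(self):
        doy = np.arange(1, 366)
        precip = np.ones(365)  # exactly 1 mm: neither wet (>1) nor dry (<1)
        days = pd.DataFrame({"doy": doy, "tmin": 10.0, "tmax": 20.0,
                             "precip": precip, "srad": 20.0, "vp": 1.0})
        feats = wf.aggregate_windows(days, 120)
        assert feats["wet_days_W2"] == 0
        assert feats["dry_days_W2"] == 0

    def test_gap_raises_with_offsets(self, random_daily_frame):
        days = random_daily_frame(3)
        days = days[days["doy"] != 125]
        with pytest.raises(MissingDaysError) as err:
            wf.aggregate_windows(days, 120)
        assert 5 in err.value.missing_offsets

    def test_permuting_days_within_window_preserves_features(
        self, random_daily_frame
    ):
        days = random_daily_frame(11)
        base = wf.aggregate_windows(days, 120)
        # reverse the rows of W3 (offsets 60..89 → doy 180..209)
        idx = days.index[(days["doy"] >= 180) & (days["doy"] <= 209)]
        shuffled = days.copy()
        block = shuffled.loc[idx].iloc[::-1]
        block.index = idx
        block["doy"] = days.loc[idx, "doy"].values  # keep doys, permute weather
        for col in ["tmin", "tmax", "precip", "srad", "vp", "dayl"]:
            shuffled.loc[idx, col] = block[col].values[::-1]
        after = wf.aggregate_windows(shuffled, 120)
        pd.testing.assert_series_equal(base, after)

    def test_year_boundary_series(self, random_daily_frame):
        tail = random_daily_frame(21).assign(year=2009)
        head = random_daily_frame(22).assign(year=2010)
        days = pd.concat([tail, head], ignore_index=True)
        feats = wf.aggregate_windows(days, 20, sowing_year=2010)
        assert feats["n_days_season"] == 180

    def test_tree_predictor_frame_is_31_columns(self, random_daily_frame):
        feats = wf.aggregate_windows(random_daily_frame(5), 120)
        df = feats.to_frame().T.assign(state="IA")
        X = wf.tree_predictor_frame(df)
        assert X.shape[1] == 31
        assert list(X.columns)[-1] == "state"
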