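import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatadapt.environment import (
    daytime_summary,
    diary_summary,
    globe_temp,
    mvpa_from_counts,
    natural_wet_bulb,
    psychrometric_wet_bulb,
    solar_irradiance,
    wbgt,
    wbgt_from_met,
)


class TestSolarIrradiance:
    def test_midnight_zero(self):
        assert solar_irradiance("2023-01-15 00:00", -35.3, 149.1, 0.0) == 0.0

    def test_equinox_equator_noon(self):
        # overhead sun: 1367 * 0.75 ~ 1025 W/m2
        s = solar_irradiance("2023-03-21 12:00", 0.0, 0.0, 0.0)
        assert s == pytest.approx(1025.0, rel=0.01)

    def test_cloud_attenuates(self):
        clear = solar_irradiance("2023-01-15 12:00", -35.3, 149.1, 0.0)
        overcast = solar_irradiance("2023-01-15 12:00", -35.3, 149.1, 1.0)
        assert 0 < overcast < clear
        assert overcast == pytest.approx(0.25 * clear, rel=1e-6)

    def test_symmetric_about_solar_noon(self):
        # equation of time is fixed within a day, so +/- offsets from the
        # true solar noon give equal irradiance
        lat, lon = -35.3, 150.0
        base = pd.Timestamp("2023-01-15 12:00")
        # locate solar noon by scanning
        grid = [base + pd.Timedelta(minutes=m) for m in range(-120, 121)]
        vals = [solar_irradiance(t, lat, lon, 0.0) for t in grid]
        noon = grid[int(np.argmax(vals))]
        for dt in (30, 90, 150):
            a = solar_irradiance(noon - pd.Timedelta(minutes=dt), lat, lon, 0.0)
            b = solar_irradiance(noon + pd.Timedelta(minutes=dt), lat, lon, 0.0)
            assert a == pytest.approx(b, rel=0.02)

    def test_invalid_cloud(self):
        with pytest.raises(ValueError):
            solar_irradiance("2023-01-15 12:00", 0, 0, 1.5)


class TestGlobeTemp:
    def test_no_sun_returns_drybulb(self):
        assert globe_temp(30.0, 50.0, 5.0, 0.0) == 30.0

    def test_sun_heats_globe(self):
        assert globe_temp(30.0, 50.0, 1.0, 800.0) > 30.0

    def test_wind_cools_globe(self):
        slow = globe_temp(30.0, 50.0, 0.5, 800.0)
        fast = globe_temp(30.0, 50.0, 5.0, 800.0)
        assert fast < slow

    def test_matches_independent_scan_oracle(self, rng):
        """brentq solution agrees with a brute-force scan of the same balance."""
        from heatadapt.calorimetry import SIGMA
        from heatadapt.environment import _sphere_h

        for _ in range(10):
            ta = rng.uniform(15, 40)
            wind = rng.uniform(0.3, 5.0)
            solar = rng.uniform(100, 1000)
            tg = globe_temp(ta, 50.0, wind, solar)
            h = _sphere_h(wind, 0.15)
            grid = np.arange(ta, ta + 60.0, 0.01)
            resid = (
                0.95 * 0.40 * solar
                - h * (grid - ta)
                - 0.95 * SIGMA * ((grid + 273.15) ** 4 - (ta + 273.15) ** 4)
            )
            oracle = grid[np.argmin(np.abs(resid))]
            assert tg == pytest.approx(oracle, abs=0.5)


class TestNaturalWetBulb:
    def test_saturated_no_sun_equals_drybulb(self):
        assert natural_wet_bulb(25.0, 100.0, 1.0, 0.0) == pytest.approx(25.0, abs=0.1)

    def test_tracks_psychrometric_wet_bulb_without_sun(self, rng):
        for _ in range(20):
            ta = rng.uniform(15.0, 35.0)
            rh = rng.uniform(20.0, 90.0)
            wind = rng.uniform(1.0, 4.0)
            tnw = natural_wet_bulb(ta, rh, wind, 0.0)
            assert tnw == pytest.approx(psychrometric_wet_bulb(ta, rh), abs=0.5)

    def test_monotone_in_rh(self):
        vals = [natural_wet_bulb(30.0, rh, 1.0, 300.0) for rh in (20, 40, 60, 80, 100)]
        assert np.all(np.diff(vals) > 0)


class TestWBGT:
    def test_identity(self):
        assert wbgt(25.0, 25.0, 25.0) == 25.0

    def test_hand_arithmetic(self):
        assert wbgt(18.0, 34.0, 24.0) == pytest.approx(21.8)

    @settings(max_examples=50, derandomize=True)
    @given(
        tnw=st.floats(5, 30), tg=st.floats(10, 60), tdb=st.floats(5, 45), shift=st.floats(-5, 5)
    )
    def test_shift_equivariance(self, tnw, tg, tdb, shift):
        assert wbgt(tnw + shift, tg + shift, tdb + shift) == pytest.approx(
            wbgt(tnw, tg, tdb) + shift, abs=1e-9
        )

    def test_solver_convergence_and_bounds_on_random_grid(self, rng):
        """Both balances converge and land inside physical bounds."""
        for _ in range(2000):
            ta = rng.uniform(-5, 44)
            rh = rng.uniform(5, 100)
            wind = rng.uniform(0.1, 10.0)
            solar = rng.uniform(0, 1100)
            tg = globe_temp(ta, rh, wind, solar)
            tnw = natural_wet_bulb(ta, rh, wind, solar)
            w = wbgt(tnw, tg, ta)
            assert tg >= ta - 1e-9
            assert min(tnw, ta) - 1e-9 <= w <= max(tg, ta) + 1e-9


class TestDaytimeSummary:
    @staticmethod
    def _table(values, start="2023-01-01", days=3):
        ts = pd.date_range(start, periods=24 * days, freq="h")
        return pd.DataFrame({"timestamp": ts, "wbgt_c": values})

    def test_constant_series(self):
        t = self._table(np.full(72, 21.2))
        s = daytime_summary(t)
        assert s.period_mean == pytest.approx(21.2)
        assert s.period_sd == pytest.approx(0.0)

    def test_sinusoid_matches_closed_form(self):
        ts = pd.date_range("2023-01-01", periods=24 * 5, freq="h")
        hours = ts.hour.to_numpy()
        vals = 20.0 + 5.0 * np.cos(2 * np.pi * (hours - 15) / 24.0)
        s = daytime_summary(pd.DataFrame({"timestamp": ts, "wbgt_c": vals}))
        expected = 20.0 + 5.0 * np.mean(
            np.cos(2 * np.pi * (np.arange(8, 18) - 15) / 24.0)
        )
        assert s.period_mean == pytest.approx(expected, abs=1e-9)

    def test_low_coverage_day_dropped(self):
        t = self._table(np.full(72, 20.0))
        keep = ~((pd.to_datetime(t["timestamp"]).dt.date == pd.Timestamp("2023-01-02").date())
                 & (pd.to_datetime(t["timestamp"]).dt.hour >= 12))
        s = daytime_summary(t[keep])
        assert len(s.dropped_days) == 1
        assert len(s.daily) == 2

    def test_window_edges(self):
        # 08:00 included, 18:00 excluded
        t = self._table(np.arange(72.0), days=3)
        hours_used = sorted(
            pd.to_datetime(t["timestamp"]).dt.hour[
                (pd.to_datetime(t["timestamp"]).dt.hour >= 8)
                & (pd.to_datetime(t["timestamp"]).dt.hour < 18)
            ].unique()
        )
        assert hours_used == list(range(8, 18))


class TestMVPA:
    @staticmethod
    def _epochs(vm):
        ts = pd.date_range("2023-01-01", periods=vm.size, freq="min")
        a = vm / np.sqrt(3.0)
        return pd.DataFrame({"timestamp": ts, "axis1": a, "axis2": a, "axis3": a})

    def test_all_zero_day_flagged_nonwear(self):
        res = mvpa_from_counts(self._epochs(np.zeros(1440)))
        assert res.mean_h_per_day == 0.0
        assert res.all_nonwear

    def test_counting_example(self):
        # 120 min at 3000 counts/min, rest zero -> 2.0 h/day
        vm = np.zeros(1440)
        vm[300:420] = 3000.0
        res = mvpa_from_counts(self._epochs(vm))
        assert res.mean_h_per_day == pytest.approx(2.0)

    def test_raising_cutpoint_never_increases_mvpa(self):
        vm = np.abs(np.random.default_rng(0).normal(2000, 1500, 1440 * 3))
        ep = self._epochs(vm)
        prev = np.inf
        for cut in (1500, 2690, 4000, 6000):
            m = mvpa_from_counts(ep, cutpoint_cpm=cut).mean_h_per_day
            assert m <= prev + 1e-12
            prev = m

    def test_non_60s_epochs_rejected(self):
        ts = pd.date_range("2023-01-01", periods=100, freq="30s")
        df = pd.DataFrame({"timestamp": ts, "axis1": 1.0, "axis2": 1.0, "axis3": 1.0})
        with pytest.raises(ValueError):
            mvpa_from_counts(df)


class TestDiarySummary:
    def test_single_bout(self):
        d = pd.DataFrame(
            [{"start": pd.Timestamp("2023-01-02 16:00"), "duration_h": 2.0,
              "location": "outdoor", "rpe": 5}]
        )
        s = diary_summary(d)
        assert s.by_intensity["moderate"] == 2.0
        assert s.outdoor_h_wk == 2.0
        assert s.mode_bin_start_hour == 15

    def test_outdoor_total_by_construction(self):
        rows = [
            {"start": pd.Timestamp("2023-01-02 15:30") + pd.Timedelta(days=i),
             "duration_h": 7.4 / 7, "location": "outdoor", "rpe": 7}
            for i in range(7)
        ]
        s = diary_summary(pd.DataFrame(rows))
        assert s.outdoor_h_wk == pytest.approx(7.4)
        assert s.outdoor_by_intensity["high"] == pytest.approx(7.4)

    def test_out_of_range_rpe_rejected(self):
        d = pd.DataFrame(
            [
                {"start": pd.Timestamp("2023-01-02 10:00"), "duration_h": 1.0,
                 "location": "outdoor", "rpe": 12},
                {"start": pd.Timestamp("2023-01-02 12:00"), "duration_h": 1.0,
                 "location": "indoor", "rpe": 3},
            ]
        )
        s = diary_summary(d)
        assert s.rejected_rows == 1
        assert s.total_h_wk == 1.0


def test_wbgt_from_met_pipeline_columns():
    from heatadapt.synthetic import generate_met_year

    met = generate_met_year(n_days=2, seed=0)
    out = wbgt_from_met(met)
    for col in ("solar_wm2", "globe_temp_c", "nat_wet_bulb_c", "wbgt_c"):
        assert col in out.columns
    night = out[pd.to_datetime(out["timestamp"]).dt.hour == 0]
    assert (night["solar_wm2"] == 0).all()
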