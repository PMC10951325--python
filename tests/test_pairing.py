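"""Ingest and matchup rules: window averaging, depth strata, spin-up filter."""

import numpy as np
import pandas as pd
import pytest

import reefskill as rs
from reefskill import pairing
from reefskill.series import PairedDataset

from conftest import make_site


def _series(times, values, cadence, site="X", source="observed", **meta):
    m = rs.SiteMeta(site_id=site, lat=meta.get("lat", 21.0),
                    lon=meta.get("lon", -157.0), depth_m=meta.get("depth", 5.0))
    return rs.TemperatureSeries(m, source, pd.Series(values, index=times), cadence)


def _snapshots(start, periods, value=25.0, site="X"):
    t = pd.date_range(start, periods=periods, freq="3h", tz="UTC")
    return _series(t, np.full(periods, value), 180, site=site, source="model")


class TestReadObsCsv:
    def test_basic_two_rows(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(
            "site_id,latitude,longitude,depth,time,temperature\n"
            "A,21.0,-157.0,5,2012-01-01T00:00:00Z,25.0\n"
            "A,21.0,-157.0,5,2012-01-01T00:05:00Z,25.1\n")
        series = pairing.read_obs_csv(p)
        assert len(series) == 1 and len(series[0]) == 2

    def test_units_row_skipped(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(
            "site_id,latitude,longitude,depth,time,temperature\n"
            ",degrees_north,degrees_east,m,UTC,degree_C\n"
            "A,21.0,-157.0,5,2012-01-01T00:00:00Z,25.0\n"
            "A,21.0,-157.0,5,2012-01-01T00:05:00Z,25.1\n")
        series = pairing.read_obs_csv(p)
        assert len(series[0]) == 2

    def test_blank_temperature_dropped(self, tmp_path):
        rows = [f"A,21.0,-157.0,5,2012-01-01T00:{5*i:02d}:00Z,25.{i}"
                for i in range(10)]
        rows[4] = "A,21.0,-157.0,5,2012-01-01T00:20:00Z,"
        p = tmp_path / "obs.csv"
        p.write_text("site_id,latitude,longitude,depth,time,temperature\n"
                     + "\n".join(rows) + "\n")
        series = pairing.read_obs_csv(p)
        assert len(series[0]) == 9

    def test_interleaved_sites_split_and_sorted(self, tmp_path):
        # two sites written in interleaved, shuffled row order
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            rows.append(("A", f"2012-01-01T{i:02d}:00:00Z", 25.0 + i))
            rows.append(("B", f"2012-01-01T{i:02d}:00:00Z", 20.0 + i))
        rng.shuffle(rows)
        p = tmp_path / "obs.csv"
        p.write_text("site_id,latitude,longitude,depth,time,temperature\n"
                     + "\n".join(f"{s},21.0,-157.0,5,{t},{v}" for s, t, v in rows))
        series = {s.meta.site_id: s for s in pairing.read_obs_csv(p)}
        assert set(series) == {"A", "B"}
        # per-site values recovered by independent grouping
        for site, base in (("A", 25.0), ("B", 20.0)):
            assert np.array_equal(series[site].values, base + np.arange(6))
            assert series[site].timestamps.is_monotonic_increasing

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text("site_id,latitude,longitude,time,temperature\nA,21,-157,t,25\n")
        with pytest.raises(ValueError, match="depth"):
            pairing.read_obs_csv(p)


class TestReadModelSeries:
    def _write_grid(self, path, lats, lons, strata, times, values):
        """CF NetCDF fixture via xarray (scipy NetCDF3 backend)."""
        import xarray as xr
        ds = xr.Dataset(
            {"temperature": (("time", "depth", "latitude", "longitude"), values)},
            coords={"time": times.tz_localize(None), "depth": strata,
                    "latitude": lats, "longitude": lons},
        )
        ds.to_netcdf(path, engine="scipy")

    def test_single_cell_roundtrip(self, tmp_path):
        times = pd.date_range("2012-01-01", periods=8, freq="3h", tz="UTC")
        vals = 25.0 + np.arange(8.0).reshape(8, 1, 1, 1)
        p = tmp_path / "grid.nc"
        self._write_grid(p, [21.0], [-157.0], [5.0], times, vals)
        s = pairing.read_model_series(p, 21.0, -157.0, 5.0)
        assert np.array_equal(s.values, 25.0 + np.arange(8.0))

    def test_nearest_cell_matches_brute_force(self, tmp_path):
        lats, lons = [20.9, 21.1], [-157.2, -156.9]
        times = pd.date_range("2012-01-01", periods=4, freq="3h", tz="UTC")
        vals = np.arange(4 * 1 * 2 * 2, dtype=float).reshape(4, 1, 2, 2)
        p = tmp_path / "grid.nc"
        self._write_grid(p, lats, lons, [10.0], times, vals)
        lat0, lon0 = 21.05, -156.95
        s = pairing.read_model_series(p, lat0, lon0, 10.0)
        # exhaustive scan oracle
        best = min(((i, j) for i in range(2) for j in range(2)),
                   key=lambda ij: pairing.great_circle_m(
                       lats[ij[0]], lons[ij[1]], lat0, lon0))
        assert np.array_equal(s.values, vals[:, 0, best[0], best[1]])

    def test_midpoint_tie_takes_lower_index(self, tmp_path):
        lats = [21.0]
        lons = [-157.0, -156.8]
        times = pd.date_range("2012-01-01", periods=2, freq="3h", tz="UTC")
        vals = np.array([[[[1.0, 2.0]]], [[[3.0, 4.0]]]])
        p = tmp_path / "grid.nc"
        self._write_grid(p, lats, lons, [5.0], times, vals)
        s = pairing.read_model_series(p, 21.0, -156.9, 5.0)
        assert np.array_equal(s.values, [1.0, 3.0])

    def test_absent_stratum_lists_available(self, tmp_path):
        times = pd.date_range("2012-01-01", periods=2, freq="3h", tz="UTC")
        p = tmp_path / "grid.nc"
        self._write_grid(p, [21.0], [-157.0], [5.0, 10.0], times,
                         np.zeros((2, 2, 1, 1)) + 25.0)
        with pytest.raises(ValueError, match="10"):
            pairing.read_model_series(p, 21.0, -157.0, 7.5)

    def test_point_outside_domain_rejected(self, tmp_path):
        times = pd.date_range("2012-01-01", periods=2, freq="3h", tz="UTC")
        p = tmp_path / "grid.nc"
        self._write_grid(p, [21.0], [-157.0], [5.0], times, np.zeros((2, 1, 1, 1)) + 25.0)
        with pytest.raises(ValueError, match="outside"):
            pairing.read_model_series(p, 30.0, -157.0, 5.0)

    def test_griddap_csv_equivalent(self, tmp_path):
        times = pd.date_range("2012-01-01", periods=3, freq="3h", tz="UTC")
        rows = []
        for i, t in enumerate(times):
            rows.append(f"{t.isoformat()},5.0,21.0,-157.0,{25.0 + i}")
        p = tmp_path / "grid.csv"
        p.write_text("time,depth,latitude,longitude,temperature\n" + "\n".join(rows))
        s = pairing.read_model_series(p, 21.0, -157.0, 5.0)
        assert np.array_equal(s.values, [25.0, 26.0, 27.0])


class TestMatchDepth:
    @pytest.mark.parametrize("obs_depth,expected", [
        (5.0, 5.0),     # exact
        (15.0, 10.0),   # tie between 10 and 20 -> shallower
        (23.7, 20.0),   # nearest
        (29.0, 30.0),
        (7.5, 5.0),     # tie between 5 and 10 -> shallower
    ])
    def test_nearest_with_shallow_tie(self, obs_depth, expected):
        assert pairing.match_depth(obs_depth, [5, 10, 20, 30]) == expected

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            pairing.match_depth(5.0, [])


class TestPairSeries:
    def test_5min_window_is_five_samples(self):
        # snapshot at 06:00 averages obs at 05:50, 05:55, 06:00, 06:05, 06:10
        t = pd.date_range("2012-01-01", periods=288, freq="5min", tz="UTC")
        obs = _series(t, 25.0 + 0.01 * np.arange(288.0), 5)
        model = _snapshots("2012-01-01", 8)
        pairs = rs.pair_series(obs, model)
        row = pairs[pairs.time == pd.Timestamp("2012-01-01T06:00Z")].iloc[0]
        assert row.n_obs_in_window == 5
        expect = np.mean([25.0 + 0.01 * k for k in (70, 71, 72, 73, 74)])
        assert row.obs == pytest.approx(expect, abs=1e-12)

    def test_30min_window_is_five_samples(self):
        # snapshot at 06:00 averages obs at 05:00, 05:30, 06:00, 06:30, 07:00
        t = pd.date_range("2012-01-01", periods=96, freq="30min", tz="UTC")
        obs = _series(t, 25.0 + 0.01 * np.arange(96.0), 30)
        model = _snapshots("2012-01-01", 8)
        pairs = rs.pair_series(obs, model)
        row = pairs[pairs.time == pd.Timestamp("2012-01-01T06:00Z")].iloc[0]
        assert row.n_obs_in_window == 5
        expect = np.mean([25.0 + 0.01 * k for k in (10, 11, 12, 13, 14)])
        assert row.obs == pytest.approx(expect, abs=1e-12)

    def test_constant_obs_constant_matchups(self):
        t = pd.date_range("2012-01-01", periods=288, freq="5min", tz="UTC")
        obs = _series(t, np.full(288, 26.5), 5)
        pairs = rs.pair_series(obs, _snapshots("2012-01-01", 8))
        assert np.allclose(pairs["obs"], 26.5)

    def test_unsupported_cadence_rejected(self):
        t = pd.date_range("2012-01-01", periods=24, freq="15min", tz="UTC")
        obs = _series(t, np.full(24, 25.0), 15)
        with pytest.raises(ValueError, match="cadence"):
            rs.pair_series(obs, _snapshots("2012-01-01", 2))

    def test_no_matchups_outside_overlap(self):
        t = pd.date_range("2012-01-01", periods=288, freq="5min", tz="UTC")
        obs = _series(t, np.full(288, 25.0), 5)
        model = _snapshots("2011-12-31", 24)  # starts a day before obs
        pairs = rs.pair_series(obs, model, min_window_n=1)
        assert pairs["time"].min() >= obs.timestamps[0]
        assert pairs["time"].max() <= obs.timestamps[-1]

    def test_sparse_windows_flagged_and_dropped(self):
        t = pd.date_range("2012-01-01", periods=288, freq="5min", tz="UTC")
        keep = np.ones(288, bool)
        keep[70:74] = False  # leave only one sample near the 06:00 window
        obs = _series(t[keep], np.full(keep.sum(), 25.0), 5)
        strict = rs.pair_series(obs, _snapshots("2012-01-01", 8), min_window_n=3)
        lax = rs.pair_series(obs, _snapshots("2012-01-01", 8), min_window_n=1)
        assert pd.Timestamp("2012-01-01T06:00Z") not in set(strict["time"])
        row = lax[lax.time == pd.Timestamp("2012-01-01T06:00Z")].iloc[0]
        assert row.n_obs_in_window == 1

    def test_pairing_order_independent(self, small_archive):
        # shuffling input rows of the paired frame reproduces the same dataset
        _, _, obs, model, ds = small_archive
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.n)
        reshuffled = PairedDataset(ds.frame.iloc[perm])
        a = ds.frame.sort_values(["site_id", "time"]).reset_index(drop=True)
        b = reshuffled.frame.sort_values(["site_id", "time"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_zero_error_diff_bounded_by_window_range(self):
        cfg = make_site(harmonics=[rs.HarmonicComponent(24.0, 0.3)],
                        noise_sd=0.0, rednoise_sd=0.0)
        truth = rs.generate_true_series(cfg, 0)
        model = rs.degrade_to_model(truth, rs.ModelErrorConfig(), 0)
        pairs = rs.pair_series(truth, model)
        # max |obs_window_mean - snapshot| bounded by truth range over ±10 min
        max_rate = 0.3 * 2 * np.pi / 24.0  # °C per hour
        assert np.abs(pairs["obs"] - pairs["model"]).max() <= max_rate * (10 / 60)


class TestExcludeSpinup:
    def _mixed(self):
        t = (list(pd.date_range("2010-12-29", periods=10, freq="3h", tz="UTC"))
             + list(pd.date_range("2011-01-02", periods=10, freq="3h", tz="UTC")))
        from conftest import pairs_from_arrays
        return pairs_from_arrays(np.full(20, 25.0), np.full(20, 25.1), times=t)

    def test_pre_cutoff_removed(self):
        ds = self._mixed()
        out = rs.exclude_spinup(ds)
        assert out.n == 10
        assert (out.frame["time"] >= pd.Timestamp("2011-01-01T00:00Z")).all()

    def test_all_post_cutoff_unchanged(self, small_archive):
        *_, ds = small_archive
        assert rs.exclude_spinup(ds).n == ds.n

    def test_count_matches_brute_force_scan(self):
        ds = self._mixed()
        cutoff = pd.Timestamp("2011-01-01T00:00Z")
        brute = sum(1 for t in ds.frame["time"] if t >= cutoff)
        assert rs.exclude_spinup(ds).n == brute
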