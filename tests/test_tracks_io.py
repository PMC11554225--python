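"""Track ingest, trip linking, exclusion masking and 1-minute resampling."""

import io as pyio
import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from effortmap import io, tracks
from effortmap.geometry import wrap_heading

from conftest import make_track


def _csv(text):
    return pyio.StringIO(text)


class TestReadTracks:
    HEADER = "vessel_id,timestamp,lat,lon,sog,cog\n"

    def test_well_formed_identity(self):
        pings, rep = io.read_tracks(
            _csv(
                self.HEADER
                + "V1,2016-01-01T00:00:00Z,41.0,-70.5,5.0,90\n"
                + "V1,2016-01-01T00:01:00Z,41.0,-70.49,5.1,91\n"
                + "V1,2016-01-01T00:02:00Z,41.0,-70.48,5.2,92\n"
            )
        )
        assert len(pings) == 3 and rep.n_kept == 3 and rep.rejected == {}

    def test_invalid_latitude_rejected(self):
        pings, rep = io.read_tracks(
            _csv(
                self.HEADER
                + "V1,2016-01-01T00:00:00Z,95.0,-70.5,5.0,90\n"
                + "V1,2016-01-01T00:01:00Z,41.0,-70.5,5.0,90\n"
                + "V1,2016-01-01T00:02:00Z,41.0,-70.5,5.0,90\n"
            )
        )
        assert len(pings) == 2
        assert rep.rejected == {"lat_out_of_range": 1}

    def test_unparseable_timestamp_rejected_not_fatal(self):
        pings, rep = io.read_tracks(
            _csv(
                self.HEADER
                + "V1,not-a-time,41.0,-70.5,5.0,90\n"
                + "V1,2016-01-01T00:01:00Z,41.0,-70.5,5.0,90\n"
            )
        )
        assert len(pings) == 1
        assert rep.rejected["unparseable_timestamp"] == 1

    def test_missing_column_fatal(self):
        with pytest.raises(ValueError, match="missing required columns"):
            io.read_tracks(_csv("vessel_id,timestamp,lat,lon,sog\nV1,2016,1,1,1\n"))

    def test_duplicates_collapse_to_first_matches_seen_set_scan(self, rng):
        n = 1000
        ts = pd.date_range("2016-01-01", periods=n, freq="1min", tz="UTC")
        rows = pd.DataFrame(
            {
                "vessel_id": "V1",
                "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
                "lat": rng.uniform(40, 41, n).round(6),
                "lon": rng.uniform(-71, -70, n).round(6),
                "sog": rng.uniform(0, 10, n).round(2),
                "cog": rng.uniform(0, 360, n).round(1) % 360,
            }
        )
        dup_idx = rng.choice(n, 5, replace=False)
        dupes = rows.iloc[dup_idx].copy()
        dupes["sog"] = 99.0  # later file-order duplicates must lose
        full = pd.concat([rows, dupes])
        pings, rep = io.read_tracks(_csv(full.to_csv(index=False)))

        # oracle: linear scan over file order with a seen-set
        seen, kept = set(), 0
        for _, row in full.iterrows():
            key = (row["vessel_id"], row["timestamp"])
            if key not in seen:
                seen.add(key)
                kept += 1
        assert len(pings) == kept == n
        assert rep.n_duplicates == 5
        assert not (pings["sog"] == 99.0).any()

    def test_marinecadastre_dialect(self):
        pings, _ = io.read_tracks(
            _csv(
                "MMSI,BaseDateTime,LAT,LON,SOG,COG\n"
                "367000001,2016-01-01T00:00:00,41.0,-70.5,5.0,90\n"
            ),
            column_map=io.MARINECADASTRE_COLUMNS,
        )
        assert list(pings["vessel_id"]) == ["367000001"]
        assert pings["timestamp"].dt.tz is not None


class TestLinkTrips:
    def _trips(self):
        return pd.DataFrame(
            {
                "trip_id": ["T1", "T2"],
                "vessel_id": ["V1", "V1"],
                "depart": pd.to_datetime(["2016-01-01T00:00Z", "2016-01-02T00:00Z"], utc=True),
                "return": pd.to_datetime(["2016-01-01T12:00Z", "2016-01-02T12:00Z"], utc=True),
                "landed_value": [1000.0, 2000.0],
            }
        )

    def _pings(self, ts_list):
        return pd.DataFrame(
            {
                "vessel_id": "V1",
                "timestamp": pd.to_datetime(ts_list, utc=True),
                "lat": 41.0,
                "lon": -70.5,
                "sog": 5.0,
                "cog": 0.0,
            }
        )

    def test_midpoint_assigned_and_post_return_unassigned(self):
        pings = self._pings(["2016-01-01T06:00:00Z", "2016-01-01T12:00:01Z"])
        out = tracks.link_trips(pings, self._trips())
        assert out["trip_id"].iloc[0] == "T1"
        assert pd.isna(out["trip_id"].iloc[1])

    def test_overlap_fatal_with_ids(self):
        trips = self._trips()
        trips.loc[1, "depart"] = pd.Timestamp("2016-01-01T11:00Z")
        with pytest.raises(ValueError, match="T1.*T2"):
            tracks.link_trips(self._pings(["2016-01-01T06:00Z"]), trips)

    def test_random_pings_match_brute_force_interval_test(self, rng):
        gaps = rng.uniform(2e4, 1e5, 10)
        starts = np.concatenate([[0.0], np.cumsum(gaps)[:-1]])
        durations = rng.uniform(0.2, 0.8, 10) * gaps  # strictly inside the gap
        trips = pd.DataFrame(
            {
                "trip_id": [f"T{i}" for i in range(10)],
                "vessel_id": "V1",
                "depart": pd.to_datetime(starts * 1e9, utc=True),
                "return": pd.to_datetime((starts + durations) * 1e9, utc=True),
                "landed_value": 0.0,
            }
        )
        pings = self._pings(pd.to_datetime(rng.uniform(0, 1.1e6, 500) * 1e9, utc=True))
        out = tracks.link_trips(pings, trips)
        for i in range(len(pings)):
            expected = None
            for _, t in trips.iterrows():
                if t["depart"] <= pings["timestamp"].iloc[i] <= t["return"]:
                    expected = t["trip_id"]
            got = out["trip_id"].iloc[i]
            assert (pd.isna(got) and expected is None) or got == expected


class TestMaskExclusion:
    def _pings(self, lon, lat):
        return pd.DataFrame(
            {"vessel_id": "V1", "timestamp": pd.Timestamp("2016-01-01", tz="UTC"),
             "lat": lat, "lon": lon, "sog": 5.0, "cog": 0.0}
        )

    def test_empty_polygon_set_keeps_all(self):
        p = self._pings([-70.5, -70.6], [41.0, 41.1])
        assert len(tracks.mask_exclusion_zone(p, {})) == 2

    def test_all_inside_removed_boundary_kept(self):
        poly = box(0.0, 0.0, 1.0, 1.0)
        p = self._pings([0.5, 0.5, 1.0], [0.5, 0.6, 0.5])  # last on boundary
        out = tracks.mask_exclusion_zone(p, [poly])
        assert len(out) == 1 and out["lon"].iloc[0] == 1.0

    def test_random_points_match_ray_casting_oracle(self, rng):
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        xs = rng.uniform(-0.5, 1.5, 400)
        ys = rng.uniform(-0.5, 1.5, 400)
        out = tracks.mask_exclusion_zone(self._pings(xs, ys), [poly])
        kept = set(zip(out["lon"], out["lat"]))

        def ray_cast_inside(x, y):  # strict interior of the unit square
            return 0 < x < 1 and 0 < y < 1

        for x, y in zip(xs, ys):
            assert ((x, y) in kept) == (not ray_cast_inside(x, y))

    def test_invalid_polygon_fatal(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid"):
            tracks.mask_exclusion_zone(self._pings([0.5], [0.5]), [bowtie])


class TestResample:
    def test_already_on_grid_is_identity(self):
        df = make_track(n=10)
        out = tracks.resample_trip(df)
        assert len(out) == 10
        np.testing.assert_allclose(out["lat"], df["lat"])
        np.testing.assert_allclose(out["sog"], df["sog"])
        assert not out["interpolated"].any()

    def test_linear_midpoint_sog(self):
        df = make_track(n=2, step_min=2, sog=4.0)
        df.loc[1, "sog"] = 6.0
        out = tracks.resample_trip(df)
        assert len(out) == 3
        assert out["sog"].iloc[1] == pytest.approx(5.0)
        assert out["interpolated"].tolist() == [False, True, False]

    def test_circular_cog_midpoint(self):
        df = make_track(n=2, step_min=2)
        df.loc[0, "cog"] = 350.0
        df.loc[1, "cog"] = 10.0
        out = tracks.resample_trip(df)
        assert out["cog"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_irregular_track_matches_interpolation_formula(self, rng):
        # 10 irregular pings over 30 min -> 31 rows on an exact 60 s grid
        # whole-second offsets represent exactly in nanosecond timestamps
        offsets = np.sort(
            np.concatenate(
                [[0.0, 1800.0], rng.choice(np.arange(1.0, 1800.0), 8, replace=False)]
            )
        )
        t0 = pd.Timestamp("2016-03-01T00:00:00Z")
        df = pd.DataFrame(
            {
                "vessel_id": "V1",
                "trip_id": "T1",
                "timestamp": t0 + pd.to_timedelta(offsets, unit="s"),
                "lat": rng.uniform(40, 41, 10),
                "lon": rng.uniform(-71, -70, 10),
                "sog": rng.uniform(2, 10, 10),
                "cog": rng.uniform(0, 360, 10),
                "source": "AIS",
                "interpolated": False,
            }
        )
        out = tracks.resample_trip(df)
        assert len(out) == 31
        grid_s = (out["timestamp"] - t0).dt.total_seconds().to_numpy()
        np.testing.assert_allclose(grid_s, 60.0 * np.arange(31))
        # closed-form linear interpolation oracle per field
        for col in ["lat", "lon", "sog"]:
            expect = np.interp(grid_s, offsets, df[col].to_numpy())
            np.testing.assert_allclose(out[col], expect, rtol=1e-12)
        # observed timestamps on the grid keep observed values
        on_grid = np.isin(offsets, grid_s)
        for orig, t in zip(df[on_grid].itertuples(), offsets[on_grid]):
            row = out[grid_s == t].iloc[0]
            assert row["sog"] == orig.sog and not row["interpolated"]

    def test_idempotent(self, rng):
        df = make_track(n=25, sog=rng.uniform(3, 8, 25), cog=rng.uniform(0, 360, 25))
        once = tracks.resample_trip(df)
        twice = tracks.resample_trip(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_overshoot_between_neighbours(self, rng):
        offsets = np.sort(np.concatenate([[0.0, 600.0], rng.uniform(1, 599, 5)]))
        sog = rng.uniform(0, 12, 7)
        df = pd.DataFrame(
            {
                "vessel_id": "V1",
                "trip_id": "T1",
                "timestamp": pd.Timestamp("2016-01-01", tz="UTC")
                + pd.to_timedelta(offsets, unit="s"),
                "lat": 41.0, "lon": -70.5, "sog": sog,
                "cog": 0.0, "source": "AIS", "interpolated": False,
            }
        )
        out = tracks.resample_trip(df)
        assert out["sog"].min() >= sog.min() - 1e-12
        assert out["sog"].max() <= sog.max() + 1e-12

    def test_large_gap_splits_segments(self):
        a = make_track(n=5)
        b = make_track(n=5, t0="2016-03-01T02:00:00Z")
        df = pd.concat([a, b], ignore_index=True).drop(columns="segment")
        out = tracks.resample_trip(df, max_gap_s=1800)
        assert set(out["segment"]) == {0, 1}
        # no fabricated pings inside the 2 h gap
        gap = (out["timestamp"] > a["timestamp"].iloc[-1]) & (
            out["timestamp"] < b["timestamp"].iloc[0]
        )
        assert not gap.any()

    def test_single_ping_warns(self):
        df = make_track(n=1)
        with pytest.warns(UserWarning, match="single ping"):
            out = tracks.resample_trip(df)
        assert len(out) == 1
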