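"""GPS mobility: projection, segmentation, imputation, locations, features."""

import numpy as np
import pandas as pd
import pytest

from phenotrack import mobility
from phenotrack.config import MobilityConfig
from phenotrack.mobility import (
    FLIGHT,
    GAP,
    PAUSE,
    PlanarRef,
    SignificantLocationSet,
    bin_day_positions,
    daily_mobility_features,
    detect_home,
    impute_gaps,
    inverse_projection,
    make_segments,
    project_to_plane,
    routine_similarity,
    segment_flights_pauses,
    significant_locations,
)


def seg_row(kind, t0, t1, p0, p1, provenance="observed"):
    return dict(kind=kind, t_start=float(t0), t_end=float(t1),
                x_start=float(p0[0]), y_start=float(p0[1]),
                x_end=float(p1[0]), y_end=float(p1[1]), provenance=provenance)


def track_from(points):
    """[(t_s, x, y), ...] -> planar track frame (timestamps in ms)."""
    t, x, y = zip(*points)
    return pd.DataFrame({"timestamp": (np.array(t) * 1000).astype(np.int64),
                         "x": np.array(x, float), "y": np.array(y, float)})


class TestProjection:
    def test_milli_degree_of_latitude_is_111_meters(self):
        gps = pd.DataFrame({"timestamp": [0, 1000],
                            "latitude": [42.0, 42.001],
                            "longitude": [-71.0, -71.0],
                            "accuracy": [5.0, 5.0]})
        track, _ = project_to_plane(gps)
        d = np.hypot(track["x"].diff().iloc[1], track["y"].diff().iloc[1])
        assert d == pytest.approx(111.2, abs=0.5)

    def test_identical_points_have_zero_distance(self):
        gps = pd.DataFrame({"timestamp": [0, 1000], "latitude": [42.0, 42.0],
                            "longitude": [-71.0, -71.0], "accuracy": [5.0, 5.0]})
        track, _ = project_to_plane(gps)
        assert np.hypot(track["x"].diff().iloc[1], track["y"].diff().iloc[1]) == 0

    def test_projection_round_trips_through_inverse(self):
        rng = np.random.default_rng(0)
        gps = pd.DataFrame({"timestamp": np.arange(20) * 1000,
                            "latitude": 42.3 + rng.normal(0, 0.02, 20),
                            "longitude": -71.1 + rng.normal(0, 0.02, 20),
                            "accuracy": np.full(20, 5.0)})
        track, ref = project_to_plane(gps)
        lat, lon = inverse_projection(track["x"], track["y"], ref)
        assert np.allclose(lat, gps["latitude"], atol=1e-9)
        assert np.allclose(lon, gps["longitude"], atol=1e-9)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            project_to_plane(pd.DataFrame(columns=["timestamp", "latitude",
                                                   "longitude", "accuracy"]))


class TestSegmentation:
    def test_jittered_stationary_points_collapse_to_single_pause(self):
        rng = np.random.default_rng(1)
        pts = [(t, rng.uniform(-2.5, 2.5), rng.uniform(-2.5, 2.5))
               for t in range(0, 600, 10)]
        seg = segment_flights_pauses(track_from(pts))
        pauses = seg[seg["kind"] == PAUSE]
        assert len(pauses) == 1
        assert pauses.iloc[0]["t_end"] - pauses.iloc[0]["t_start"] == 590_000

    def test_two_distant_fixes_become_one_flight(self):
        seg = segment_flights_pauses(track_from([(0, 0, 0), (30, 100, 0)]))
        flights = seg[seg["kind"] == FLIGHT]
        assert len(flights) == 1
        f = flights.iloc[0]
        assert np.hypot(f["x_end"] - f["x_start"], f["y_end"] - f["y_start"]) == 100

    def test_planted_pauses_and_flights_recovered(self):
        cfg = MobilityConfig()
        anchors = [(0.0, 0.0), (500.0, 0.0), (500.0, 800.0)]
        pts = []
        t = 0.0
        for i, (ax, ay) in enumerate(anchors):
            for _ in range(60):  # 10-min pause at each anchor
                pts.append((t, ax, ay))
                t += 10
            if i < len(anchors) - 1:  # 100 s flight to the next anchor
                nx, ny = anchors[i + 1]
                for k in range(10):
                    f = k / 10
                    pts.append((t, ax + f * (nx - ax), ay + f * (ny - ay)))
                    t += 10
        seg = segment_flights_pauses(track_from(pts), cfg)
        pauses = seg[seg["kind"] == PAUSE]
        flights = seg[seg["kind"] == FLIGHT]
        assert len(pauses) == 3
        assert len(flights) == 2
        for (ax, ay), (_, p) in zip(anchors, pauses.iterrows()):
            assert np.hypot(p["x_start"] - ax, p["y_start"] - ay) < cfg.pause_radius_m

    def test_long_gap_becomes_gap_segment(self):
        pts = [(0, 0, 0), (10, 0, 0), (20, 0, 0), (1000, 50, 0), (1010, 50, 0)]
        seg = segment_flights_pauses(track_from(pts))
        gaps = seg[seg["kind"] == GAP]
        assert len(gaps) == 1
        g = gaps.iloc[0]
        assert (g["x_start"], g["x_end"]) == (0.0, 50.0)

    def test_empty_stream_gives_empty_sequence(self):
        seg = segment_flights_pauses(pd.DataFrame(columns=["timestamp", "x", "y"]))
        assert len(seg) == 0

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            segment_flights_pauses(track_from([(10, 0, 0), (0, 1, 1)]))


class TestImputation:
    def _segments_with_gap(self, gap_end_pos=(0.0, 0.0)):
        rows = [
            seg_row(PAUSE, 0, 3_600_000, (0, 0), (0, 0)),
            seg_row(GAP, 3_600_000, 7_200_000, (0, 0), gap_end_pos),
            seg_row(PAUSE, 7_200_000, 10_800_000, gap_end_pos, gap_end_pos),
        ]
        return make_segments(rows)

    def test_no_gaps_is_identity(self):
        seg = make_segments([seg_row(PAUSE, 0, 1000, (0, 0), (0, 0))])
        out = impute_gaps(seg, rng=np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, seg)

    def test_same_position_gap_with_pause_donors_becomes_pause_there(self):
        seg = self._segments_with_gap()
        out = impute_gaps(seg, method="resampling", rng=np.random.default_rng(0))
        imputed = out[out["provenance"] == "imputed"]
        assert len(imputed) >= 1
        assert (imputed["kind"] == PAUSE).all()
        assert np.allclose(imputed[["x_start", "y_start", "x_end", "y_end"]], 0.0)

    @pytest.mark.parametrize("method", ["resampling", "linear"])
    def test_imputed_subsequence_matches_gap_endpoints_exactly(self, method):
        seg = self._segments_with_gap(gap_end_pos=(800.0, -300.0))
        out = impute_gaps(seg, method=method, rng=np.random.default_rng(3))
        imputed = out[out["provenance"] == "imputed"].sort_values("t_start")
        assert imputed.iloc[0]["t_start"] == 3_600_000
        assert imputed.iloc[-1]["t_end"] == 7_200_000
        assert (imputed.iloc[0]["x_start"], imputed.iloc[0]["y_start"]) == (0.0, 0.0)
        assert (imputed.iloc[-1]["x_end"], imputed.iloc[-1]["y_end"]) == (800.0, -300.0)
        # contiguity inside the filled gap
        t = imputed[["t_start", "t_end"]].to_numpy()
        assert np.allclose(t[1:, 0], t[:-1, 1])

    def test_no_donors_falls_back_to_linear_with_warning(self):
        seg = make_segments([seg_row(GAP, 0, 1000, (0, 0), (10, 0))])
        with pytest.warns(UserWarning, match="linear"):
            out = impute_gaps(seg, method="resampling", rng=np.random.default_rng(0))
        assert (out["kind"] == FLIGHT).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            impute_gaps(make_segments([]), method="spline")


class TestHomeAndLocations:
    def test_stationary_subject_home_is_that_location(self):
        seg = make_segments(
            [seg_row(PAUSE, 0, 2 * 86_400_000, (120.0, -40.0), (120.0, -40.0))]
        )
        home = detect_home(seg)
        assert np.allclose(home, [120.0, -40.0], atol=1e-6)

    def test_home_follows_majority_of_nights(self):
        rows = []
        for d in range(10):
            base = d * 86_400_000
            pos = (0.0, 0.0) if d < 9 else (5000.0, 0.0)
            rows.append(seg_row(PAUSE, base, base + 8 * 3_600_000, pos, pos))  # 00-08h
            rows.append(seg_row(PAUSE, base + 12 * 3_600_000, base + 20 * 3_600_000,
                                (1000.0, 1000.0), (1000.0, 1000.0)))  # daytime
        home = detect_home(make_segments(rows))
        assert np.hypot(home[0], home[1]) < 50

    def test_simulated_home_recovered_within_50_m(self, small_cohort, small_features):
        sub = small_cohort.demographics["subject"].iloc[0]
        from phenotrack.mobility import subject_mobility_days
        from phenotrack.simulate import CITY_REF

        # project about the simulator's reference so coordinates are comparable
        res = subject_mobility_days(
            small_cohort.gps[sub], tz="UTC", seed=1,
            gps_on_s=small_cohort.config.gps_on_s, gps_off_s=small_cohort.config.gps_off_s,
            ref=CITY_REF,
        )
        assert np.hypot(*(res.home - small_cohort.homes[sub])) < 50

    def test_no_pauses_means_no_home(self):
        seg = make_segments([seg_row(FLIGHT, 0, 1000, (0, 0), (100, 0))])
        assert detect_home(seg) is None

    def test_single_cluster_when_all_pauses_close(self):
        rows = [seg_row(PAUSE, i * 1000, i * 1000 + 900, (i, i), (i, i)) for i in range(5)]
        locs = significant_locations(make_segments(rows))
        assert locs.k == 1

    def test_two_distant_anchors_give_two_clusters_near_truth(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            anchor = (0.0, 0.0) if i % 2 == 0 else (2000.0, 0.0)
            p = (anchor[0] + rng.normal(0, 20), anchor[1] + rng.normal(0, 20))
            rows.append(seg_row(PAUSE, i * 10_000, i * 10_000 + 9000, p, p))
        locs = significant_locations(make_segments(rows))
        assert locs.k == 2
        d0 = np.linalg.norm(locs.centroids - np.array([0.0, 0.0]), axis=1).min()
        d1 = np.linalg.norm(locs.centroids - np.array([2000.0, 0.0]), axis=1).min()
        assert d0 < 100 and d1 < 100

    def test_k_max_one_forces_single_cluster(self):
        rng = np.random.default_rng(0)
        rows = [seg_row(PAUSE, i * 1000, i * 1000 + 900,
                        (rng.uniform(0, 5000), 0), (rng.uniform(0, 5000), 0))
                for i in range(10)]
        locs = significant_locations(make_segments(rows), MobilityConfig(k_max=1))
        assert locs.k == 1


class TestDailyFeatures:
    def _stationary_day(self, pos=(0.0, 0.0)):
        return make_segments([seg_row(PAUSE, 0, 86_400_000, pos, pos)])

    def test_stationary_day_closed_form(self):
        day = self._stationary_day()
        locs = SignificantLocationSet(np.array([[0.0, 0.0]]))
        f = daily_mobility_features(day, home=np.zeros(2), locations=locs)
        assert f["distance_m"] == 0
        assert f["radius_of_gyration_m"] == 0
        assert f["max_diameter_m"] == 0
        assert f["home_time_min"] == pytest.approx(1440)
        assert f["sig_location_entropy"] == 0
        assert f["prob_pause"] == pytest.approx(1.0)

    def test_two_location_equal_time_day_closed_form(self):
        half = 43_200_000
        a, b = (0.0, 0.0), (1000.0, 0.0)
        day = make_segments([
            seg_row(PAUSE, 0, half, a, a),
            seg_row(FLIGHT, half, half + 1, a, b),
            seg_row(PAUSE, half + 1, 86_400_000 - 1, b, b),
            seg_row(FLIGHT, 86_400_000 - 1, 86_400_000, b, a),
        ])
        locs = SignificantLocationSet(np.array([[0.0, 0.0], [1000.0, 0.0]]))
        f = daily_mobility_features(day, home=np.zeros(2), locations=locs)
        assert f["distance_m"] == pytest.approx(2000.0)
        assert f["max_home_distance_m"] == pytest.approx(1000.0)
        assert f["radius_of_gyration_m"] == pytest.approx(500.0, rel=1e-4)
        assert f["sig_location_entropy"] == pytest.approx(np.log(2), rel=1e-6)
        assert f["n_significant_locations"] == 2

    def test_single_flight_day_has_zero_flight_sd(self):
        day = make_segments([
            seg_row(PAUSE, 0, 1000, (0, 0), (0, 0)),
            seg_row(FLIGHT, 1000, 2000, (0, 0), (300.0, 400.0)),
            seg_row(PAUSE, 2000, 86_400_000, (300.0, 400.0), (300.0, 400.0)),
        ])
        f = daily_mobility_features(day, home=None, locations=None)
        assert f["mean_flight_length_m"] == pytest.approx(500.0)
        assert f["sd_flight_length_m"] == 0.0

    def test_empty_day_gives_all_missing(self):
        f = daily_mobility_features(make_segments([]), home=None, locations=None)
        assert all(np.isnan(v) for v in f.values())

    def test_distances_invariant_under_translation_and_rog_under_rotation(self):
        day = make_segments([
            seg_row(PAUSE, 0, 10_000_000, (0, 0), (0, 0)),
            seg_row(FLIGHT, 10_000_000, 11_000_000, (0, 0), (700.0, -300.0)),
            seg_row(PAUSE, 11_000_000, 86_400_000, (700.0, -300.0), (700.0, -300.0)),
        ])
        f0 = daily_mobility_features(day, home=np.zeros(2), locations=None)
        shifted = day.copy()
        for c in ("x_start", "x_end"):
            shifted[c] += 12345.0
        for c in ("y_start", "y_end"):
            shifted[c] -= 999.0
        f1 = daily_mobility_features(shifted, home=np.array([12345.0, -999.0]),
                                     locations=None)
        for k in ("distance_m", "max_diameter_m", "max_home_distance_m",
                  "radius_of_gyration_m", "home_time_min"):
            assert f1[k] == pytest.approx(f0[k], rel=1e-9)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = day.copy()
        xy0 = day[["x_start", "y_start"]].to_numpy() @ R.T
        xy1 = day[["x_end", "y_end"]].to_numpy() @ R.T
        rotated[["x_start", "y_start"]] = xy0
        rotated[["x_end", "y_end"]] = xy1
        f2 = daily_mobility_features(rotated, home=np.zeros(2), locations=None)
        assert f2["radius_of_gyration_m"] == pytest.approx(f0["radius_of_gyration_m"], rel=1e-9)

    def test_entropy_bounded_by_log_cluster_count(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            k = rng.integers(1, 5)
            centroids = rng.uniform(-5000, 5000, (k, 2))
            rows = []
            for i in range(12):
                c = centroids[rng.integers(k)]
                rows.append(seg_row(PAUSE, i * 3_600_000, i * 3_600_000 + int(rng.uniform(1, 3000)) * 1000,
                                    c, c))
            locs = SignificantLocationSet(centroids)
            f = daily_mobility_features(make_segments(rows), home=None, locations=locs)
            assert 0 <= f["sig_location_entropy"] <= np.log(k) + 1e-12


class TestRoutines:
    def test_identical_days_have_similarity_one(self):
        bins = np.tile([[100.0, 200.0]], (48, 1))
        assert routine_similarity(bins, bins.copy(), 500.0) == 1.0

    def test_far_apart_days_have_similarity_zero(self):
        a = np.tile([[0.0, 0.0]], (48, 1))
        b = np.tile([[10_000.0, 0.0]], (48, 1))
        assert routine_similarity(a, b, 500.0) == 0.0

    def test_half_colocated_bins_give_half(self):
        a = np.tile([[0.0, 0.0]], (48, 1))
        b = a.copy()
        b[24:] = [10_000.0, 0.0]
        assert routine_similarity(a, b, 500.0) == 0.5

    def test_no_coobserved_bins_is_missing(self):
        a = np.full((48, 2), np.nan)
        a[:24] = 0.0
        b = np.full((48, 2), np.nan)
        b[24:] = 0.0
        assert np.isnan(routine_similarity(a, b, 500.0))

    def test_bin_positions_time_weighted_mean(self):
        day = make_segments([seg_row(PAUSE, 0, 86_400_000, (50.0, 60.0), (50.0, 60.0))])
        bins = bin_day_positions(day, 0.0, 86_400_000.0, 30)
        assert bins.shape == (48, 2)
        assert np.allclose(bins, [50.0, 60.0])
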