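"""Rule-cascade tests: boundary senses of every filter and the
vehicle detector, plus orchestration precedence."""

import numpy as np
import pandas as pd
import pytest

from iotrack.classify import (
    RuleConfig,
    apply_duration_filters,
    bridge_drive_bouts,
    classify_track,
    corrections,
    detect_drive_minutes,
    footprint_filter,
)
from iotrack.destinations import Area, Cluster, cluster_stats, detect_destinations, st_dbscan
from iotrack.preprocess import annotate_speeds

from conftest import T0, make_track, xy_to_latlon


def _cluster(instance=10.0, speed=1.2, lux=np.nan, offset_m=0.0, cid=0):
    lat, lon = xy_to_latlon(offset_m, 0.0)
    return Cluster(
        cid=cid,
        member_index=np.arange(12),
        aid=0,
        mean_lat=float(lat),
        mean_lon=float(lon),
        t_start=T0,
        t_end=T0 + pd.Timedelta(minutes=instance),
        instance_time_min=instance,
        mean_speed_mps=speed,
        mean_lux=lux,
    )


def _area(area_time=10.0):
    lat, lon = xy_to_latlon(0.0, 0.0)
    return Area(aid=0, cluster_ids=[0], mean_lat=float(lat), mean_lon=float(lon), area_time_min=area_time)


class TestDurationFilters:
    @pytest.mark.parametrize(
        "instance, area_time, offset_m, speed, expected",
        [
            (35.0, 35.0, 50.0, 1.2, "F1"),   # long dwell
            (30.0, 30.0, 50.0, 1.2, "F1"),   # inclusive boundary
            (29.9, 29.9, 50.0, 1.2, None),   # just below, far from centre, fast
            (16.0, 31.0, 50.0, 1.2, "F2"),   # moderate dwell at a major destination
            (15.0, 31.0, 50.0, 1.2, None),   # strictly over 15 required
            (16.0, 30.0, 50.0, 1.2, None),   # strictly over 30 required
            (16.0, 16.0, 3.0, 1.2, "F3"),    # near destination centre, >= 15 min
            (16.0, 16.0, 9.999, 1.2, "F3"),  # just inside the 10 m boundary
            (16.0, 16.0, 10.001, 1.2, None),  # just beyond 10 m
            (14.9, 14.9, 3.0, 1.2, None),    # too short for F3
            (16.0, 16.0, 50.0, 0.5, "F4"),   # slow singleton destination
            (15.0, 15.0, 50.0, 0.89, "F4"),  # inclusive 15 min, strict < 0.9
            (16.0, 16.0, 50.0, 0.9, None),   # speed boundary is strict
            (14.9, 14.9, 50.0, 0.5, None),   # too short for F4
        ],
    )
    def test_filter_boundaries(self, instance, area_time, offset_m, speed, expected):
        cluster = _cluster(instance=instance, speed=speed, offset_m=offset_m)
        assert apply_duration_filters(cluster, _area(area_time)) == expected

    def test_first_matching_filter_wins(self):
        cluster = _cluster(instance=35.0, speed=0.1, offset_m=0.0)
        assert apply_duration_filters(cluster, _area(40.0)) == "F1"

    def test_monotone_in_f1_threshold(self):
        cluster = _cluster(instance=25.0, speed=2.0, offset_m=50.0)
        loose = RuleConfig(f1_min=20.0)
        tight = RuleConfig(f1_min=30.0)
        assert apply_duration_filters(cluster, _area(25.0), loose) == "F1"
        assert apply_duration_filters(cluster, _area(25.0), tight) is None


class TestFootprintFilter:
    def _cluster_with_points(self, inside, outside):
        # outside points at 21 m keep the mean centre within the footprint
        xy = [(0, 0)] * inside + [(21, 0)] * outside
        track = make_track(xy)
        c = cluster_stats(track, np.zeros(len(xy), dtype=int))[0]
        return track, c

    def test_majority_inside_is_indoor(self, square_building):
        track, c = self._cluster_with_points(8, 4)
        assert footprint_filter(track, c, square_building)

    def test_center_outside_blocks(self, square_building):
        xy = [(100, 0)] * 12  # all points (and centre) outside
        track = make_track(xy)
        c = cluster_stats(track, np.zeros(12, dtype=int))[0]
        assert not footprint_filter(track, c, square_building)

    def test_exactly_half_inside_is_not_enough(self, square_building):
        track, c = self._cluster_with_points(6, 6)
        c.mean_lat, c.mean_lon = (float(v) for v in xy_to_latlon(0.0, 0.0))
        assert not footprint_filter(track, c, square_building)

    def test_boundary_point_counts_as_inside(self, square_building):
        # points exactly on the footprint edge (x = 10 m)
        track = make_track([(10.0, 0.0)] * 12)
        c = cluster_stats(track, np.zeros(12, dtype=int))[0]
        c.mean_lat, c.mean_lon = (float(v) for v in xy_to_latlon(10.0, 0.0))
        assert footprint_filter(track, c, square_building)


class TestCorrections:
    def test_lux_over_threshold_reclassified(self):
        c = _cluster(lux=300.0)
        out = corrections(make_track([(0, 0)] * 12), {0: "F1"}, [c], parks=None)
        assert out[0] == "LUX"

    def test_lux_at_threshold_stays_indoor(self):
        c = _cluster(lux=240.0)
        out = corrections(make_track([(0, 0)] * 12), {0: "F1"}, [c], parks=None)
        assert out[0] == "F1"

    def test_missing_lux_skips_check(self):
        c = _cluster(lux=np.nan)
        out = corrections(make_track([(0, 0)] * 12), {0: "F1"}, [c], parks=None)
        assert out[0] == "F1"

    def test_park_majority_reclassified(self, square_park):
        xy = [(0, 0)] * 8 + [(100, 0)] * 4  # 8/12 inside the park, centre inside
        track = make_track(xy)
        c = cluster_stats(track, np.zeros(12, dtype=int))[0]
        c.mean_lat, c.mean_lon = (float(v) for v in xy_to_latlon(0.0, 0.0))
        out = corrections(track, {0: "F1"}, [c], parks=square_park)
        assert out[0] == "PARK"

    def test_lux_applied_before_park(self, square_park):
        track = make_track([(0, 0)] * 12)
        c = cluster_stats(track, np.zeros(12, dtype=int))[0]
        c.mean_lux = 500.0
        out = corrections(track, {0: "F1"}, [c], parks=square_park)
        assert out[0] == "LUX"  # provenance shows lux fired first

    def test_lowering_lux_threshold_shrinks_indoor_set(self):
        clusters = [_cluster(lux=150.0, cid=0), _cluster(lux=220.0, cid=1)]
        track = make_track([(0, 0)] * 12)
        high = corrections(track, {0: "F1", 1: "F1"}, clusters, None, RuleConfig(lux_threshold=240))
        low = corrections(track, {0: "F1", 1: "F1"}, clusters, None, RuleConfig(lux_threshold=200))
        indoor_high = {cid for cid, r in high.items() if r not in ("LUX", "PARK")}
        indoor_low = {cid for cid, r in low.items() if r not in ("LUX", "PARK")}
        assert indoor_low <= indoor_high
        assert indoor_low == {0}


def _speed_track(speeds_mps, epoch_s=5):
    """Track moving east with the given per-epoch speeds."""
    xs = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_mps) * epoch_s)])
    track = make_track([(x, 0.0) for x in xs])
    return annotate_speeds(track)


class TestDriveDetection:
    def test_fast_minute_flags_all_epochs(self):
        track = _speed_track([7.0] * 24)
        flags = detect_drive_minutes(track)
        assert flags[1:].all()

    def test_threshold_minute_not_flagged(self):
        # speeds pinned to the exact threshold float: strictly-over rule
        track = make_track([(0, 0)] * 24)
        track["speed_mps"] = 6.944
        assert not detect_drive_minutes(track).any()
        track["speed_mps"] = 6.9441
        assert detect_drive_minutes(track).all()

    def test_stationary_track_unflagged(self):
        track = annotate_speeds(make_track([(0, 0)] * 48))
        assert not detect_drive_minutes(track).any()

    def test_windows_aligned_to_first_epoch(self):
        # 12 slow epochs then 12 fast: only the second window is flagged
        track = _speed_track([0.5] * 12 + [12.0] * 12)
        flags = detect_drive_minutes(track)
        assert not flags[:12].any()
        assert flags[13:24].all()


def _flags(pattern, epochs_per_min=12):
    """'D'/'N' pattern string in minutes -> boolean epoch flags."""
    return np.concatenate([[c == "D"] * epochs_per_min for c in pattern]).astype(bool)


class TestBridging:
    def test_gap_bridged_when_left_bout_long(self):
        flags = _flags("DDDNND")
        out = bridge_drive_bouts(flags)
        assert out.all()

    def test_gap_not_bridged_when_both_bouts_short(self):
        flags = _flags("DNND")
        out = bridge_drive_bouts(flags)
        assert np.array_equal(out, flags)

    def test_long_gap_never_bridged(self):
        flags = _flags("DDDNNNNDDD")  # 4-min gap >= 3-min cap
        out = bridge_drive_bouts(flags)
        assert np.array_equal(out, flags)

    def test_leading_and_trailing_gaps_untouched(self):
        flags = _flags("NDDDN")
        out = bridge_drive_bouts(flags)
        assert np.array_equal(out, flags)

    def test_fixed_point_chains_bridges(self):
        # after the first bridge the merged bout supports the second one
        flags = _flags("DDDNNDNND")
        out = bridge_drive_bouts(flags)
        assert out.all()
        assert np.array_equal(bridge_drive_bouts(out), out)  # idempotent at fixed point


class TestClassifyTrack:
    def test_no_clusters_no_driving_all_default_out(self):
        track = annotate_speeds(make_track([(20 * i, 0) for i in range(30)]))
        labeled, info = classify_track(track, [], [], None, None)
        assert (labeled["label"] == "outdoor").all()
        assert (labeled["rule"] == "DEFAULT-OUT").all()

    def test_indoor_precedence_over_drive(self):
        # stationary dwell embedded in an artificially fast minute:
        # cluster label must win over the vehicle flag
        track = annotate_speeds(make_track([(0, 0)] * 60))
        track["speed_mps"] = 8.0  # forced fast windows
        labels, clusters, areas = detect_destinations(track)
        cfg = RuleConfig(f1_min=4.0)  # dwell of 5 min marked indoor via F1
        labeled, _ = classify_track(track, clusters, areas, None, None, cfg)
        assert (labeled["label"] == "indoor").all()

    def test_every_epoch_labeled_exactly_once(self):
        track = annotate_speeds(make_track([(0, 0)] * 200 + [(12 * 5 * i, 0) for i in range(1, 60)]))
        labels, clusters, areas = detect_destinations(track)
        labeled, _ = classify_track(track, clusters, areas, None, None)
        assert labeled["label"].isin(["indoor", "outdoor", "vehicle"]).all()
        assert len(labeled) == len(track)

    def test_pipeline_runs_without_layers(self):
        track = annotate_speeds(make_track([(0, 0)] * 400))
        labels, clusters, areas = detect_destinations(track)
        labeled, info = classify_track(track, clusters, areas, None, None)
        assert not info["footprint_filter_used"]
        assert labeled["label"].notna().all()

    def test_drive_and_bridge_provenance(self):
        speeds = [12.0] * 36 + [1.0] * 12 + [12.0] * 36
        track = _speed_track(speeds)
        labeled, _ = classify_track(track, [], [], None, None)
        assert (labeled["label"] == "vehicle").all()
        assert (labeled["rule"].iloc[:36] == "DRIVE").all()
        assert (labeled["rule"].iloc[36:48] == "DRIVE-BRIDGE").all()
        assert (labeled["rule"].iloc[48:] == "DRIVE").all()
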