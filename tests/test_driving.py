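import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vergedrive.driving import (
    DrivingEventLog, DrivingTrace, LaneGeometry, count_events,
    compute_driving_metrics, default_geometry, lane_excursion_distances,
    mean_speed, reaction_times, read_event_log, read_trace_csv, sdlp,
    speed_sd, write_event_log, write_trace_csv,
)


def make_trace(lat, speed=50.0, section="dual_carriageway", ds=10.0,
               geometry=None):
    n = len(lat)
    df = pd.DataFrame({
        "t": np.arange(n, dtype=float),
        "s_path": ds * np.arange(n),
        "speed": np.broadcast_to(np.asarray(speed, float), (n,)).copy(),
        "lat_offset": np.asarray(lat, float),
        "section": section,
    })
    return DrivingTrace(df, geometry or default_geometry())


class TestSpeedStats:
    def test_constant_speed(self):
        tr = make_trace([0] * 5, speed=50.0)
        assert mean_speed(tr, "dual_carriageway") == 50.0
        assert speed_sd(tr, "dual_carriageway") == 0.0

    def test_two_point_sd(self):
        tr = make_trace([0, 0], speed=[40.0, 60.0])
        assert mean_speed(tr, "dual_carriageway") == 50.0
        assert speed_sd(tr, "dual_carriageway") == pytest.approx(math.sqrt(200))

    def test_alternating_dense(self):
        tr = make_trace([0] * 400, speed=[115.0, 125.0] * 200)
        assert mean_speed(tr, "dual_carriageway") == pytest.approx(120.0)

    def test_empty_section_errors(self):
        tr = make_trace([0, 0])
        with pytest.raises(ValueError):
            mean_speed(tr, "inner_city")

    def test_translation_invariance_and_scaling(self, rng):
        v = rng.uniform(30, 90, 50)
        a = speed_sd(make_trace(np.zeros(50), speed=v), "dual_carriageway")
        b = speed_sd(make_trace(np.zeros(50), speed=v + 17.0), "dual_carriageway")
        c = speed_sd(make_trace(np.zeros(50), speed=v * 2.0), "dual_carriageway")
        assert b == pytest.approx(a)
        assert c == pytest.approx(2 * a)


class TestSdlp:
    def test_constant_offset_zero(self):
        assert sdlp(make_trace([0.3] * 10), "dual_carriageway") \
            == pytest.approx(0.0, abs=1e-12)

    def test_four_point_oracle(self):
        # sample SD (n-1) of {0.4, 0.6, 0.4, 0.6}
        expected = np.std([0.4, 0.6, 0.4, 0.6], ddof=1)
        assert sdlp(make_trace([0.4, 0.6, 0.4, 0.6]), "dual_carriageway") \
            == pytest.approx(expected)
        assert expected == pytest.approx(0.11547, abs=1e-5)

    def test_sinusoid_closed_form(self):
        # dense uniform sampling over whole periods: SD -> A / sqrt(2)
        amp = 0.4
        t = np.arange(0, 10, 0.001)
        lat = amp * np.sin(2 * math.pi * t)          # 10 whole periods
        assert sdlp(make_trace(lat, ds=0.5), "dual_carriageway") \
            == pytest.approx(amp / math.sqrt(2), rel=0.01)

    def test_translation_invariance(self, rng):
        lat = rng.normal(0, 0.2, 100)
        a = sdlp(make_trace(lat), "dual_carriageway")
        b = sdlp(make_trace(lat + 0.5), "dual_carriageway")
        assert b == pytest.approx(a)

    def test_singleton_section_errors(self):
        df = pd.DataFrame({"t": [0.0, 1.0], "s_path": [0.0, 10.0],
                           "speed": 50.0, "lat_offset": 0.0,
                           "section": ["dual_carriageway", "inner_city"]})
        tr = DrivingTrace(df)
        with pytest.raises(ValueError):
            sdlp(tr, "inner_city")


class TestLaneExcursions:
    def test_inside_lane_all_zero(self):
        assert lane_excursion_distances(make_trace([0.1, -0.5, 0.8, 0.0]),
                                        "dual_carriageway") == (0.0, 0.0, 0.0)

    def test_hand_built_shoulder_and_opposite(self, small_trace):
        # dual carriageway: starts at indices 1,2 invade (+ side) -> 20 m;
        # the -1.0 start has no opposite lane -> warned, dtiol 0
        with pytest.warns(UserWarning, match="no opposite lane"):
            dtis, dtiol, tdtol = lane_excursion_distances(
                small_trace, "dual_carriageway")
        assert (dtis, dtiol, tdtol) == (20.0, 0.0, 20.0)
        # mountain road: one + interval start (10 m), two - starts (20 m)
        dtis, dtiol, tdtol = lane_excursion_distances(small_trace,
                                                      "mountain_road")
        assert (dtis, dtiol, tdtol) == (10.0, 20.0, 30.0)

    def test_exactly_100m_constructed(self):
        lat = np.zeros(30)
        lat[5:15] = 1.2                      # 10 interval starts x 10 m
        tr = make_trace(lat, ds=10.0)
        dtis, _, _ = lane_excursion_distances(tr, "dual_carriageway")
        assert dtis == 100.0

    def test_boundary_contact_is_not_invasion(self):
        # |lat| + half width == lane half width touches but does not cross
        tr = make_trace([0.85, 0.85, 0.85])
        assert lane_excursion_distances(tr, "dual_carriageway")[0] == 0.0

    def test_monotone_in_vehicle_width(self, rng):
        lat = rng.normal(0, 0.6, 200)
        prev = -1.0
        for half in (0.5, 0.7, 0.9, 1.1):
            geom = {"dual_carriageway": LaneGeometry(vehicle_half_width=half)}
            tr = make_trace(lat, geometry=geom)
            tdtol = lane_excursion_distances(tr, "dual_carriageway")[2]
            assert tdtol >= prev
            prev = tdtol

    @given(st.integers(0, 2 ** 31 - 1))
    def test_additivity_any_trace(self, seed):
        r = np.random.default_rng(seed)
        lat = r.normal(0, 0.7, 60)
        geom = {"mountain_road": LaneGeometry(opposite_lane_side=-1)}
        tr = make_trace(lat, section="mountain_road", geometry=geom)
        dtis, dtiol, tdtol = lane_excursion_distances(tr, "mountain_road")
        assert tdtol == dtis + dtiol
        # independent union-mask recomputation
        s = tr.samples["s_path"].to_numpy()
        outside = np.abs(lat[:-1]) > 0.85
        assert np.isclose(np.diff(s)[outside].sum(), tdtol, rtol=1e-12)

    def test_missing_geometry_errors(self, small_trace):
        small_trace.geometry.pop("mountain_road")
        with pytest.raises(ValueError, match="geometry"):
            lane_excursion_distances(small_trace, "mountain_road")


class TestReactionTimes:
    def test_single_match(self):
        ev = DrivingEventLog(brake_light_onsets=[10.0], brake_presses=[10.93])
        res = reaction_times(ev)
        assert res.times == pytest.approx([0.93])
        assert res.mean == pytest.approx(0.93)

    def test_two_onsets_two_presses(self):
        ev = DrivingEventLog(brake_light_onsets=[10.0, 50.0],
                             brake_presses=[10.8, 51.0])
        res = reaction_times(ev)
        assert res.times == pytest.approx([0.8, 1.0])
        assert res.mean == pytest.approx(0.9)

    def test_unmatched_onset_flagged(self):
        ev = DrivingEventLog(brake_light_onsets=[10.0])
        res = reaction_times(ev)
        assert res.times == [] and math.isnan(res.mean)
        assert res.missed_onsets == [10.0]

    def test_press_before_onset_ignored_with_warning(self):
        ev = DrivingEventLog(brake_light_onsets=[10.0], brake_presses=[5.0, 10.4])
        with pytest.warns(UserWarning, match="before the first"):
            res = reaction_times(ev)
        assert res.times == pytest.approx([0.4])
        assert res.ignored_presses == [5.0]

    def test_press_after_next_onset_not_stolen(self):
        # the press at 21.0 belongs to the second onset's window only
        ev = DrivingEventLog(brake_light_onsets=[10.0, 20.0],
                             brake_presses=[21.0])
        res = reaction_times(ev)
        assert res.times == pytest.approx([1.0])
        assert res.missed_onsets == [10.0]

    @given(st.integers(0, 2 ** 31 - 1))
    def test_no_press_reused(self, seed):
        r = np.random.default_rng(seed)
        onsets = np.sort(r.uniform(0, 100, 6))
        presses = np.sort(r.uniform(0, 100, 6))
        res = reaction_times(DrivingEventLog(brake_light_onsets=list(onsets),
                                             brake_presses=list(presses)))
        assert len(res.times) + len(res.missed_onsets) == 6
        assert len(res.times) <= min(len(onsets), len(presses))
        assert all(t > 0 for t in res.times)


def test_count_events():
    assert count_events(DrivingEventLog()) == (0, 0, 0)
    ev = DrivingEventLog(collisions=[1, 2, 3, 4],
                         signaling_mistakes=[5, 6],
                         engine_stalls=[7, 8, 9])
    assert count_events(ev) == (4, 2, 3)


class TestTraceValidation:
    def test_non_monotone_time_rejected(self):
        df = pd.DataFrame({"t": [0.0, 0.0], "s_path": [0, 1], "speed": 1.0,
                           "lat_offset": 0.0, "section": "inner_city"})
        with pytest.raises(ValueError, match="strictly increasing"):
            DrivingTrace(df)

    def test_decreasing_path_rejected(self):
        df = pd.DataFrame({"t": [0.0, 1.0], "s_path": [5, 1], "speed": 1.0,
                           "lat_offset": 0.0, "section": "inner_city"})
        with pytest.raises(ValueError, match="non-decreasing"):
            DrivingTrace(df)

    def test_split_section_rejected(self):
        df = pd.DataFrame({"t": [0., 1., 2.], "s_path": [0, 1, 2],
                           "speed": 1.0, "lat_offset": 0.0,
                           "section": ["a", "b", "a"]})
        with pytest.raises(ValueError, match="contiguous"):
            DrivingTrace(df)


def test_io_round_trip(tmp_path, small_trace):
    trace_path = tmp_path / "trace.csv"
    write_trace_csv(small_trace, trace_path)
    back = read_trace_csv(trace_path)
    pd.testing.assert_frame_equal(back.samples, small_trace.samples)

    ev = DrivingEventLog(brake_light_onsets=[1.0, 4.0], brake_presses=[1.9],
                         collisions=[2.5], engine_stalls=[3.0, 3.5])
    ev_path = tmp_path / "events.jsonl"
    write_event_log(ev, ev_path)
    back_ev = read_event_log(ev_path)
    assert back_ev == ev
    with pytest.raises(ValueError, match="unknown event type"):
        (tmp_path / "bad.jsonl").write_text(json.dumps({"type": "x", "t": 1}))
        read_event_log(tmp_path / "bad.jsonl")


def test_compute_driving_metrics_names(small_trace):
    ev = DrivingEventLog(brake_light_onsets=[6.5], brake_presses=[7.3],
                         collisions=[8.0])
    with pytest.warns(UserWarning):
        m = compute_driving_metrics(small_trace, ev)
    assert m["mr_tdtol"] == m["mr_dtis"] + m["mr_dtiol"]
    assert m["mr_reaction_time"] == pytest.approx(0.8)
    assert m["collisions"] == 1
    assert "ic_mean_speed" not in m  # trace has no inner-city section
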