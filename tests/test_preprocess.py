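"""Detection filters: clustering, central retention, edges, lifespans,
co-detection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtrap_avoidance.data import SurveyDataset
from camtrap_avoidance.preprocess import (
    TestParams,
    cluster_events,
    co_detection_rate,
    edge_exclusion,
    independence_filter,
    lifespan_filter,
    preprocess_survey,
)

from conftest import make_detections, make_rolls


def ts(*hhmm):
    return np.array([np.datetime64(f"2021-06-01T{t}") for t in hhmm])


class TestClustering:
    def test_singleton(self):
        clusters = cluster_events(ts("10:00"))
        assert [list(c) for c in clusters] == [[0]]

    def test_gap_breaks_chain(self):
        clusters = cluster_events(ts("10:00", "10:10", "10:20", "11:40"), 30)
        assert [list(c) for c in clusters] == [[0, 1, 2], [3]]

    def test_transitive_chaining_spans_beyond_gap(self):
        clusters = cluster_events(ts("10:00", "10:29", "10:58"), 30)
        assert [list(c) for c in clusters] == [[0, 1, 2]]

    def test_exact_gap_breaks(self):
        clusters = cluster_events(ts("10:00", "10:30"), 30)
        assert [list(c) for c in clusters] == [[0], [1]]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cluster_events(ts("11:00", "10:00"))

    def test_empty(self):
        assert cluster_events(ts()) == []


class TestIndependenceFilter:
    def test_central_of_three_kept(self):
        times = ts("10:00", "10:10", "10:20")
        assert list(times[independence_filter(times)]) == [np.datetime64("2021-06-01T10:10")]

    def test_singleton_kept(self):
        times = ts("10:00")
        assert list(independence_filter(times)) == [0]

    def test_even_cluster_keeps_earlier_middle(self):
        times = ts("10:00", "10:10", "10:20", "10:29")
        assert list(times[independence_filter(times)]) == [np.datetime64("2021-06-01T10:10")]

    @given(st.lists(st.integers(min_value=0, max_value=5000), min_size=0, max_size=60))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_idempotent_and_one_per_cluster(self, minutes):
        times = np.sort(np.datetime64("2021-06-01T00:00")
                        + np.array(sorted(minutes), dtype="timedelta64[m]"))
        reps = independence_filter(times)
        assert len(reps) == len(cluster_events(times))
        again = independence_filter(times[reps])
        assert np.array_equal(times[reps][again], times[reps])
        assert len(reps) <= len(times)


class TestEdgeExclusion:
    START, END = "2020-01-01T00:00", "2020-02-01T00:00"

    @pytest.mark.parametrize("event,kept", [
        ("2020-01-02T12:00", False),   # < 72 h after deployment
        ("2020-01-15T12:00", True),    # mid-roll
        ("2020-01-30T13:00", False),   # after end - 72 h = 2020-01-29T00:00
        ("2020-01-04T00:00", True),    # exactly start + 72 h (closed)
        ("2020-01-29T00:00", True),    # exactly end - 72 h (closed)
    ])
    def test_boundary_arithmetic(self, event, kept):
        mask = edge_exclusion(ts_one(event), self.START, self.END, 72.0)
        assert mask[0] == kept

    def test_idempotent(self):
        times = np.array(["2020-01-02T12:00", "2020-01-15T12:00",
                          "2020-01-30T13:00"], dtype="datetime64[ns]")
        once = times[edge_exclusion(times, self.START, self.END)]
        twice = once[edge_exclusion(once, self.START, self.END)]
        assert np.array_equal(once, twice)

    def test_oversized_margin_warns_and_empties(self):
        times = ts_one("2020-01-15T12:00")
        with pytest.warns(UserWarning, match="whole roll"):
            mask = edge_exclusion(times, self.START, self.END, margin_h=400.0)
        assert not mask.any()


def ts_one(s):
    return np.array([s], dtype="datetime64[ns]")


class TestLifespanFilter:
    @pytest.mark.parametrize("days,kept", [(90, True), (29.9, False), (30.0, True)])
    def test_strict_30_day_boundary(self, days, kept):
        start = pd.Timestamp("2021-01-01")
        rolls = pd.DataFrame([{
            "roll_id": "R1", "camera_id": "C1", "site_id": "S1",
            "start": start, "end": start + pd.Timedelta(days=days),
        }])
        assert (len(lifespan_filter(rolls, 30.0)) == 1) == kept


class TestCoDetection:
    def test_single_species_is_zero(self):
        det = make_detections([("A", "lion", "2021-01-01T10:00"),
                               ("A", "lion", "2021-01-02T10:00")])
        assert co_detection_rate(det) == 0.0

    def test_half_of_predator_days_co_detected(self):
        det = make_detections([
            ("A", "lion", "2021-01-01T10:00"),
            ("A", "hyena", "2021-01-01T20:00"),
            ("A", "lion", "2021-01-02T10:00"),
        ])
        assert co_detection_rate(det) == pytest.approx(50.0)

    def test_days_are_camera_local(self):
        det = make_detections([
            ("A", "lion", "2021-01-01T10:00"),
            ("B", "hyena", "2021-01-01T10:00"),
        ])
        assert co_detection_rate(det) == 0.0

    def test_no_predators_undefined(self):
        assert co_detection_rate(make_detections([])) is None


class TestTestParams:
    def test_margin_block_mismatch_warns(self):
        with pytest.warns(UserWarning, match="edge_margin"):
            TestParams(edge_margin_h=48.0)

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.0}, {"independence_gap_min": 0.0},
        {"n_blocks_per_side": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError):
                TestParams(**kwargs)


class TestPreprocessSurvey:
    def test_prey_untouched_predators_filtered_rolls_dropped(self):
        rolls = pd.concat([
            make_rolls(("C1", "2021-01-01T00:00", "2021-04-01T00:00")),
            make_rolls(("C2", "2021-01-01T00:00", "2021-01-20T00:00")),  # 19 d
        ], ignore_index=True)
        det = make_detections([
            # prey burst: must NOT be collapsed
            ("C1", "prey", "2021-02-01T10:00"),
            ("C1", "prey", "2021-02-01T10:10"),
            # predator burst: collapses to central, mid-roll
            ("C1", "predator", "2021-02-01T22:00"),
            ("C1", "predator", "2021-02-01T22:05"),
            ("C1", "predator", "2021-02-01T22:10"),
            # predator too close to deployment: edge-excluded
            ("C1", "predator", "2021-01-02T05:00"),
            # anything on the short roll disappears with it
            ("C2", "prey", "2021-01-10T10:00"),
        ])
        ds = SurveyDataset(det, rolls, {"prey": "prey", "predator": "predator"})
        filtered, report = preprocess_survey(ds, TestParams())

        prey = filtered.for_species("prey")
        assert len(prey) == 2 and set(prey["camera_id"]) == {"C1"}
        pred = filtered.for_species("predator")
        assert list(pred["timestamp"]) == [pd.Timestamp("2021-02-01T22:05")]
        assert len(filtered.rolls) == 1
        assert report["lifespan_filter"] == {"rolls_before": 2, "rolls_after": 1}
        assert report["predator_filters"]["before"] == {"predator": 4}
        assert report["predator_filters"]["after"] == {"predator": 1}
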