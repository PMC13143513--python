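"""Block counting, date randomization, and empirical p-values."""

import numpy as np
import pandas as pd
import pytest

from camtrap_avoidance.data import SurveyDataset
from camtrap_avoidance.preprocess import TestParams
from camtrap_avoidance.randtest import (
    block_counts,
    block_labels,
    eligible_dates,
    enumerate_null,
    null_distribution,
    p_values,
    randomize_once,
    run_site_test,
)

from conftest import make_detections, make_rolls

PARAMS = TestParams(n_iterations=200, seed=42)


class TestBlockCounts:
    T0 = pd.Timestamp("2021-06-05T12:00")

    def test_no_prey_all_zero(self):
        assert list(block_counts(np.array([], dtype="datetime64[ns]"),
                                 self.T0, PARAMS)) == [0] * 6

    def test_offsets_land_in_their_blocks(self):
        prey = pd.to_datetime([
            "2021-06-02T13:00",  # -71 h -> block [-72,-48)
            "2021-06-04T06:00",  # -30 h -> block [-48,-24)
            "2021-06-05T18:00",  # +6 h  -> block (0,24]
            "2021-06-06T18:00",  # +30 h -> block (24,48]
        ]).to_numpy()
        assert list(block_counts(prey, self.T0, PARAMS)) == [1, 1, 0, 1, 1, 0]

    def test_zero_offset_belongs_to_no_block(self):
        prey = pd.to_datetime([self.T0]).to_numpy()
        assert list(block_counts(prey, self.T0, PARAMS)) == [0] * 6

    def test_block_closure_at_24h_boundaries(self):
        prey = pd.to_datetime(["2021-06-04T12:00",   # exactly -24 h -> [-24,0)? no: [-48,-24)... closed-left
                               "2021-06-06T12:00"])  # exactly +24 h -> (0,24]
        counts = list(block_counts(prey.to_numpy(), self.T0, PARAMS))
        # -24 h sits at the closed left edge of [-24,0); +24 h at the closed
        # right edge of (0,24].
        assert counts == [0, 0, 1, 1, 0, 0]

    def test_beyond_72h_ignored(self):
        prey = pd.to_datetime(["2021-06-01T12:00", "2021-06-09T12:00"]).to_numpy()
        assert list(block_counts(prey, self.T0, PARAMS)) == [0] * 6

    def test_labels_chronological(self):
        assert block_labels(PARAMS) == [
            "[-72,-48)", "[-48,-24)", "[-24,0)", "(0,24]", "(24,48]", "(48,72]"]


class TestEligibleDates:
    def test_90_day_roll(self):
        start, end = pd.Timestamp("2021-01-01"), pd.Timestamp("2021-04-01")
        dates = eligible_dates(start, end, pd.Timedelta(hours=14), PARAMS)
        assert len(dates) == 84
        cand = dates + pd.Timedelta(hours=14)
        assert (cand >= start + pd.Timedelta(hours=72)).all()
        assert (cand <= end - pd.Timedelta(hours=72)).all()

    def test_30_day_roll(self):
        start = pd.Timestamp("2021-01-01")
        dates = eligible_dates(start, start + pd.Timedelta(days=30),
                               pd.Timedelta(hours=9, minutes=30), PARAMS)
        assert len(dates) == 24

    def test_oversized_margin_empty(self):
        start = pd.Timestamp("2021-01-01")
        assert len(eligible_dates(start, start + pd.Timedelta(days=5),
                                  pd.Timedelta(hours=12), PARAMS)) == 0


class TestRandomizeOnce:
    START, END = pd.Timestamp("2021-01-01"), pd.Timestamp("2021-04-01")

    def test_forced_single_date(self, rng):
        start = pd.Timestamp("2021-01-01T00:00")
        end = start + pd.Timedelta(days=6, hours=2)  # window [Jan 4 00:00, 02:00]
        dates = eligible_dates(start, end, pd.Timedelta(hours=1), PARAMS)
        assert len(dates) == 1  # the draw is forced
        times = pd.to_datetime(["2021-01-04T01:00"])
        new = randomize_once(times, start, end, PARAMS, rng)
        assert list(new) == [pd.Timestamp("2021-01-04T01:00")]

    def test_times_of_day_preserved(self, rng):
        times = pd.to_datetime(["2021-01-10T06:15", "2021-02-01T23:50",
                                "2021-03-05T13:05", "2021-03-05T13:05"])
        new = randomize_once(times, self.START, self.END, PARAMS, rng)
        tod = lambda idx: sorted(t - t.normalize() for t in idx)
        assert tod(new) == tod(pd.DatetimeIndex(times))
        assert len(new) == len(times)

    def test_collisions_allowed(self, rng):
        start = pd.Timestamp("2021-01-01")
        end = start + pd.Timedelta(days=8)  # two eligible dates
        times = pd.to_datetime(["2021-01-04T12:00"] * 2)
        seen_same = False
        for _ in range(40):
            new = randomize_once(times, start, end, PARAMS, rng)
            if new[0].normalize() == new[1].normalize():
                seen_same = True
                break
        assert seen_same

    def test_empty_eligible_set_raises(self, rng):
        start = pd.Timestamp("2021-01-01")
        with pytest.raises(ValueError, match="no eligible dates"):
            randomize_once(pd.to_datetime(["2021-01-02T12:00"]), start,
                           start + pd.Timedelta(days=4), PARAMS, rng)


class TestPValues:
    NULL = np.array([[0, 0], [1, 5], [2, 2], [2, 3], [3, 4],
                     [4, 5], [5, 6], [5, 7], [6, 1], [7, 5]])

    def test_after_block_counts_lower_tail_with_ties(self):
        null = self.NULL[:, [0]].repeat(2, axis=1)
        p = p_values(np.array([2, 2]), null, 1)
        assert p[1] == pytest.approx(0.4)  # {0,1,2,2} of 10

    def test_before_block_counts_upper_tail_with_ties(self):
        null = self.NULL[:, [0]].repeat(2, axis=1)
        p = p_values(np.array([5, 5]), null, 1)
        assert p[0] == pytest.approx(0.4)  # {5,5,6,7} of 10

    def test_all_ties_give_p_one(self):
        null = np.full((50, 6), 3)
        p = p_values(np.full(6, 3), null, 3)
        assert (p == 1.0).all()

    def test_tie_identity_per_block(self, rng):
        null = rng.poisson(4.0, size=(500, 6))
        obs = rng.poisson(4.0, size=6)
        n_le = (null <= obs).sum(axis=0)
        n_ge = (null >= obs).sum(axis=0)
        n_eq = (null == obs).sum(axis=0)
        assert (n_le + n_ge == 500 + n_eq).all()

    def test_zero_iterations_error(self):
        with pytest.raises(ValueError, match="zero iterations"):
            p_values(np.zeros(6), np.zeros((0, 6)), 3)


class TestNullDistribution:
    def test_no_cooccurrence_is_no_data(self):
        rolls = pd.concat([
            make_rolls(("C1", "2021-01-01T00:00", "2021-04-01T00:00")),
            make_rolls(("C2", "2021-01-01T00:00", "2021-04-01T00:00")),
        ], ignore_index=True)
        det = make_detections([
            ("C1", "prey", "2021-02-01T10:00"),
            ("C2", "predator", "2021-02-01T22:00"),
        ])
        ds = SurveyDataset(det, rolls, {"prey": "prey", "predator": "predator"})
        obs, null, info = null_distribution(ds, "prey", "predator", PARAMS)
        assert obs is None and null is None
        assert info["n_rolls_used"] == 0

    def test_observed_independent_of_seed(self, toy_dataset):
        obs1, _, _ = null_distribution(toy_dataset, "prey", "predator",
                                       PARAMS.with_(seed=1))
        obs2, _, _ = null_distribution(toy_dataset, "prey", "predator",
                                       PARAMS.with_(seed=999))
        assert np.array_equal(obs1, obs2)

    def test_monte_carlo_matches_enumeration(self):
        """Single event, 10 eligible dates: the Monte-Carlo null must match
        the exact 10-outcome distribution within binomial error."""
        from camtrap_avoidance.studies import _single_event_dataset
        ds, params = _single_event_dataset(0)
        params = params.with_(seed=5)
        obs, outcomes = enumerate_null(ds, "prey", "predator", params)
        _, null, _ = null_distribution(ds, "prey", "predator", params)
        # Total-variation distance between the empirical row distribution and
        # the uniform-over-outcomes exact one.
        rows_exact, counts_exact = np.unique(outcomes, axis=0, return_counts=True)
        tv = 0.0
        for row, c in zip(rows_exact, counts_exact):
            emp = (null.counts == row).all(axis=1).mean()
            tv += abs(emp - c / len(outcomes))
        emp_mass = sum((null.counts == row).all(axis=1).mean() for row in rows_exact)
        tv += 1.0 - emp_mass  # mass on rows outside the exact support (none expected)
        assert tv / 2 < 0.05

    def test_no_predators_is_no_data(self, toy_dataset):
        det = toy_dataset.detections
        ds = toy_dataset.with_detections(det[det["species"] == "prey"])
        result = run_site_test(ds, "prey", "predator", PARAMS, preprocessed=True)
        assert not result.has_data
        assert result.p is None and result.significant is None


class TestConservation:
    def test_randomization_preserves_counts_and_times_of_day(self, rng):
        start, end = pd.Timestamp("2021-01-01"), pd.Timestamp("2021-04-01")
        times = pd.to_datetime(["2021-01-10T06:15", "2021-02-01T23:50",
                                "2021-03-05T13:05"])
        tod_before = sorted(t - t.normalize() for t in times)
        for _ in range(50):
            new = randomize_once(times, start, end, PARAMS, rng)
            assert len(new) == 3
            assert sorted(t - t.normalize() for t in new) == tod_before
            assert ((new >= start) & (new <= end)).all()
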