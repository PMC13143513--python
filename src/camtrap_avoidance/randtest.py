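"""Reactive-avoidance randomization test.

The statistic is the total number of prey detections in consecutive 24-h
blocks spanning 72 h before and after each (filtered) predator detection,
summed over predator events, camera-local.  The null distribution is built
by relocating every predator event to a uniformly drawn calendar date within
its roll — keeping the event's clock time, so diel activity structure is
preserved — and recounting.  Empirical one-sided p-values count ties as
extreme: after-blocks test for *depressed* prey counts (avoidance),
before-blocks for *elevated* counts (the baseline / predator-following
check).

Block conventions: before-blocks are closed-left/open-right ending at the
event time t0, after-blocks open-left/closed-right starting at t0; a prey
detection exactly at t0 belongs to no block.  Randomized dates are confined
to ``[roll.start + margin, roll.end - margin]``, the same interval observed
events were restricted to, so observed and null counts face identical
exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurveyDataset
from .preprocess import TestParams, preprocess_survey

__all__ = [
    "NullDistribution",
    "TestResult",
    "block_counts",
    "block_labels",
    "eligible_dates",
    "randomize_once",
    "null_distribution",
    "enumerate_null",
    "p_values",
    "run_site_test",
]

logger = logging.getLogger(__name__)

_NS_PER_HOUR = 3.6e12
_DAY = pd.Timedelta(days=1)


def _to_hours(times) -> np.ndarray:
    """datetime64 -> float hours since the Unix epoch."""
    return np.asarray(times, dtype="datetime64[ns]").astype("int64") / _NS_PER_HOUR


def block_labels(params: TestParams) -> list:
    """Chronological labels, e.g. ``[-72,-48) ... (48,72]`` in hours."""
    w, n = params.block_width_h, params.n_blocks_per_side
    fmt = lambda x: f"{x:g}"
    before = [f"[{fmt(-(n - i) * w)},{fmt(-(n - i - 1) * w)})" for i in range(n)]
    after = [f"({fmt(i * w)},{fmt((i + 1) * w)}]" for i in range(n)]
    return before + after


def _count_matrix(prey_sorted_h: np.ndarray, t0s_h: np.ndarray,
                  width_h: float, n_side: int) -> np.ndarray:
    """Block counts for each candidate reference time.

    Returns an ``(len(t0s), 2 * n_side)`` integer matrix; columns are
    chronological.  ``prey_sorted_h`` must be sorted ascending.
    """
    t0s_h = np.atleast_1d(np.asarray(t0s_h, dtype=float))
    k = np.arange(n_side + 1, dtype=float)
    # Before-block edges t0-72, t0-48, t0-24, t0 (closed-left, open-right);
    # after-block edges t0, t0+24, t0+48, t0+72 (open-left, closed-right).
    before_edges = t0s_h[:, None] - width_h * (n_side - k)[None, :]
    after_edges = t0s_h[:, None] + width_h * k[None, :]
    cb = np.searchsorted(prey_sorted_h, before_edges, side="left")
    ca = np.searchsorted(prey_sorted_h, after_edges, side="right")
    return np.concatenate([np.diff(cb, axis=1), np.diff(ca, axis=1)], axis=1)


def block_counts(prey_times, t0, params: TestParams) -> np.ndarray:
    """Prey counts around one reference time, chronological order."""
    prey_h = np.sort(_to_hours(prey_times))
    t0_h = _to_hours([pd.Timestamp(t0).to_datetime64()])
    return _count_matrix(prey_h, t0_h, params.block_width_h,
                         params.n_blocks_per_side)[0]


def eligible_dates(roll_start, roll_end, time_of_day: pd.Timedelta,
                   params: TestParams) -> pd.DatetimeIndex:
    """Calendar dates d such that d + time_of_day lies inside the roll's
    margin-trimmed interval ``[start + margin, end - margin]``."""
    lo = pd.Timestamp(roll_start) + pd.Timedelta(hours=params.edge_margin_h)
    hi = pd.Timestamp(roll_end) - pd.Timedelta(hours=params.edge_margin_h)
    if lo > hi:
        return pd.DatetimeIndex([])
    days = pd.date_range(lo.normalize(), hi.normalize(), freq="D")
    cand = days + time_of_day
    return days[(cand >= lo) & (cand <= hi)]


def randomize_once(times, roll_start, roll_end, params: TestParams,
                   rng: np.random.Generator) -> pd.DatetimeIndex:
    """Reassign each event a uniform eligible date, keeping its clock time.

    Events are relocated independently with replacement: two events may land
    on the same date.  Raises ``ValueError`` if any event has no eligible
    date (roll too short for the margin).
    """
    times = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[ns]"))
    new = []
    for t in times:
        tod = t - t.normalize()
        dates = eligible_dates(roll_start, roll_end, tod, params)
        if len(dates) == 0:
            raise ValueError(
                f"no eligible dates for event at {t} in roll "
                f"[{roll_start} .. {roll_end}] with margin {params.edge_margin_h} h"
            )
        new.append(dates[rng.integers(0, len(dates))] + tod)
    return pd.DatetimeIndex(new)


@dataclass
class NullDistribution:
    """Randomization-null block counts: one row per iteration."""

    counts: np.ndarray  # (n_iterations, 2 * n_blocks_per_side) ints
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.counts.shape[0]


@dataclass
class TestResult:
    """Outcome of one site x prey x predator randomization test.

    ``p`` is ``None`` when no roll had both species ("no data"); otherwise
    one empirical one-sided p-value per block, chronological order.
    """

    __test__ = False  # not a pytest class despite the name

    site_id: str
    prey_species: str
    predator_species: str
    observed: np.ndarray | None
    p: np.ndarray | None
    n_predator_events: int
    n_rolls_used: int
    n_iterations: int
    seed: int
    alpha: float
    labels: list

    @property
    def has_data(self) -> bool:
        return self.p is not None

    @property
    def significant(self) -> np.ndarray | None:
        return None if self.p is None else self.p < self.alpha


class _EventTable:
    """Per-event eligible-date count matrices for one prey/predator pair."""

    def __init__(self, dataset: SurveyDataset, prey: str, predator: str,
                 params: TestParams):
        det = dataset.detections
        prey_det = det[det["species"] == prey]
        pred_det = det[det["species"] == predator]

        prey_rolls = set(prey_det["roll_id"])
        pred_rolls = set(pred_det["roll_id"])
        self.rolls_used = sorted(prey_rolls & pred_rolls)
        roll_info = dataset.rolls.set_index("roll_id")

        self.prey_by_cam = {
            cam: np.sort(_to_hours(g["timestamp"].to_numpy()))
            for cam, g in prey_det.groupby("camera_id")
        }

        self.matrices: list[np.ndarray] = []  # (n_dates_e, 2n) per event
        self.observed = np.zeros(2 * params.n_blocks_per_side, dtype="int64")
        self.n_events = 0
        dropped_rolls = []
        for roll_id in self.rolls_used:
            info = roll_info.loc[roll_id]
            events = pred_det.loc[pred_det["roll_id"] == roll_id, "timestamp"]
            prey_h = self.prey_by_cam.get(info["camera_id"], np.empty(0))
            mats, obs_rows = [], []
            ok = True
            for t in pd.DatetimeIndex(events):
                tod = t - t.normalize()
                dates = eligible_dates(info["start"], info["end"], tod, params)
                if len(dates) == 0:
                    ok = False
                    break
                t0s = _to_hours((dates + tod).to_numpy())
                mats.append(_count_matrix(prey_h, t0s, params.block_width_h,
                                          params.n_blocks_per_side))
                obs_rows.append(_count_matrix(prey_h, _to_hours([t.to_datetime64()]),
                                              params.block_width_h,
                                              params.n_blocks_per_side)[0])
            if not ok:
                dropped_rolls.append(roll_id)
                continue
            self.matrices.extend(mats)
            for row in obs_rows:
                self.observed += row
            self.n_events += len(mats)
        if dropped_rolls:
            logger.warning(
                "excluded %d roll(s) whose events had no eligible dates: %s",
                len(dropped_rolls), dropped_rolls,
            )
            self.rolls_used = [r for r in self.rolls_used if r not in set(dropped_rolls)]


def null_distribution(dataset: SurveyDataset, prey: str, predator: str,
                      params: TestParams, rng: np.random.Generator | None = None):
    """Observed block counts and the Monte-Carlo null.

    Expects predator detections already filtered (see
    :func:`~camtrap_avoidance.preprocess.preprocess_survey`).  Only rolls with
    at least one prey and one predator detection enter the test.  Returns
    ``(observed, NullDistribution, info)`` or ``(None, None, info)`` when no
    roll qualifies.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    table = _EventTable(dataset, prey, predator, params)
    info = {"n_predator_events": table.n_events, "n_rolls_used": len(table.rolls_used)}
    if table.n_events == 0:
        return None, None, info

    n_blocks = 2 * params.n_blocks_per_side
    counts = np.zeros((params.n_iterations, n_blocks), dtype="int64")
    for mat in table.matrices:
        idx = rng.integers(0, mat.shape[0], size=params.n_iterations)
        counts += mat[idx]
    return table.observed, NullDistribution(counts, params.seed), info


def enumerate_null(dataset: SurveyDataset, prey: str, predator: str,
                   params: TestParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact null for the single-event case by exhausting eligible dates.

    Returns ``(observed, all_outcomes)`` where ``all_outcomes`` has one row
    per eligible date, each equally likely under the null.  Only valid when
    exactly one predator event remains; raises otherwise.
    """
    table = _EventTable(dataset, prey, predator, params)
    if table.n_events != 1:
        raise ValueError(f"exact enumeration needs exactly 1 event, got {table.n_events}")
    return table.observed, table.matrices[0]


def p_values(observed: np.ndarray, null_counts: np.ndarray,
             n_blocks_per_side: int) -> np.ndarray:
    """Empirical one-sided p per block, ties inclusive.

    Before-blocks (first half): proportion of iterations with count >=
    observed (elevated prey presence is the alternative).  After-blocks:
    proportion with count <= observed (depressed presence).
    """
    null_counts = np.asarray(null_counts)
    if null_counts.shape[0] == 0:
        raise ValueError("null distribution has zero iterations")
    observed = np.asarray(observed)
    n = n_blocks_per_side
    p = np.empty(2 * n, dtype=float)
    p[:n] = (null_counts[:, :n] >= observed[:n]).mean(axis=0)
    p[n:] = (null_counts[:, n:] <= observed[n:]).mean(axis=0)
    return p


def run_site_test(dataset: SurveyDataset, prey: str, predator: str,
                  params: TestParams, preprocessed: bool = False,
                  rng: np.random.Generator | None = None,
                  keep_null: bool = False):
    """Filter, randomize, and test one prey/predator pair on one site.

    Returns a :class:`TestResult`, or ``(TestResult, NullDistribution)``
    when ``keep_null`` is set (for histogram export).
    """
    sites = dataset.rolls["site_id"].unique()
    site_id = sites[0] if len(sites) == 1 else "/".join(map(str, sites))
    if not preprocessed:
        dataset, _ = preprocess_survey(dataset, params)
    observed, null, info = null_distribution(dataset, prey, predator, params, rng)
    if observed is None:
        result = TestResult(site_id, prey, predator, None, None,
                            info["n_predator_events"], info["n_rolls_used"],
                            params.n_iterations, params.seed, params.alpha,
                            block_labels(params))
    else:
        p = p_values(observed, null.counts, params.n_blocks_per_side)
        result = TestResult(site_id, prey, predator, observed, p,
                            info["n_predator_events"], info["n_rolls_used"],
                            params.n_iterations, params.seed, params.alpha,
                            block_labels(params))
    return (result, null) if keep_null else result
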