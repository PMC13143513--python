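"""Detection filtering applied before the randomization test.

Four curation rules:

* **time-to-independence**: chains of same-species, same-camera detections
  separated by less than a gap (default 30 min) collapse to their central
  element, so a burst of triggers by one passage counts once and the
  retained time is symmetric for before/after comparisons;
* **edge exclusion**: predator events within a margin (default 72 h) of a
  roll's start or end are discarded so full before/after count windows are
  observable;
* **lifespan filter**: rolls shorter than a minimum (default 30 days) are
  dropped entirely — their randomization window would be too narrow;
* **co-detection rate**: the fraction of camera-days with one predator that
  also saw a second predator species, a diagnostic for predator-following
  confounds.

Only predator detections are independence-filtered and edge-excluded; prey
detections are touched only by roll removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import SurveyDataset

__all__ = [
    "TestParams",
    "cluster_events",
    "independence_filter",
    "edge_exclusion",
    "lifespan_filter",
    "co_detection_rate",
    "preprocess_survey",
]


@dataclass(frozen=True)
class TestParams:
    """Tunable parameters of the filtering and randomization procedure.

    Durations carry their unit in the name.  ``edge_margin_h`` should equal
    ``n_blocks_per_side * block_width_h`` so that every retained event has
    fully observable count windows; a mismatch is allowed but warned about.
    """

    __test__ = False  # not a pytest class despite the name

    independence_gap_min: float = 30.0
    edge_margin_h: float = 72.0
    block_width_h: float = 24.0
    n_blocks_per_side: int = 3
    n_iterations: int = 1000
    alpha: float = 0.05
    min_lifespan_days: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("independence_gap_min", "edge_margin_h", "block_width_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_blocks_per_side < 1 or self.n_iterations < 0:
            raise ValueError("n_blocks_per_side must be >= 1, n_iterations >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_blocks_per_side * self.block_width_h != self.edge_margin_h:
            warnings.warn(
                "edge_margin_h != n_blocks_per_side * block_width_h: "
                "outer blocks extend past the guaranteed-observable window",
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "TestParams":
        return replace(self, **kwargs)


def _check_sorted(times: np.ndarray) -> None:
    if len(times) > 1 and (np.diff(times.astype("datetime64[ns]").astype("int64")) < 0).any():
        raise ValueError("events must be sorted ascending by timestamp")


def cluster_events(times, gap_min: float = 30.0) -> list:
    """Partition sorted event times into maximal chains whose consecutive
    gaps are strictly below ``gap_min`` minutes.

    Chaining is transitive: [10:00, 10:29, 10:58] is one cluster even though
    its span exceeds the gap.  Returns a list of index arrays into ``times``.
    """
    times = np.asarray(times, dtype="datetime64[ns]")
    _check_sorted(times)
    if len(times) == 0:
        return []
    gaps_min = np.diff(times.astype("int64")) / 60e9
    breaks = np.flatnonzero(gaps_min >= gap_min) + 1
    return np.split(np.arange(len(times)), breaks)


def independence_filter(times, gap_min: float = 30.0) -> np.ndarray:
    """Indices of the central element of each cluster (1-based position
    ``ceil(k/2)`` — the earlier middle element when k is even)."""
    clusters = cluster_events(times, gap_min)
    return np.array([c[(len(c) - 1) // 2] for c in clusters], dtype="int64")


def edge_exclusion(times, roll_start, roll_end, margin_h: float = 72.0) -> np.ndarray:
    """Boolean mask keeping events in the closed interval
    ``[start + margin, end - margin]``."""
    times = np.asarray(times, dtype="datetime64[ns]")
    start = pd.Timestamp(roll_start) + pd.Timedelta(hours=margin_h)
    end = pd.Timestamp(roll_end) - pd.Timedelta(hours=margin_h)
    if start > end:
        warnings.warn(
            f"edge margin {margin_h} h covers the whole roll "
            f"({roll_start} .. {roll_end}); all events excluded",
            stacklevel=2,
        )
        return np.zeros(len(times), dtype=bool)
    return (times >= start.to_datetime64()) & (times <= end.to_datetime64())


def lifespan_filter(rolls: pd.DataFrame, min_days: float = 30.0) -> pd.DataFrame:
    """Rolls whose lifespan (end - start) is at least ``min_days`` days;
    strictly shorter rolls are dropped."""
    days = (rolls["end"] - rolls["start"]).dt.total_seconds() / 86400.0
    return rolls[days >= min_days].reset_index(drop=True)


def co_detection_rate(predator_detections: pd.DataFrame,
                      predator_species=None) -> float | None:
    """Percentage of camera-days with any predator detection that saw at
    least two distinct predator species.

    A "day" is a calendar day at one camera.  Returns ``None`` when there are
    no predator detections (the rate is undefined).
    """
    det = predator_detections
    if predator_species is not None:
        det = det[det["species"].isin(set(predator_species))]
    if len(det) == 0:
        return None
    days = det.assign(day=det["timestamp"].dt.normalize())
    n_species = days.groupby(["camera_id", "day"])["species"].nunique()
    return float((n_species >= 2).mean() * 100.0)


def _filter_predators(det: pd.DataFrame, rolls: pd.DataFrame,
                      params: TestParams) -> pd.DataFrame:
    """Independence filter then edge exclusion, per roll and species."""
    bounds = rolls.set_index("roll_id")[["start", "end"]]
    kept = []
    for (roll_id, _species), grp in det.groupby(["roll_id", "species"], sort=False):
        grp = grp.sort_values("timestamp", kind="mergesort")
        times = grp["timestamp"].to_numpy()
        reps = independence_filter(times, params.independence_gap_min)
        grp = grp.iloc[reps]
        start, end = bounds.loc[roll_id]
        mask = edge_exclusion(grp["timestamp"].to_numpy(), start, end, params.edge_margin_h)
        kept.append(grp[mask])
    if not kept:
        return det.iloc[0:0]
    return pd.concat(kept).sort_values(
        ["camera_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def preprocess_survey(dataset: SurveyDataset, params: TestParams):
    """Apply the full filter stack; returns ``(filtered_dataset, report)``.

    ``report`` maps each stage to before/after detection counts per species,
    suitable for a filter report.  Predator species are taken from
    ``dataset.species_roles``.
    """
    report = {}
    rolls0 = dataset.rolls
    rolls = lifespan_filter(rolls0, params.min_lifespan_days)
    report["lifespan_filter"] = {
        "rolls_before": len(rolls0),
        "rolls_after": len(rolls),
    }

    det = dataset.detections
    on_kept = det["roll_id"].isin(set(rolls["roll_id"]))
    report["roll_removal"] = {
        "detections_before": len(det),
        "detections_after": int(on_kept.sum()),
        "by_species_removed": det.loc[~on_kept, "species"].value_counts().to_dict(),
    }
    det = det[on_kept].reset_index(drop=True)

    predators = set(dataset.species_with_role("predator"))
    is_pred = det["species"].isin(predators)
    pred_before = det[is_pred]
    with warnings.catch_warnings():
        # Sub-margin rolls were already dropped by the lifespan filter when
        # min_lifespan_days >= 2 * margin / 24; stray warnings are not useful here.
        warnings.simplefilter("ignore")
        pred_after = _filter_predators(pred_before, rolls, params)
    report["predator_filters"] = {
        "before": pred_before["species"].value_counts().to_dict(),
        "after": pred_after["species"].value_counts().to_dict(),
    }

    rate = co_detection_rate(pred_after)
    report["predator_co_detection_pct"] = rate if rate is not None else "not applicable"

    out = pd.concat([det[~is_pred], pred_after], ignore_index=True).sort_values(
        ["camera_id", "timestamp", "species"], kind="mergesort").reset_index(drop=True)
    filtered = SurveyDataset(out, rolls, dataset.species_roles, dataset.excluded_cameras)
    return filtered, report
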