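"""Synthetic camera-trap surveys with known injected interaction effects.

Each species is an inhomogeneous Poisson process per camera whose intensity
is piecewise-constant over hours of the day (the diel profile) and integrates
to the nominal daily rate.  Reactive avoidance is injected by thinning: for
``avoidance_duration_h`` hours after each predator trigger at a camera, prey
intensity is multiplied by ``1 - avoidance_effect``.  Suppression windows of
overlapping predator events union rather than compound, so the effect size
stays interpretable as the per-window rate reduction.  A predator-following
artifact (elevated predator rate after prey passage) can be injected the same
way via ``attraction_effect``.  Burst triggering — the near-simultaneous
repeat triggers real cameras produce — is emulated by spawning extra triggers
inside the time-to-independence gap, so the cluster filter has something real
to do.

All randomness flows from ``Scenario.seed`` through named
``numpy.random.SeedSequence`` substreams, so identical scenarios give
bit-identical surveys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SurveyDataset

__all__ = ["Scenario", "simulate_rolls", "simulate_species", "simulate_interacting"]

#: Diurnal profile (prey): activity concentrated 06:00-19:00 with morning and
#: late-afternoon peaks, the classic pattern for a day-active primate/grazer.
DIURNAL_DIEL = (
    0.0, 0.0, 0.0, 0.0, 0.0, 0.2,
    1.0, 2.5, 3.0, 2.5, 1.8, 1.2,
    1.0, 1.0, 1.2, 1.8, 2.5, 3.0,
    2.0, 0.5, 0.0, 0.0, 0.0, 0.0,
)

#: Nocturnal-crepuscular profile (predator): active dusk to dawn.
NOCTURNAL_DIEL = (
    2.5, 2.5, 2.0, 2.0, 2.0, 1.5,
    1.0, 0.4, 0.1, 0.0, 0.0, 0.0,
    0.0, 0.0, 0.0, 0.0, 0.1, 0.5,
    1.0, 1.5, 2.0, 2.5, 3.0, 3.0,
)

_SURVEY_START = np.datetime64("2021-01-01T00:00")
_MINUTE = np.timedelta64(1, "m")


@dataclass(frozen=True)
class Scenario:
    """Parameter set for one synthetic survey.

    Rates are expected detections per camera-day at baseline; diel vectors
    are 24 non-negative relative weights (hour of day); ``avoidance_effect``
    is the fraction by which prey intensity drops for ``avoidance_duration_h``
    hours after a predator trigger at the same camera, and
    ``attraction_effect`` the analogous fractional *increase* in predator
    intensity after a prey trigger.  ``burst_prob`` is the probability a
    detection spawns extra triggers within ±``burst_gap_min``/2 minutes.
    """

    n_cameras: int = 20
    roll_days: float = 90.0
    prey_rate: float = 1.0
    predator_rate: float = 0.3
    prey_diel: tuple = DIURNAL_DIEL
    predator_diel: tuple = NOCTURNAL_DIEL
    avoidance_effect: float = 0.0
    avoidance_duration_h: float = 24.0
    attraction_effect: float = 0.0
    attraction_duration_h: float = 24.0
    burst_prob: float = 0.1
    burst_gap_min: float = 30.0
    seed: int = 0
    site_id: str = "SYN"
    prey_species: str = "prey"
    predator_species: str = "predator"

    def __post_init__(self) -> None:
        if self.n_cameras < 0:
            raise ValueError("n_cameras must be non-negative")
        if self.roll_days <= 0:
            raise ValueError("roll_days must be positive")
        for name in ("prey_rate", "predator_rate", "attraction_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.avoidance_effect <= 1.0:
            raise ValueError("avoidance_effect must lie in [0, 1]")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must lie in [0, 1]")
        for name in ("prey_diel", "predator_diel"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (24,) or (w < 0).any() or not (w > 0).any():
                raise ValueError(
                    f"{name} must be 24 non-negative weights with at least one positive"
                )

    def with_(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


def simulate_rolls(scenario: Scenario) -> pd.DataFrame:
    """One roll per camera, all starting together and running ``roll_days``."""
    start = _SURVEY_START
    end = start + np.timedelta64(round(scenario.roll_days * 24 * 60), "m")
    rows = [
        {
            "roll_id": f"CAM{i + 1:03d}-R1",
            "camera_id": f"CAM{i + 1:03d}",
            "site_id": scenario.site_id,
            "start": pd.Timestamp(start),
            "end": pd.Timestamp(end),
        }
        for i in range(scenario.n_cameras)
    ]
    return pd.DataFrame(rows, columns=["roll_id", "camera_id", "site_id", "start", "end"])


def _diel_hourly_rate(rate_per_day: float, diel) -> np.ndarray:
    """Events/hour for each hour of day; integrates to rate_per_day over 24 h."""
    w = np.asarray(diel, dtype=float)
    if not (w > 0).any():
        raise ValueError("diel weight vector must have a positive entry")
    return rate_per_day * w / w.sum()


def _sample_inhomogeneous(start: pd.Timestamp, end: pd.Timestamp,
                          hourly_rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Times (datetime64[m]) of an inhomogeneous Poisson process on [start, end)
    with the given piecewise-constant hour-of-day intensity, by inverting the
    cumulative intensity."""
    t0 = start.to_datetime64().astype("datetime64[m]").astype("int64") / 60.0  # hours
    t1 = end.to_datetime64().astype("datetime64[m]").astype("int64") / 60.0
    edges = np.concatenate([[t0], np.arange(math.floor(t0) + 1, math.ceil(t1)), [t1]])
    edges = edges[(edges >= t0) & (edges <= t1)]
    hod = (np.floor(edges[:-1]).astype("int64")) % 24
    seg_rate = hourly_rate[hod]
    seg_mass = seg_rate * np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(seg_mass)])
    total = cum[-1]
    n = rng.poisson(total)
    if n == 0:
        return np.empty(0, dtype="datetime64[m]")
    u = rng.uniform(0.0, total, size=n)
    seg = np.searchsorted(cum, u, side="right") - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (u - cum[seg]) / seg_mass[seg]
    times_h = edges[seg] + frac * np.diff(edges)[seg]
    times_h.sort()
    return np.floor(times_h * 60.0).astype("int64").astype("datetime64[m]")


def simulate_species(rolls: pd.DataFrame, rate: float, diel, rng: np.random.Generator,
                     species: str = "sp", site_id: str | None = None) -> pd.DataFrame:
    """Detections of one species across all rolls (independent per roll).

    Times are floored to minute resolution, the survey's declared clock.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    hourly = _diel_hourly_rate(rate, diel)
    frames = []
    for roll in rolls.itertuples(index=False):
        times = _sample_inhomogeneous(roll.start, roll.end, hourly, rng)
        if len(times) == 0:
            continue
        frames.append(pd.DataFrame({
            "site_id": site_id if site_id is not None else roll.site_id,
            "camera_id": roll.camera_id,
            "roll_id": roll.roll_id,
            "species": species,
            "timestamp": pd.to_datetime(times).astype("datetime64[ns]"),
        }))
    cols = ["site_id", "camera_id", "roll_id", "species", "timestamp"]
    if not frames:
        return pd.DataFrame(columns=cols).astype({"timestamp": "datetime64[ns]"})
    return pd.concat(frames, ignore_index=True)[cols]


def _in_windows(query_h: np.ndarray, anchors_h: np.ndarray, duration_h: float) -> np.ndarray:
    """True where a query time falls in (a, a + duration] for some anchor a."""
    if len(anchors_h) == 0:
        return np.zeros(len(query_h), dtype=bool)
    anchors = np.sort(anchors_h)
    idx = np.searchsorted(anchors, query_h, side="left")  # anchors[idx-1] < q
    has_prev = idx > 0
    prev = anchors[np.maximum(idx - 1, 0)]
    return has_prev & (query_h - prev <= duration_h)


def _hours(ts: pd.Series) -> np.ndarray:
    """Float hours since epoch, robust to non-nanosecond datetime units."""
    return np.asarray(ts.to_numpy(), dtype="datetime64[ns]").astype("int64") / 3.6e12


def _thin_by_windows(det: pd.DataFrame, anchors: pd.DataFrame, duration_h: float,
                     drop_prob: float, rng: np.random.Generator) -> pd.DataFrame:
    """Drop each detection inside a same-camera anchor window with ``drop_prob``."""
    keep = np.ones(len(det), dtype=bool)
    anchor_by_cam = {c: _hours(g["timestamp"]) for c, g in anchors.groupby("camera_id")}
    for cam, grp in det.groupby("camera_id"):
        in_win = _in_windows(_hours(grp["timestamp"]),
                             anchor_by_cam.get(cam, np.empty(0)), duration_h)
        u = rng.uniform(size=len(grp))
        keep[det.index.get_indexer(grp.index)] = ~in_win | (u >= drop_prob)
    return det[keep].reset_index(drop=True)


def _add_bursts(det: pd.DataFrame, rolls: pd.DataFrame, burst_prob: float,
                gap_min: float, rng: np.random.Generator) -> pd.DataFrame:
    """Spawn 1-2 extra triggers within ±gap/2 of a random subset of parents."""
    if burst_prob == 0.0 or len(det) == 0:
        return det
    parents = det[rng.uniform(size=len(det)) < burst_prob]
    if len(parents) == 0:
        return det
    bounds = rolls.set_index("roll_id")[["start", "end"]]
    extras = []
    for row in parents.itertuples(index=False):
        n_extra = int(rng.integers(1, 3))
        offsets = rng.uniform(-gap_min / 2.0, gap_min / 2.0, size=n_extra)
        lo, hi = bounds.loc[row.roll_id]
        for off in offsets:
            t = row.timestamp + pd.Timedelta(minutes=float(off))
            t = min(max(t, lo), hi).floor("min")
            extras.append({
                "site_id": row.site_id, "camera_id": row.camera_id,
                "roll_id": row.roll_id, "species": row.species, "timestamp": t,
            })
    return pd.concat([det, pd.DataFrame(extras)], ignore_index=True)


def simulate_interacting(scenario: Scenario) -> SurveyDataset:
    """Full survey: predator and prey processes with the configured coupling.

    Construction order (substreams spawned from ``seed`` in this order:
    prey base, predator base, predator thinning, burst insertion, prey
    thinning):

    1. baseline prey process per camera;
    2. predator process — simulated at its ceiling rate
       ``predator_rate * (1 + attraction_effect)`` and thinned down to the
       baseline rate *outside* post-prey attraction windows, so predator
       intensity is elevated by ``1 + attraction_effect`` for
       ``attraction_duration_h`` after each baseline prey trigger;
    3. burst triggers for both species;
    4. prey thinning: every prey trigger (bursts included) inside a
       post-predator window of length ``avoidance_duration_h`` is dropped
       with probability ``avoidance_effect``.

    With ``avoidance_effect == attraction_effect == 0`` and
    ``burst_prob == 0`` the result is exactly two independent
    :func:`simulate_species` runs composed into one dataset.
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    s_prey, s_pred, s_pred_thin, s_burst, s_prey_thin = ss.spawn(5)

    rolls = simulate_rolls(sc)
    prey0 = simulate_species(rolls, sc.prey_rate, sc.prey_diel,
                             np.random.default_rng(s_prey), sc.prey_species)

    ceiling = sc.predator_rate * (1.0 + sc.attraction_effect)
    pred0 = simulate_species(rolls, ceiling, sc.predator_diel,
                             np.random.default_rng(s_pred), sc.predator_species)
    # Thin the predator back to baseline where no prey passed recently.
    drop_outside = sc.attraction_effect / (1.0 + sc.attraction_effect)
    if drop_outside > 0:
        rng = np.random.default_rng(s_pred_thin)
        keep = np.ones(len(pred0), dtype=bool)
        prey_by_cam = {c: _hours(g["timestamp"]) for c, g in prey0.groupby("camera_id")}
        for cam, grp in pred0.groupby("camera_id"):
            in_win = _in_windows(_hours(grp["timestamp"]),
                                 prey_by_cam.get(cam, np.empty(0)),
                                 sc.attraction_duration_h)
            u = rng.uniform(size=len(grp))
            keep[pred0.index.get_indexer(grp.index)] = in_win | (u >= drop_outside)
        pred = pred0[keep].reset_index(drop=True)
    else:
        pred = pred0

    rng_burst = np.random.default_rng(s_burst)
    prey_all = _add_bursts(prey0, rolls, sc.burst_prob, sc.burst_gap_min, rng_burst)
    pred_all = _add_bursts(pred, rolls, sc.burst_prob, sc.burst_gap_min, rng_burst)

    if sc.avoidance_effect > 0:
        prey_final = _thin_by_windows(prey_all, pred_all, sc.avoidance_duration_h,
                                      sc.avoidance_effect,
                                      np.random.default_rng(s_prey_thin))
    else:
        prey_final = prey_all

    det = pd.concat([prey_final, pred_all], ignore_index=True)
    det = det.sort_values(["camera_id", "timestamp", "species"],
                          kind="mergesort").reset_index(drop=True)
    roles = {sc.prey_species: "prey", sc.predator_species: "predator"}
    return SurveyDataset(det, rolls, species_roles=roles)
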