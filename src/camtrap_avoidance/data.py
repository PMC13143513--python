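"""Survey data containers, validation, and CSV readers/writers.

The on-disk dialect is deliberately small: two comma-separated UTF-8 files
with mandatory headers and ISO 8601 local-naive timestamps at minute
resolution or finer.  A *detection* is one motion-triggered capture event of
one species at one camera (one row regardless of picture count or number of
individuals); a *roll* is the continuous operating interval of one camera
between two services, the unit within which dates are later randomized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_COLUMNS",
    "ROLL_COLUMNS",
    "SchemaError",
    "ValidationError",
    "SurveyDataset",
    "read_survey",
    "write_survey",
]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["site_id", "camera_id", "roll_id", "species", "timestamp"]
ROLL_COLUMNS = ["roll_id", "camera_id", "site_id", "start", "end"]

#: Species roles a survey distinguishes.
ROLES = ("prey", "predator", "other")


class SchemaError(ValueError):
    """A file does not match the documented column schema."""


class ValidationError(ValueError):
    """Rows violate a dataset invariant (e.g. detection outside its roll)."""


@dataclass
class SurveyDataset:
    """A validated camera-trap survey.

    Attributes
    ----------
    detections
        One row per capture event with columns ``site_id, camera_id,
        roll_id, species, timestamp`` (``timestamp`` is ``datetime64[ns]``,
        local naive time).
    rolls
        One row per roll with columns ``roll_id, camera_id, site_id, start,
        end``.
    species_roles
        Mapping species name -> one of ``{"prey", "predator", "other"}``.
    excluded_cameras
        Cameras removed at load time (e.g. waterhole cameras); kept for
        provenance only — no detection or roll of these cameras remains.
    """

    detections: pd.DataFrame
    rolls: pd.DataFrame
    species_roles: dict = field(default_factory=dict)
    excluded_cameras: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.detections = _normalize_detections(self.detections)
        self.rolls = _normalize_rolls(self.rolls)

    # -- convenience -----------------------------------------------------
    @property
    def n_detections(self) -> int:
        return len(self.detections)

    def species_with_role(self, role: str) -> list:
        return sorted(s for s, r in self.species_roles.items() if r == role)

    def for_species(self, species: str) -> pd.DataFrame:
        return self.detections[self.detections["species"] == species]

    def with_detections(self, detections: pd.DataFrame) -> "SurveyDataset":
        return replace(self, detections=_normalize_detections(detections))

    def validate(self) -> None:
        validate_survey(self)


def _normalize_detections(det: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in det.columns]
    if missing:
        raise SchemaError(f"detection table missing column(s): {', '.join(missing)}")
    det = det[DETECTION_COLUMNS].copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"]).astype("datetime64[ns]")
    return det.reset_index(drop=True)


def _normalize_rolls(rolls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROLL_COLUMNS if c not in rolls.columns]
    if missing:
        raise SchemaError(f"roll table missing column(s): {', '.join(missing)}")
    rolls = rolls[ROLL_COLUMNS].copy()
    for col in ("start", "end"):
        rolls[col] = pd.to_datetime(rolls[col]).astype("datetime64[ns]")
    return rolls.reset_index(drop=True)


def validate_survey(dataset: SurveyDataset) -> None:
    """Check all survey invariants, raising :class:`ValidationError` on the
    first violated one with the offending rows named."""
    rolls, det = dataset.rolls, dataset.detections

    if rolls["roll_id"].duplicated().any():
        dupes = rolls.loc[rolls["roll_id"].duplicated(), "roll_id"].tolist()
        raise ValidationError(f"duplicate roll_id(s): {dupes}")
    bad = rolls[rolls["end"] <= rolls["start"]]
    if len(bad):
        raise ValidationError(f"roll end <= start for roll_id(s): {bad['roll_id'].tolist()}")
    # Rolls of one camera must not overlap.
    for cam, grp in rolls.groupby("camera_id", sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].values[1:] < g["end"].values[:-1]
        if overlap.any():
            raise ValidationError(f"overlapping rolls on camera {cam!r}")

    if (det["species"].astype(str).str.len() == 0).any():
        rows = det.index[det["species"].astype(str).str.len() == 0].tolist()
        raise ValidationError(f"empty species label at row(s) {rows}")

    merged = det.merge(rolls, on="roll_id", how="left", suffixes=("", "_roll"))
    unknown = merged["start"].isna()
    if unknown.any():
        rows = merged.index[unknown].tolist()
        ids = merged.loc[unknown, "roll_id"].unique().tolist()
        raise ValidationError(
            f"detection row(s) {rows} reference unknown roll_id(s) {ids}"
        )
    outside = (merged["timestamp"] < merged["start"]) | (merged["timestamp"] > merged["end"])
    if outside.any():
        rows = merged.index[outside].tolist()
        raise ValidationError(
            f"detection row(s) {rows} have timestamps outside their roll interval"
        )


def _read_csv(path, columns, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"{what} file {path} missing column(s): {', '.join(missing)}")
    return raw


def _parse_timestamps(series: pd.Series, path, colname: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & (series.astype(str).str.len() > 0)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        lines = (series.index[bad] + 2).tolist()
        raise SchemaError(
            f"unparseable {colname} timestamp(s) in {path} at line(s) {lines[:10]}"
        )
    if parsed.isna().any():
        lines = (series.index[parsed.isna()] + 2).tolist()
        raise SchemaError(f"empty {colname} timestamp(s) in {path} at line(s) {lines[:10]}")
    return parsed


def read_survey(detections_path, rolls_path, config=None) -> SurveyDataset:
    """Load and validate a survey from its two CSV files.

    ``config`` (an :class:`~camtrap_avoidance.config.AnalysisConfig`, or any
    object with ``species_roles`` and ``excluded_cameras`` attributes) supplies
    the species-role map and the camera exclusion list; excluded cameras are
    dropped — detections and rolls both — before validation, and the dropped
    row counts are logged.
    """
    species_roles = dict(getattr(config, "species_roles", {}) or {})
    excluded = frozenset(getattr(config, "excluded_cameras", ()) or ())

    det_raw = _read_csv(detections_path, DETECTION_COLUMNS, "detection")
    roll_raw = _read_csv(rolls_path, ROLL_COLUMNS, "roll")

    det = det_raw[DETECTION_COLUMNS].copy()
    det["timestamp"] = _parse_timestamps(det_raw["timestamp"], detections_path, "timestamp")
    rolls = roll_raw[ROLL_COLUMNS].copy()
    rolls["start"] = _parse_timestamps(roll_raw["start"], rolls_path, "start")
    rolls["end"] = _parse_timestamps(roll_raw["end"], rolls_path, "end")

    if excluded:
        n_det, n_roll = len(det), len(rolls)
        det = det[~det["camera_id"].isin(excluded)].reset_index(drop=True)
        rolls = rolls[~rolls["camera_id"].isin(excluded)].reset_index(drop=True)
        logger.info(
            "camera exclusion list (%d cameras): dropped %d detections, %d rolls",
            len(excluded), n_det - len(det), n_roll - len(rolls),
        )

    dataset = SurveyDataset(det, rolls, species_roles, excluded)
    validate_survey(dataset)
    logger.info(
        "loaded survey: %d detections on %d rolls (%d cameras)",
        len(det), len(rolls), rolls["camera_id"].nunique(),
    )
    return dataset


def _timestamp_format(ts: pd.Series) -> str:
    """Minute strings when the data are minute-resolution, else seconds."""
    ns = ts.astype("int64")
    if (ns % 60_000_000_000 == 0).all():
        return "%Y-%m-%dT%H:%M"
    return "%Y-%m-%dT%H:%M:%S"


def write_survey(dataset: SurveyDataset, out_dir) -> Path:
    """Write ``detections.csv`` and ``rolls.csv`` into ``out_dir``.

    Round-trip guarantee: :func:`read_survey` on the written files reproduces
    the dataset exactly at the declared timestamp resolution.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    det = dataset.detections.copy()
    if len(det):
        det["timestamp"] = det["timestamp"].dt.strftime(_timestamp_format(det["timestamp"]))
    det.to_csv(out_dir / "detections.csv", index=False)

    rolls = dataset.rolls.copy()
    if len(rolls):
        fmt = _timestamp_format(pd.concat([rolls["start"], rolls["end"]], ignore_index=True))
        rolls["start"] = rolls["start"].dt.strftime(fmt)
        rolls["end"] = rolls["end"].dt.strftime(fmt)
    rolls.to_csv(out_dir / "rolls.csv", index=False)
    return out_dir
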