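import numpy as np
import pandas as pd
import pytest

from camtrap_avoidance.data import SurveyDataset


def make_rolls(*spans, site="S1"):
    """Rolls from (camera_id, start, end) triples; roll_id = camera_id + '-R1'."""
    rows = [
        {"roll_id": f"{cam}-R1", "camera_id": cam, "site_id": site,
         "start": pd.Timestamp(start), "end": pd.Timestamp(end)}
        for cam, start, end in spans
    ]
    return pd.DataFrame(rows, columns=["roll_id", "camera_id", "site_id", "start", "end"])


def make_detections(rows, site="S1"):
    """Detections from (camera_id, species, timestamp) triples."""
    recs = [
        {"site_id": site, "camera_id": cam, "roll_id": f"{cam}-R1",
         "species": sp, "timestamp": pd.Timestamp(ts)}
        for cam, sp, ts in rows
    ]
    cols = ["site_id", "camera_id", "roll_id", "species", "timestamp"]
    if not recs:
        return pd.DataFrame(columns=cols).astype({"timestamp": "datetime64[ns]"})
    return pd.DataFrame(recs, columns=cols)


@pytest.fixture
def toy_dataset():
    """One 60-day roll with a few prey and predator detections mid-roll."""
    rolls = make_rolls(("C1", "2021-01-01T00:00", "2021-03-02T00:00"))
    det = make_detections([
        ("C1", "prey", "2021-01-10T08:00"),
        ("C1", "prey", "2021-01-20T09:30"),
        ("C1", "prey", "2021-02-05T17:00"),
        ("C1", "predator", "2021-01-15T22:00"),
        ("C1", "predator", "2021-02-10T03:00"),
    ])
    return SurveyDataset(det, rolls,
                         {"prey": "prey", "predator": "predator"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
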