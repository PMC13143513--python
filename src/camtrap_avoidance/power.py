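"""Downsampling power study.

How much significance survives when a well-detected prey species is thinned
to the sample size of a sparser one?  Prey detections are subsampled without
replacement to a target n, the randomization test is re-run per subset with
an independent substream, and the per-block p-values are summarized as mean,
standard deviation, and the fraction significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurveyDataset
from .preprocess import TestParams, preprocess_survey
from .randtest import TestResult, block_labels, run_site_test

__all__ = ["DownsamplingResult", "downsample", "downsampling_study"]


@dataclass
class DownsamplingResult:
    """Per-subset p-values and their summary for one downsampling study."""

    subset_size: int
    n_subsets: int
    p_matrix: np.ndarray          # (n_subsets, 2 * n_blocks_per_side)
    mean_p: np.ndarray
    sd_p: np.ndarray              # NaN when n_subsets < 2
    frac_significant: np.ndarray  # fraction of subsets with p < alpha
    alpha: float
    labels: list

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": self.labels,
            "mean_p": self.mean_p,
            "sd_p": self.sd_p,
            "frac_significant": self.frac_significant,
        })


def downsample(prey_detections: pd.DataFrame, n: int,
               rng: np.random.Generator) -> pd.DataFrame:
    """Uniform subsample of exactly ``n`` detections without replacement,
    returned in timestamp order."""
    total = len(prey_detections)
    if n > total:
        raise ValueError(f"cannot downsample to {n} from {total} detections")
    idx = rng.choice(total, size=n, replace=False)
    sub = prey_detections.iloc[np.sort(idx)]
    return sub.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def downsampling_study(dataset: SurveyDataset, prey: str, predator: str,
                       n: int, n_subsets: int,
                       params: TestParams) -> DownsamplingResult:
    """Repeatedly subsample prey to ``n`` and re-run the site test.

    Predator detections are untouched.  Subset ``i`` draws both its sample
    and its randomization from substream ``i`` of ``params.seed``, so the
    study is reproducible while subsets stay independent.
    """
    filtered, _ = preprocess_survey(dataset, params)
    det = filtered.detections
    prey_det = det[det["species"] == prey]
    others = det[det["species"] != prey]

    streams = np.random.SeedSequence(params.seed).spawn(n_subsets)
    rows = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        sub = downsample(prey_det, n, rng)
        ds = filtered.with_detections(pd.concat([others, sub], ignore_index=True))
        result: TestResult = run_site_test(ds, prey, predator, params,
                                           preprocessed=True, rng=rng)
        rows.append(result.p if result.has_data
                    else np.full(2 * params.n_blocks_per_side, np.nan))
    p_matrix = np.array(rows, dtype=float)

    sd = (np.nanstd(p_matrix, axis=0, ddof=1) if n_subsets > 1
          else np.full(p_matrix.shape[1], np.nan))
    return DownsamplingResult(
        subset_size=n,
        n_subsets=n_subsets,
        p_matrix=p_matrix,
        mean_p=np.nanmean(p_matrix, axis=0),
        sd_p=sd,
        frac_significant=np.nanmean(p_matrix < params.alpha, axis=0),
        alpha=params.alpha,
        labels=block_labels(params),
    )
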