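"""Result tables: one row per site x prey x predator with the six block
p-values in chronological order, three-decimal formatting, and a star for
significance at alpha.  Full precision stays in the machine-readable CSVs;
rounding is presentation only."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .randtest import TestResult

__all__ = ["results_frame", "report_table", "null_histograms"]


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Machine-readable result table (full precision)."""
    if results:
        ref = results[0]
        for r in results[1:]:
            if r.labels != ref.labels or r.alpha != ref.alpha:
                raise ValueError("results mix incompatible test parameters")
    rows = []
    for r in results:
        row = {
            "site_id": r.site_id,
            "prey_species": r.prey_species,
            "predator_species": r.predator_species,
            "n_predator_events": r.n_predator_events,
            "n_rolls_used": r.n_rolls_used,
            "n_iterations": r.n_iterations,
            "seed": r.seed,
        }
        for j, lab in enumerate(r.labels):
            row[f"p {lab}"] = r.p[j] if r.has_data else np.nan
            row[f"obs {lab}"] = int(r.observed[j]) if r.has_data else np.nan
        rows.append(row)
    cols = None
    if results:
        cols = list(rows[0].keys())
    return pd.DataFrame(rows, columns=cols)


def report_table(results: list[TestResult], out_path) -> Path:
    """Write the presentation table: p to three decimals, ``*`` below alpha."""
    frame = results_frame(results)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if not len(frame):
        pd.DataFrame(columns=["site_id", "prey_species", "predator_species"]
                     ).to_csv(out_path, index=False)
        return out_path
    alpha = results[0].alpha
    pretty = frame[["site_id", "prey_species", "predator_species"]].copy()
    for lab in results[0].labels:
        p = frame[f"p {lab}"]
        pretty[lab] = [
            "no data" if np.isnan(v) else f"{v:.3f}" + ("*" if v < alpha else "")
            for v in p
        ]
    pretty.to_csv(out_path, index=False)
    return out_path


def null_histograms(result: TestResult, null_counts: np.ndarray,
                    out_path) -> Path:
    """Per-block histogram of null counts (the data behind density panels):
    columns block, count, n_iterations_with_count, observed."""
    rows = []
    for j, lab in enumerate(result.labels):
        values, freq = np.unique(null_counts[:, j], return_counts=True)
        for v, f in zip(values, freq):
            rows.append({
                "block": lab,
                "count": int(v),
                "n_iterations_with_count": int(f),
                "observed": int(result.observed[j]),
            })
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path
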