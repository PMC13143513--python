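"""Run the reactive-avoidance randomization test on the filtered
worked-example survey: prey counts in six 24-h blocks around each predator
detection, against 1000 date-randomized relocations per event.

Writes the p-value table (full precision + presentation) and the per-block
null-count histograms under results/test/.
"""

import argparse
from pathlib import Path

import numpy as np

from camtrap_avoidance.data import read_survey
from camtrap_avoidance.preprocess import TestParams
from camtrap_avoidance.randtest import run_site_test
from camtrap_avoidance.report import null_histograms, report_table, results_frame

IN, OUT = Path("results/filtered"), Path("results/test")


class _Roles:
    species_roles = {"prey": "prey", "predator": "predator"}
    excluded_cameras = []


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iterations", type=int, default=1000)
    args = ap.parse_args()

    dataset = read_survey(IN / "detections.csv", IN / "rolls.csv", _Roles())
    params = TestParams(n_iterations=args.iterations, seed=args.seed)
    result, null = run_site_test(dataset, "prey", "predator", params,
                                 preprocessed=True, keep_null=True)

    OUT.mkdir(parents=True, exist_ok=True)
    results_frame([result]).to_csv(OUT / "test_results_full.csv", index=False)
    report_table([result], OUT / "test_results_table.csv")
    null_histograms(result, null.counts, OUT / "null_histograms.csv")

    print(f"{result.n_predator_events} predator events on "
          f"{result.n_rolls_used} rolls, {result.n_iterations} iterations")
    for lab, obs, p in zip(result.labels, result.observed, result.p):
        star = " *" if p < result.alpha else ""
        print(f"  block {lab:>10}: observed {obs:4d}  p = {p:.3f}{star}")
    k = params.n_blocks_per_side
    if result.p[k] < result.alpha:
        print("finding: prey detections 0-24 h after predator passage are "
              "significantly depressed (the injected avoidance is recovered)")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
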