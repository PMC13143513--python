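"""Apply the detection filters to the worked-example survey: 30-min
time-to-independence on predator detections (central detection retained),
72-h roll-edge exclusion, 30-day minimum roll lifespan.

Reads results/survey/, writes the filtered survey and a filter report under
results/filtered/.
"""

import json
from pathlib import Path

from camtrap_avoidance.data import read_survey, write_survey
from camtrap_avoidance.preprocess import TestParams, preprocess_survey

IN, OUT = Path("results/survey"), Path("results/filtered")


class _Roles:
    species_roles = {"prey": "prey", "predator": "predator"}
    excluded_cameras = []


def main():
    dataset = read_survey(IN / "detections.csv", IN / "rolls.csv", _Roles())
    filtered, report = preprocess_survey(dataset, TestParams())
    write_survey(filtered, OUT)
    OUT.joinpath("filter_report.json").write_text(
        json.dumps(report, indent=2, default=str))

    before = report["predator_filters"]["before"].get("predator", 0)
    after = report["predator_filters"]["after"].get("predator", 0)
    print(f"rolls: {report['lifespan_filter']['rolls_before']} -> "
          f"{report['lifespan_filter']['rolls_after']} (lifespan >= 30 d)")
    print(f"predator detections: {before} -> {after} "
          "(independence filter + 72-h edge exclusion)")
    print(f"predator co-detection rate: {report['predator_co_detection_pct']}"
          " (single predator species: no following confound)")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
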