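# camtrap-avoidance

Randomization tests for **reactive predator avoidance** in camera-trap
detection data: after a predator passes a camera, do prey detections in the
following hours drop below what chance predicts?

The package is for ecologists working with multi-species camera-trap
surveys (one detection table plus deployment/roll metadata). It implements
the full analysis pipeline — bespoke detection filters, a diel-preserving
date-randomization null, empirical one-sided p-values over 24-h blocks, and
a downsampling power study — together with a synthetic survey generator
with *known injected* avoidance, so every stage can be validated end to end
without field data.

## The statistic and its null

For each filtered predator detection at time *t₀* at a camera, prey
detections at the same camera are counted in six consecutive 24-h blocks,
[−72,−48), [−48,−24), [−24,0), (0,24], (24,48], (48,72] hours relative to
*t₀*, and summed over all predator events. Under the no-avoidance null,
each predator event is relocated to a calendar date drawn uniformly from
its camera roll (the continuous operating interval between services),
**keeping the event's clock time** so diel activity structure is preserved,
and the counts are recomputed; 1000 relocations give the null distribution.
The empirical one-sided p-value for an after-block is

p = #{iterations with null count ≤ observed} / N

(ties inclusive; before-blocks use ≥, testing for *elevated* prey presence
as the baseline check). Avoidance shows up as a depressed (0,24] count with
small p.

Before testing, detections pass the survey's curation rules: a 30-min
time-to-independence filter on predator detections (chains of triggers
separated by <30 min collapse to their *central* element, keeping the
retained time symmetric for before/after comparisons), exclusion of
predator events within 72 h of a roll's start or end (so all six blocks are
observable, and randomized dates are confined to the same margin-trimmed
interval), and removal of rolls shorter than 30 days (too little room to
randomize). Only rolls with at least one detection of both species enter
the test.

## Worked example

The numbered scripts under `analysis/` run the pipeline on a synthetic
survey (20 cameras, 90-day rolls, a diurnal prey at ~1 detection/day and a
sparse nocturnal predator at ~0.03/day, with prey intensity multiplied by
0.4 for 24 h after each predator trigger):

```
python analysis/01_simulate_survey.py --seed 11
python analysis/02_preprocess.py
python analysis/03_randomization_test.py --seed 11
python analysis/04_power_downsampling.py --seed 11
```

which prints (seed 11):

```
38 predator events on 16 rolls, 1000 iterations
  block  [-72,-48): observed   36  p = 0.836
  block  [-48,-24): observed   56  p = 0.058
  block    [-24,0): observed   45  p = 0.414
  block     (0,24]: observed   17  p = 0.000 *
  block    (24,48]: observed   47  p = 0.693
  block    (48,72]: observed   45  p = 0.599
```

The injected avoidance is recovered exactly where it was placed: the
(0,24] count (17) sits far below its null distribution while all other
blocks are unremarkable. Thinning the ~2000 prey detections to n = 200
(script 04) shows the method's sample-size floor: the same survey then
yields p (mean ± SD) = 0.213 ± 0.231 across 20 subsets, significant in only
20% of them — abundant prey data are required to see even a strong effect.

The same pipeline is available as a CLI over config files
(`camtrap-avoidance {simulate|preprocess|test|power|report} --config FILE`)
for running on real detection tables; see `src/camtrap_avoidance/data.py`
for the two-file CSV dialect.

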