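# Methods

## The test

The quantity under test is camera-local and purely temporal: prey detection
counts in consecutive 24-h blocks spanning 72 h before and after each
predator detection, summed over predator events. A prey detection that
falls in the windows of two predator events is counted twice (the statistic
is a plain sum over events); a prey detection exactly simultaneous with the
reference time belongs to no block (the before/after dichotomy is undefined
at offset zero, and before-blocks are closed-left/open-right against
after-blocks open-left/closed-right, symmetric about that excluded
instant).

The null model relocates each predator event independently, uniformly and
with replacement over the *eligible dates* of its roll — dates on which the
event's unchanged clock time falls inside `[roll start + margin, roll end −
margin]` — and recounts. Keeping clock times fixed means the null conserves
the predator's diel activity profile exactly, so a diurnal prey and a
nocturnal predator cannot generate spurious "avoidance" through activity
timing alone. Confining relocations to the same margin-trimmed interval
that observed events were filtered to gives observed and null counts
identical exposure; without it, null events could sit close enough to roll
edges that parts of their ±72-h windows fall outside the recording period,
deflating null counts and biasing p downward.

Empirical one-sided p-values count ties as extreme (`≤` for after-blocks,
where the alternative is depressed prey presence; `≥` for before-blocks,
where the baseline check looks for elevation). Inclusive ties make the
discrete p super-uniform, i.e. the test errs conservative. p-values are
reported raw, with a significance flag at α = 0.05 and no multiple-testing
correction; the per-block identity `#{≤obs} + #{≥obs} = N + #{=obs}` is
asserted in the test suite.

### Parameters

| parameter | default | why |
|---|---|---|
| `independence_gap_min` | 30 min | collapses burst triggering into one event; activity patterns of large carnivores are insensitive to the exact gap |
| `edge_margin_h` | 72 h | equals the full block span per side, so every retained event has fully observable windows |
| `block_width_h` × `n_blocks_per_side` | 24 h × 3 | 24-h blocks absorb the diel cycle; beyond 72 h, associating prey presence with the original predator passage is not meaningful |
| `n_iterations` | 1000 | p resolution 0.001 at run time (validation studies use 500: resolution 0.002 is ample at α = 0.05) |
| `min_lifespan_days` | 30 | rolls shorter than this randomize within too narrow a window to be reliable |
| `alpha` | 0.05 | conventional |

Cluster boundaries use strict chaining (consecutive gaps < gap); the
retained representative is the element at 1-based position ⌈k/2⌉ — for even
clusters the *earlier* middle element, a deterministic tie-break that does
not favor roll edges. The edge-exclusion interval is closed: events exactly
at `start + margin` or `end − margin` are retained. The lifespan filter is
strict at its boundary (a 29.9-day roll drops, a 30.0-day roll stays) and
applies per roll, since randomization operates within rolls. Only predator
detections are independence-filtered and edge-excluded; prey detections are
removed only when their whole roll is dropped.

### Randomness

One master seed per run feeds a `numpy.random.SeedSequence`. The null is
drawn as per-event index vectors (length = iterations) from a single
generator rather than one generator per iteration: statistically identical,
reproducible given the seed, and much cheaper. Replicated studies spawn a
child stream per replicate; downsampling subsets each get an independent
substream for both the subset draw and the randomization, so between-subset
variance is honest.

## The synthetic survey generator

Each species at each camera is an inhomogeneous Poisson process whose
intensity is piecewise-constant over hours of the day and integrates to the
nominal daily rate. Sampling inverts the cumulative intensity over the
roll, then floors to the survey's minute clock. Defaults place a diurnal
prey (activity 06:00–19:00, morning and late-afternoon peaks) against a
nocturnal-crepuscular predator — deliberately non-overlapping profiles, so
the calibration studies exercise exactly the confound the diel-preserving
null is meant to absorb.

Avoidance is injected by thinning: every prey trigger falling within
`avoidance_duration_h` (default 24 h) after any same-camera predator
trigger is dropped with probability `avoidance_effect` *e*. Windows of
overlapping predator events union rather than compound, so *e* stays
interpretable as the per-window rate reduction. A predator-following
artifact can be injected symmetrically (`attraction_effect`): the predator
is simulated at its ceiling rate and thinned back to baseline outside
post-prey windows. Burst triggering spawns 1–2 extra triggers within ±15
min of a parent with probability `burst_prob` (default 0.1), giving the
independence filter realistic work; suppression thinning runs after burst
insertion so burst copies obey the same suppressed intensity.

What the generator does **not** emulate: spatial structure (home ranges,
cross-camera movement of one animal), seasonal or weather-driven rate
drift, imperfect/varying detection probability, misidentification, and
multi-predator interactions beyond a single attraction kernel. Passing
tests therefore show the *statistical machinery* behaves correctly under
the model's assumptions — they do not show those assumptions hold in any
field system.

## Validation studies and their design

**Calibration** (200 null surveys, 20 cameras × 90 d, prey 1.0/day,
predator 0.3/day): per-block rejection rate at α = 0.05 stays in the 99%
binomial band [0.01, 0.09]. Under the null, observed predator dates are
themselves uniform over the margin-trimmed roll, so observed and null
counts are exchangeable and p is super-uniform.

**Power** (100 surveys, 30 cameras, prey 3/day, predator 0.5/day,
e = 0.8, D = 24 h): the (0,24] block rejects essentially always.

**Known limitation — conservatism next to a strong effect.** In the same
power scenario the far after-blocks become *conservative* (rejection ≈
0.01–0.04, below the nominal 0.05): observed (24,48] and (48,72] windows
can never overlap the anchoring event's own suppression patch, while
uniformly relocated null windows can, deflating the null mean by ~2%
(~0.6 σ on the aggregate count at these densities). The same contamination
elevates observed *before*-block counts relative to the null, so a strong
true avoidance effect can manifest as apparently significant pre-predator
prey elevation. Both are properties of the randomization design itself —
the null distribution is estimated from data that contain the effect
elsewhere in the series — and practitioners should read far-block and
before-block p-values with this in mind.

**Oracle agreement.** With a single predator event and ~10 eligible dates,
the null can be enumerated exactly (each date equally likely). The
Monte-Carlo null at 10,000 iterations matches the enumeration within 0.006
in per-block p on the shipped fixture, bounding Monte-Carlo error
independently of the implementation path.

**Downsampling** (e = 0.6, ~2000 prey, predator 0.03/day over 20 cameras
× 90 d; prey thinned to n = 200). The predator density here is the
deliberate design choice: the significance-loss phenomenon lives in the
sparse-count regime. At ~50 filtered predator events, the full-data
aggregate (0,24] null count is ~50 (a ~0.6× deficit is then ≳4 σ:
detection essentially certain), while at n = 200 prey the aggregate drops
to ~5, where a 0.6× deficit is ~1.3 σ and significance survives only
sporadically. Rates of large carnivores in real surveys are of this order
(one detection per camera per weeks), which is exactly why published
camera-trap avoidance tests are power-limited for all but the most
abundant prey. The 20 downsampled runs are spread across the 20 replicate
surveys (one subset each) rather than conditioned on a single survey,
matching the full-data estimator they are compared against.

Validation studies use 500 null iterations and the replicate counts above;
these sizes put Monte-Carlo error well below the effect sizes under test
while keeping the whole validation battery at a few minutes on one CPU.

## Degenerate inputs and numerical notes

Times are handled as `datetime64[ns]` throughout (inputs at minute or
second resolution are preserved and round-trip bit-identically; all-minute
data serialize as minute strings). Internally, block counting converts to
float hours since epoch (double precision leaves sub-microsecond resolution
at current dates) and counts blocks via `searchsorted` on sorted per-camera
prey arrays. An event whose roll admits no eligible date excludes that roll
from the test with a warning; a prey/predator pair with no co-occupied roll
yields an explicit "no data" result rather than a p-value; a margin wider
than half the roll empties it with a warning. Duplicate timestamps and
same-date relocations of two events are allowed by construction.
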