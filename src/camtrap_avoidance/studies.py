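"""Replicated simulation studies validating the randomization test.

Four studies, each run on synthetic surveys from :mod:`.simulate`:

* **calibration** — null surveys (no avoidance, no attraction): the
  per-block rejection rate at alpha should sit at or just under alpha
  (empirical p-values with inclusive ties are super-uniform);
* **power** — strong injected avoidance: the first post-predator block
  should reject almost always, while the last block stays at alpha;
* **oracle** — a single predator event with a handful of eligible dates,
  where the Monte-Carlo null can be checked against exhaustive enumeration;
* **downsampling** — moderate avoidance with ample prey, re-tested after
  thinning prey to a small n: significance should largely evaporate,
  quantifying the sample-size floor of the method.

Every study derives all of its randomness from one base seed via
``numpy.random.SeedSequence`` so results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SurveyDataset
from .power import downsampling_study
from .preprocess import TestParams
from .randtest import enumerate_null, null_distribution, p_values, run_site_test
from .simulate import Scenario, simulate_interacting

__all__ = [
    "NULL_SCENARIO",
    "AVOIDANCE_SCENARIO",
    "DOWNSAMPLING_SCENARIO",
    "STUDY_PARAMS",
    "calibration_study",
    "power_study",
    "oracle_agreement",
    "downsampling_validation",
]

#: Baseline null survey: a mid-sized grid with a common diurnal prey and a
#: scarcer nocturnal predator, no interaction.
NULL_SCENARIO = Scenario(n_cameras=20, roll_days=90.0, prey_rate=1.0,
                         predator_rate=0.3, avoidance_effect=0.0,
                         attraction_effect=0.0)

#: Strong avoidance: prey intensity cut by 80% for 24 h after each predator
#: trigger, with abundant detections of both species.
AVOIDANCE_SCENARIO = Scenario(n_cameras=30, roll_days=90.0, prey_rate=3.0,
                              predator_rate=0.5, avoidance_effect=0.8,
                              avoidance_duration_h=24.0)

#: Moderate avoidance with roughly two thousand prey detections and a
#: sparse predator (about one detection per camera per 25 days, the order
#: large carnivores show in practice): the regime where block counts are
#: small enough that downsampling visibly erodes significance.
DOWNSAMPLING_SCENARIO = Scenario(n_cameras=20, roll_days=90.0, prey_rate=1.0,
                                 predator_rate=0.03, avoidance_effect=0.6,
                                 avoidance_duration_h=24.0)

#: Test parameters used throughout the simulation studies; 500 null
#: iterations give p a resolution of 0.002, ample for alpha = 0.05.
STUDY_PARAMS = TestParams(n_iterations=500)


def _seed(base: int, *key: int) -> int:
    """Deterministic 31-bit child seed for (base, key...)."""
    return int(np.random.SeedSequence((base, *key)).generate_state(1)[0] >> 1)


def _replicate_pvalues(scenario: Scenario, params: TestParams,
                       n_replicates: int, base_seed: int) -> np.ndarray:
    """p-value matrix (n_replicates x blocks) over fresh synthetic surveys."""
    rows = []
    for r in range(n_replicates):
        sc = scenario.with_(seed=_seed(base_seed, r, 0))
        pr = params.with_(seed=_seed(base_seed, r, 1))
        dataset = simulate_interacting(sc)
        result = run_site_test(dataset, sc.prey_species, sc.predator_species, pr)
        rows.append(result.p)
    return np.asarray(rows, dtype=float)


def calibration_study(n_replicates: int = 200, scenario: Scenario = NULL_SCENARIO,
                      params: TestParams = STUDY_PARAMS, base_seed: int = 0) -> dict:
    """Type-I error of the test on null surveys.

    Returns per-block rejection rates at ``params.alpha`` plus the raw
    p-matrix; on a correctly calibrated test every rate is <= alpha up to
    binomial noise.
    """
    p = _replicate_pvalues(scenario, params, n_replicates, base_seed)
    return {
        "p_matrix": p,
        "rejection_rate": (p < params.alpha).mean(axis=0),
        "n_replicates": n_replicates,
        "alpha": params.alpha,
    }


def power_study(n_replicates: int = 100, scenario: Scenario = AVOIDANCE_SCENARIO,
                params: TestParams = STUDY_PARAMS, base_seed: int = 1) -> dict:
    """Rejection rates under injected avoidance.

    The block just after the predator (index ``n_blocks_per_side``) carries
    the signal; blocks beyond the avoidance window measure specificity.
    """
    p = _replicate_pvalues(scenario, params, n_replicates, base_seed)
    rates = (p < params.alpha).mean(axis=0)
    k = params.n_blocks_per_side
    return {
        "p_matrix": p,
        "rejection_rate": rates,
        "power_first_after_block": float(rates[k]),
        "rejection_last_after_block": float(rates[-1]),
        "n_replicates": n_replicates,
        "alpha": params.alpha,
    }


def _single_event_dataset(base_seed: int) -> tuple[SurveyDataset, TestParams]:
    """One short roll, one predator event, a fixed prey pattern: small enough
    that the null can be enumerated exactly over its eligible dates."""
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, 99)))
    start = pd.Timestamp("2021-03-01T00:00")
    end = start + pd.Timedelta(days=16)  # margin 72 h => ~10 eligible dates
    rolls = pd.DataFrame([{"roll_id": "R1", "camera_id": "C1", "site_id": "ORACLE",
                           "start": start, "end": end}])
    # ~25 prey detections scattered non-uniformly over the roll.
    offsets_h = np.sort(rng.uniform(0, 16 * 24, size=25))
    prey_ts = start + pd.to_timedelta(np.floor(offsets_h * 60), unit="m")
    det = pd.DataFrame({
        "site_id": "ORACLE", "camera_id": "C1", "roll_id": "R1",
        "species": "prey", "timestamp": prey_ts,
    })
    pred = pd.DataFrame([{"site_id": "ORACLE", "camera_id": "C1", "roll_id": "R1",
                          "species": "predator",
                          "timestamp": start + pd.Timedelta(days=8, hours=14)}])
    dataset = SurveyDataset(pd.concat([det, pred], ignore_index=True), rolls,
                            {"prey": "prey", "predator": "predator"})
    params = TestParams(n_iterations=10_000, min_lifespan_days=10.0)
    return dataset, params


def oracle_agreement(base_seed: int = 2) -> dict:
    """Monte-Carlo null vs exhaustive enumeration on the single-event case.

    Exact per-block p comes from averaging over every eligible date (each
    equally likely); the Monte-Carlo p uses 10,000 iterations.  Reports the
    largest absolute disagreement across blocks.
    """
    dataset, params = _single_event_dataset(base_seed)
    params = params.with_(seed=_seed(base_seed, 0))
    observed, exact_outcomes = enumerate_null(dataset, "prey", "predator", params)
    p_exact = p_values(observed, exact_outcomes, params.n_blocks_per_side)
    obs_mc, null, _ = null_distribution(dataset, "prey", "predator", params)
    assert np.array_equal(observed, obs_mc)
    p_mc = p_values(observed, null.counts, params.n_blocks_per_side)
    return {
        "p_exact": p_exact,
        "p_mc": p_mc,
        "max_abs_diff": float(np.abs(p_exact - p_mc).max()),
        "n_eligible_dates": exact_outcomes.shape[0],
    }


def downsampling_validation(n_replicates: int = 20, n_small: int = 200,
                            n_subsets: int = 20,
                            scenario: Scenario = DOWNSAMPLING_SCENARIO,
                            params: TestParams = STUDY_PARAMS,
                            base_seed: int = 3) -> dict:
    """Significance loss when abundant prey data are thinned to a small n.

    Full-data power is the fraction of replicate surveys whose first
    after-block is significant.  The ``n_subsets`` downsampled runs are
    spread across the replicate surveys round-robin (one subset per survey
    when the counts match), so the downsampled fraction is not conditioned
    on a single predator layout.
    """
    p_full = _replicate_pvalues(scenario, params, n_replicates, base_seed)
    k = params.n_blocks_per_side
    frac_full = float((p_full[:, k] < params.alpha).mean())

    p_small = []
    for j in range(n_subsets):
        r = j % n_replicates
        sc = scenario.with_(seed=_seed(base_seed, r, 0))
        dataset = simulate_interacting(sc)
        study = downsampling_study(dataset, sc.prey_species, sc.predator_species,
                                   n_small, 1,
                                   params.with_(seed=_seed(base_seed, j, 2)))
        p_small.append(study.p_matrix[0])
    p_small = np.asarray(p_small)
    frac_small = float((p_small[:, k] < params.alpha).mean())
    return {
        "frac_significant_full": frac_full,
        "frac_significant_downsampled": frac_small,
        "mean_p_downsampled": float(np.nanmean(p_small[:, k])),
        "sd_p_downsampled": float(np.nanstd(p_small[:, k], ddof=1)),
        "n_replicates": n_replicates,
        "n_small": n_small,
        "n_subsets": n_subsets,
    }
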