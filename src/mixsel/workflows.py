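"""High-level cohort analyses shared by the CLI pipeline, the acceptance
script and calibration studies.

These wrap the per-participant operations into the three cohort-level
summaries the method rests on: pattern-difference decoding (interaction
strength), the cross-decoding generalization ratio, and the
reliability-corrected between-task RDM comparison.
"""

from __future__ import annotations

import numpy as np

from .datasets import PatternDataset
from .decoding import (
    AccuracyTable,
    DecodingSpec,
    category_cross_decoding,
    category_decoding,
    condition_pairwise_decoding,
)
from .mixed_selectivity import (
    cohort_cross_decoding_ratio,
    pattern_difference_decode,
)
from .rsa import (
    category_similarity_vector,
    geometry_variance_explained,
    within_participant_between_task_correlation,
)
from .simulate import SimulationConfig, generate_dataset


def cohort_pattern_difference(datasets, spec: DecodingSpec):
    """Per-participant pattern-difference results for a cohort."""
    return {ds.participant_id: pattern_difference_decode(ds, spec)
            for ds in datasets}


def cohort_within_between(datasets, spec: DecodingSpec):
    """Within-task category decoding (task-averaged) and cross-task category
    decoding per participant."""
    within, between = [], []
    for ds in datasets:
        tasks = ds.tasks
        w = np.mean([category_decoding(ds, t, spec) for t in tasks])
        within.append(w)
        between.append(category_cross_decoding(ds, spec))
    return np.array(within), np.array(between)


def cohort_similarity_vectors(datasets, spec: DecodingSpec):
    """Within-task category similarity vectors (28 pairwise accuracies per
    task) for every participant."""
    vectors = {}
    for ds in datasets:
        table = AccuracyTable()
        for pair_id, acc in condition_pairwise_decoding(ds, spec).items():
            table.add(ds.participant_id, ds.region_id, "condition_pair",
                      pair_id, acc)
        vectors[ds.participant_id] = {
            t: category_similarity_vector(table, ds.participant_id,
                                          ds.region_id, t)
            for t in ds.tasks
        }
    return vectors


def null_calibration_summary(seed: int, spec: DecodingSpec | None = None) -> dict:
    """The three null-calibration quantities on one additive cohort.

    Generates the default additive cohort (13 participants, 10 runs per
    task, 8 categories, 100 voxels, additivity imposed in the z-scored
    space) and returns the cohort means of: pattern-difference decoding
    accuracy (chance = .5 under the null), the chance-referenced
    cross-decoding ratio (1 = full generalization), and the
    reliability-corrected between-task RDM variance explained (1 = geometry
    unchanged).
    """
    spec = spec or DecodingSpec()
    config = SimulationConfig(seed=seed)
    datasets, _ = generate_dataset(config)

    pdd = cohort_pattern_difference(datasets, spec)
    pdd_mean = float(np.mean([r.accuracy for r in pdd.values()]))

    within, between = cohort_within_between(datasets, spec)
    ratios, excluded = cohort_cross_decoding_ratio(within, between)
    ratio_mean = float(np.nanmean(ratios))

    vectors = cohort_similarity_vectors(datasets, spec)
    geometry = geometry_variance_explained(vectors)

    return {
        "n_participants": config.n_participants,
        "pattern_difference_mean": pdd_mean,
        "pattern_difference_per_participant":
            [pdd[p].accuracy for p in sorted(pdd)],
        "cross_decoding_ratio_mean": ratio_mean,
        "ratio_excluded_participants": excluded,
        "within_task_decoding_mean": float(within.mean()),
        "cross_task_decoding_mean": float(between.mean()),
        "variance_explained_mean": geometry.mean_variance_explained,
        "noise_ceiling": geometry.mean_within,
    }


def geometry_regime_summary(mode: str, interaction_gain: float, seed: int,
                            spec: DecodingSpec | None = None) -> dict:
    """Pattern-difference and geometry outcomes for a rotation or reshape
    cohort (the ventral- vs dorsal-style regimes)."""
    spec = spec or DecodingSpec()
    config = SimulationConfig(geometry_mode=mode,
                              interaction_gain=interaction_gain, seed=seed)
    datasets, _ = generate_dataset(config)
    pdd = cohort_pattern_difference(datasets, spec)
    vectors = cohort_similarity_vectors(datasets, spec)
    geometry = geometry_variance_explained(vectors)
    return {
        "pattern_difference": np.array(
            [pdd[p].accuracy for p in sorted(pdd)]
        ),
        "variance_explained": geometry.variance_explained,
        "noise_ceiling": geometry.mean_within,
    }


def graded_reshaping_cohort(gains, seed: int,
                            spec: DecodingSpec | None = None) -> dict:
    """Participants with individually graded reshaping strength.

    Each participant gets their own reshape gain; returns per-participant
    interaction accuracy and the participant's own between-task RDM
    correlation — the two quantities whose across-participant coupling links
    interaction strength to representational content change.
    """
    spec = spec or DecodingSpec()
    pdd_acc, between_r = [], []
    for i, gain in enumerate(gains):
        mode = "reshape" if gain > 0 else "additive"
        config = SimulationConfig(
            n_participants=1, geometry_mode=mode, interaction_gain=float(gain),
            seed=seed + i,
        )
        ds = generate_dataset(config)[0][0]
        pdd_acc.append(pattern_difference_decode(ds, spec).accuracy)
        vectors = cohort_similarity_vectors([ds], spec)[ds.participant_id]
        between_r.append(within_participant_between_task_correlation(vectors))
    return {
        "interaction_gain": np.asarray(gains, dtype=float),
        "pattern_difference": np.array(pdd_acc),
        "between_task_rdm_correlation": np.array(between_r),
    }
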