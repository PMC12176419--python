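"""Pairwise linear classification with run-aware cross-validation.

All decoding is two-class, linear max-margin (SVM, regularization constant
C = 1 by default), and cross-validated by *runs*: leave-one-run-out for
analyses confined to a single task, and leave-one-adjacent-run-pair-out for
analyses that need both tasks in the training set (each adjacent run pair
(2i-1, 2i) contains one run of each task under the alternating schedule).
Training and test blocks never share a fold, so no information leaks across
the CV boundary.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

from .datasets import PatternDataset, subset, znormalize_blocks

CHANCE = 0.5


class DecodingError(ValueError):
    """Raised when a decoding analysis cannot be set up validly."""


@dataclass
class DecodingSpec:
    """Classifier and cross-validation contract shared by all analyses.

    ``normalize`` applies per-block z-scoring before classification (the
    default for simulated/real beta patterns; disable for the hand-built toy
    geometries).  ``cross_train_full`` switches cross-context training from
    the default rotating all-but-one-fold scheme (training-set size matched
    to within-context decoding, so the cross-decoding ratio is not biased by
    data quantity) to training on the full training context at once.
    Exact-zero decision values are broken by a seeded coin flip.
    """

    regularization_c: float = 1.0
    normalize: bool = True
    cross_train_full: bool = False
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization_c <= 0:
            raise DecodingError("regularization_c must be positive")

    def tie_rng(self) -> np.random.Generator:
        return np.random.default_rng(self.tie_seed)


@dataclass
class AccuracyTable:
    """Long-format store of decoding accuracies.

    One record per (participant, region, analysis, condition pair); the common
    currency of all downstream statistics.
    """

    records: list = field(default_factory=list)

    def add(self, participant_id: str, region_id: str, analysis_id: str,
            condition_pair: str, accuracy: float) -> None:
        if not 0.0 <= accuracy <= 1.0:
            raise DecodingError(f"accuracy {accuracy} outside [0, 1]")
        key = (participant_id, region_id, analysis_id, condition_pair)
        if key in {(r["participant"], r["region"], r["analysis"], r["pair"])
                   for r in self.records}:
            raise DecodingError(f"duplicate accuracy record {key}")
        self.records.append(
            dict(participant=participant_id, region=region_id,
                 analysis=analysis_id, pair=condition_pair, accuracy=accuracy)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["participant", "region", "analysis", "pair", "accuracy"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AccuracyTable":
        frame = pd.read_csv(path, dtype={"participant": str, "region": str})
        table = cls()
        for rec in frame.to_dict("records"):
            table.add(rec["participant"], rec["region"], rec["analysis"],
                      rec["pair"], rec["accuracy"])
        return table

    def lookup(self, participant, region, analysis, pair) -> float:
        for r in self.records:
            if (r["participant"], r["region"], r["analysis"], r["pair"]) == (
                    participant, region, analysis, pair):
                return r["accuracy"]
        raise KeyError((participant, region, analysis, pair))


# ----------------------------------------------------------------------
# Fold construction
# ----------------------------------------------------------------------
def run_folds(labels: pd.DataFrame) -> np.ndarray:
    """Fold id per block: one fold per run (leave-one-run-out)."""
    return labels["run"].to_numpy()


def adjacent_pair_folds(labels: pd.DataFrame) -> np.ndarray:
    """Fold id per block: one fold per adjacent run pair (2i-1, 2i)."""
    runs = labels["run"].to_numpy()
    return (runs + 1) // 2


def audit_adjacent_pairs(dataset: PatternDataset) -> None:
    """Check that every adjacent run pair contains exactly one run per task."""
    run_task = dataset.run_task_map()
    runs = sorted(run_task)
    for fold in sorted({(r + 1) // 2 for r in runs}):
        members = [r for r in runs if (r + 1) // 2 == fold]
        tasks = {run_task[r] for r in members}
        if len(members) != 2 or len(tasks) != 2:
            raise DecodingError(
                f"adjacent run pair {fold} does not contain one run per task "
                f"(runs {members}, tasks {sorted(tasks)})"
            )


# ----------------------------------------------------------------------
# Core binary classification
# ----------------------------------------------------------------------
def _predict(clf: SVC, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    scores = clf.decision_function(X)
    pred = np.where(scores > 0, clf.classes_[1], clf.classes_[0])
    ties = scores == 0
    if ties.any():
        drawn = rng.choice(clf.classes_, size=int(ties.sum()))
        logger.info("decision-value tie(s) broken by seeded coin flip: %s",
                    drawn.tolist())
        pred[ties] = drawn
    return pred


def _fit(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf


def binary_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    spec: DecodingSpec,
    rng: np.random.Generator | None = None,
    permute_training: bool = False,
    perm_rng: np.random.Generator | None = None,
    permute_scope: str = "labels",
) -> tuple[float, int, int]:
    """Mean held-out accuracy over folds; returns (accuracy, n_correct, n_total).

    ``permute_training`` activates the permutation-null device, with two
    scopes.  ``"labels"`` (default, calibrated): relabel the vectors by a
    coherent within-fold permutation and run the whole cross-validation —
    training and test — under that relabeling; within-fold permutation
    preserves every fold's class balance, and relabeling both sides keeps
    the permuted statistic's variance equal to the observed one.
    ``"training_only"``: shuffle only the training labels before fitting and
    score against the true test labels; this shrinks the permuted
    accuracies' spread relative to the observed statistic (the permuted
    classifier cannot align with the test labeling across folds) and is
    anti-conservative under the null — provided for literal reproduction.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DecodingError(f"need exactly 2 classes, got {classes.tolist()}")
    unique_folds = np.unique(folds)
    if unique_folds.size < 2:
        raise DecodingError("need at least 2 cross-validation folds")
    rng = rng if rng is not None else spec.tie_rng()
    y_train_source = y
    if permute_training:
        prng = perm_rng or rng
        if permute_scope == "labels":
            y_perm = y.copy()
            for fold in unique_folds:
                idx = np.flatnonzero(folds == fold)
                y_perm[idx] = y_perm[prng.permutation(idx)]
            y = y_train_source = y_perm
        elif permute_scope == "training_only":
            # redraw (data-blind, null-preserving) until every training set
            # keeps both classes
            for _ in range(1000):
                y_train_source = prng.permutation(y)
                if all(np.unique(y_train_source[folds != f]).size == 2
                       for f in unique_folds):
                    break
            else:
                raise DecodingError(
                    "could not draw a usable label permutation"
                )
        else:
            raise DecodingError(f"unknown permute_scope {permute_scope!r}")
    fold_accs, correct, total = [], 0, 0
    for fold in unique_folds:
        test = folds == fold
        train = ~test
        ytr = y_train_source[train]
        if np.unique(ytr).size < 2:
            raise DecodingError(f"training set for fold {fold} lacks a class")
        clf = _fit(X[train], ytr, spec.regularization_c)
        pred = _predict(clf, X[test], rng)
        hits = pred == y[test]
        fold_accs.append(hits.mean())
        correct += int(hits.sum())
        total += int(hits.size)
    return float(np.mean(fold_accs)), correct, total


def _maybe_normalize(dataset: PatternDataset, spec: DecodingSpec) -> PatternDataset:
    return znormalize_blocks(dataset) if spec.normalize else dataset


# ----------------------------------------------------------------------
# Within-context analyses
# ----------------------------------------------------------------------
def pairwise_decode(
    dataset: PatternDataset,
    pair: tuple[str, str],
    spec: DecodingSpec,
    variable: str = "category",
    cv: str = "leave_one_run_out",
) -> float:
    """Two-class decoding accuracy for one condition pair.

    ``cv`` is ``"leave_one_run_out"`` (single-task analyses) or
    ``"leave_adjacent_run_pair_out"`` (analyses whose training set must span
    both tasks).
    """
    data = _maybe_normalize(dataset, spec)
    sub = subset(data, None, **{variable: list(pair)})
    if cv == "leave_one_run_out":
        folds = run_folds(sub.labels)
    elif cv == "leave_adjacent_run_pair_out":
        folds = adjacent_pair_folds(sub.labels)
    else:
        raise DecodingError(f"unknown cv scheme {cv!r}")
    acc, _, _ = binary_cv_accuracy(
        sub.betas, sub.labels[variable].to_numpy(), folds, spec
    )
    return acc


def category_pairs(categories) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(categories), 2))


def category_decoding(dataset: PatternDataset, task: str,
                      spec: DecodingSpec) -> float:
    """Mean pairwise category decoding within one task (leave-one-run-out)."""
    data = subset(dataset, None, task=task)
    accs = [
        pairwise_decode(data, pair, spec, variable="category",
                        cv="leave_one_run_out")
        for pair in category_pairs(data.categories)
    ]
    return float(np.mean(accs))


def task_decoding(dataset: PatternDataset, spec: DecodingSpec) -> float:
    """Mean task decoding within category (leave-one-adjacent-run-pair-out)."""
    tasks = dataset.tasks
    if len(tasks) != 2:
        raise DecodingError(f"need both tasks present, got {tasks}")
    accs = []
    for category in dataset.categories:
        sub = subset(dataset, None, category=category)
        accs.append(
            pairwise_decode(sub, tuple(tasks), spec, variable="task",
                            cv="leave_adjacent_run_pair_out")
        )
    return float(np.mean(accs))


# ----------------------------------------------------------------------
# Cross-context decoding
# ----------------------------------------------------------------------
def _cross_one_direction(
    data: PatternDataset,
    pair: tuple[str, str],
    decode_variable: str,
    generalization_variable: str,
    train_value: str,
    test_value: str,
    spec: DecodingSpec,
    rng: np.random.Generator,
) -> float:
    train_set = subset(data, None, **{generalization_variable: train_value,
                                      decode_variable: list(pair)})
    test_set = subset(data, None, **{generalization_variable: test_value,
                                     decode_variable: list(pair)})
    ytr = train_set.labels[decode_variable].to_numpy()
    yte = test_set.labels[decode_variable].to_numpy()
    if train_value == test_value:
        # degenerate consistency case: identical contexts reduce to ordinary
        # within-context cross-validated decoding
        folds = (adjacent_pair_folds(train_set.labels) if decode_variable == "task"
                 else run_folds(train_set.labels))
        acc, _, _ = binary_cv_accuracy(train_set.betas, ytr, folds, spec, rng=rng)
        return acc
    if spec.cross_train_full:
        clf = _fit(train_set.betas, ytr, spec.regularization_c)
        return float((_predict(clf, test_set.betas, rng) == yte).mean())
    # rotate all-but-one-fold training so training-set size matches the
    # within-context analysis; test always on the full test context
    if decode_variable == "task":
        folds = adjacent_pair_folds(train_set.labels)
    else:
        folds = run_folds(train_set.labels)
    accs = []
    for fold in np.unique(folds):
        keep = folds != fold
        if np.unique(ytr[keep]).size < 2:
            raise DecodingError(f"cross-decoding training fold {fold} lacks a class")
        clf = _fit(train_set.betas[keep], ytr[keep], spec.regularization_c)
        accs.append((_predict(clf, test_set.betas, rng) == yte).mean())
    return float(np.mean(accs))


def cross_decode(
    dataset: PatternDataset,
    train_value: str,
    test_value: str,
    decode_variable: str,
    generalization_variable: str,
    spec: DecodingSpec,
) -> float:
    """Train in one context, test in the other; mean over both directions.

    For category decoding across tasks: ``decode_variable="category"``,
    ``generalization_variable="task"``, and the accuracy is averaged over all
    category pairs.  For task decoding across categories the roles swap and
    (train_value, test_value) name two categories.
    """
    if decode_variable == generalization_variable:
        raise DecodingError("decode and generalization variables must differ")
    data = _maybe_normalize(dataset, spec)
    rng = spec.tie_rng()
    if decode_variable == "category":
        pairs = category_pairs(data.categories)
    else:
        pairs = [tuple(data.tasks)]
    accs = []
    for pair in pairs:
        fwd = _cross_one_direction(data, pair, decode_variable,
                                   generalization_variable, train_value,
                                   test_value, spec, rng)
        rev = _cross_one_direction(data, pair, decode_variable,
                                   generalization_variable, test_value,
                                   train_value, spec, rng)
        accs.append(0.5 * (fwd + rev))
    return float(np.mean(accs))


def category_cross_decoding(dataset: PatternDataset, spec: DecodingSpec) -> float:
    """Category decoding trained in one task, tested in the other (both ways)."""
    tasks = dataset.tasks
    return cross_decode(dataset, tasks[0], tasks[1], "category", "task", spec)


def task_cross_decoding(dataset: PatternDataset, spec: DecodingSpec) -> float:
    """Task decoding trained on one category, tested on another, averaged
    over all ordered category pairs."""
    data = _maybe_normalize(dataset, spec)
    rng = spec.tie_rng()
    tasks = tuple(data.tasks)
    accs = []
    for cat_a, cat_b in category_pairs(data.categories):
        fwd = _cross_one_direction(data, tasks, "task", "category",
                                   cat_a, cat_b, spec, rng)
        rev = _cross_one_direction(data, tasks, "task", "category",
                                   cat_b, cat_a, spec, rng)
        accs.append(0.5 * (fwd + rev))
    return float(np.mean(accs))


# ----------------------------------------------------------------------
# Full 16-condition pairwise decoding (for RDM construction)
# ----------------------------------------------------------------------
def condition_pair_id(cond_a: tuple[str, str], cond_b: tuple[str, str]) -> str:
    a, b = sorted([cond_a, cond_b])
    return f"{a[0]}|{a[1]}--{b[0]}|{b[1]}"


def condition_pairwise_decoding(
    dataset: PatternDataset, spec: DecodingSpec
) -> dict[str, float]:
    """Decoding accuracy for every pair of (category, task) conditions.

    Same-task pairs use leave-one-run-out CV; pairs spanning tasks use
    leave-one-adjacent-run-pair-out.  With 8 categories and 2 tasks this is
    the full 120-pair set behind the 16-condition RDM.
    """
    data = _maybe_normalize(dataset, spec)
    conditions = sorted(
        set(zip(data.labels["category"], data.labels["task"]))
    )
    results: dict[str, float] = {}
    for cond_a, cond_b in itertools.combinations(conditions, 2):
        mask = [
            (c, t) in (cond_a, cond_b)
            for c, t in zip(data.labels["category"], data.labels["task"])
        ]
        sub = subset(data, lambda lab: np.asarray(mask))
        y = np.array([
            "a" if (c, t) == cond_a else "b"
            for c, t in zip(sub.labels["category"], sub.labels["task"])
        ])
        if cond_a[1] == cond_b[1]:
            folds = run_folds(sub.labels)
        else:
            folds = adjacent_pair_folds(sub.labels)
        acc, _, _ = binary_cv_accuracy(sub.betas, y, folds, spec)
        results[condition_pair_id(cond_a, cond_b)] = acc
    return results
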