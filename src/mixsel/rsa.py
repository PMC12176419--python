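"""Representational geometry: RDMs, MDS, and reliability-corrected task effects.

The representational dissimilarity matrix (RDM) here is built from pairwise
decoding accuracies over the 16 category-by-task conditions.  To dissociate a
*rotation/shift* of the category geometry across tasks (content preserved)
from a *reshaping* (pairwise distances altered, content changed), each
participant's within-task category similarity vector is correlated with the
other participants' average vector for the same vs the opposite task; the
squared ratio of between- to mean-within-task correlation estimates the
proportion of reliable RDM variance preserved across tasks (1 = geometry
unchanged; < 1 = content change).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class GeometryError(ValueError):
    """Raised on invalid RDM or geometry-analysis inputs."""


@dataclass
class RDM:
    """Symmetric condition-by-condition dissimilarity structure."""

    condition_labels: list
    dissimilarity: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dissimilarity, dtype=float)
        n = len(self.condition_labels)
        if d.shape != (n, n):
            raise GeometryError(f"matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise GeometryError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise GeometryError("diagonal must be zero")
        self.dissimilarity = d

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle entries in canonical (row-major) pair order."""
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.dissimilarity[iu]

    def to_frame(self) -> pd.DataFrame:
        labels = ["|".join(c) if isinstance(c, tuple) else str(c)
                  for c in self.condition_labels]
        return pd.DataFrame(self.dissimilarity, index=labels, columns=labels)


@dataclass
class GeometryResult:
    """Reliability-corrected between-task geometry comparison.

    ``within_task_correlation`` is the leave-one-participant-out RDM
    reliability (noise ceiling); ``variance_explained`` is per participant
    (between / group-mean within) squared.
    """

    within_task_correlation: np.ndarray
    between_task_correlation: np.ndarray
    variance_explained: np.ndarray
    mean_within: float

    @property
    def mean_variance_explained(self) -> float:
        return float(np.mean(self.variance_explained))


# ----------------------------------------------------------------------
# First-order RDMs
# ----------------------------------------------------------------------
def condition_grid(categories, tasks) -> list[tuple[str, str]]:
    return [(c, t) for c in sorted(categories) for t in sorted(tasks)]


def build_condition_rdm(accuracy_table, participant: str, region: str,
                        analysis_id: str = "condition_pair") -> RDM:
    """Assemble the 16-condition RDM from pairwise decoding accuracies.

    Every off-diagonal cell (120 pairs for 8 categories x 2 tasks) must be
    present in the accuracy table; a missing pair raises an error naming it.
    Accuracy itself is the dissimilarity (chance .5 = indistinguishable).
    """
    from .decoding import condition_pair_id

    frame = accuracy_table.to_frame()
    rows = frame[
        (frame["participant"] == participant)
        & (frame["region"] == region)
        & (frame["analysis"] == analysis_id)
    ]
    lookup = dict(zip(rows["pair"], rows["accuracy"]))
    conds = sorted({
        tuple(part.split("|")) for key in lookup for part in key.split("--")
    })
    if not conds:
        raise GeometryError(
            f"no condition-pair accuracies for ({participant}, {region})"
        )
    n = len(conds)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        key = condition_pair_id(conds[i], conds[j])
        if key not in lookup:
            raise GeometryError(f"missing condition pair {key}")
        d[i, j] = d[j, i] = lookup[key]
    return RDM(conds, d)


def rdm_to_mds_distances(rdm: RDM) -> RDM:
    """Chance-reference the accuracies for embedding: d' = max(d - .5, 0)."""
    return RDM(list(rdm.condition_labels),
               np.maximum(rdm.dissimilarity - 0.5, 0.0) * _offdiag_mask(rdm))


def _offdiag_mask(rdm: RDM) -> np.ndarray:
    return 1.0 - np.eye(rdm.n_conditions)


def mds_embed(rdm: RDM, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of an RDM.

    Double-centers the squared distances and takes the top eigenvectors;
    exact for Euclidean inputs, deterministic, and canonicalized so that each
    returned axis has its largest-magnitude coordinate positive.  An all-zero
    RDM embeds every condition at the origin (with a warning).
    """
    d = rdm.dissimilarity
    if np.allclose(d, 0.0):
        warnings.warn("degenerate all-zero RDM: all conditions embed at origin")
        return np.zeros((rdm.n_conditions, n_dims))
    n = rdm.n_conditions
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_dims]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def category_similarity_vector(accuracy_table, participant: str, region: str,
                               task: str,
                               analysis_id: str = "condition_pair") -> np.ndarray:
    """The 28 within-task pairwise category accuracies in canonical pair order.

    No chance subtraction or clipping: the raw accuracies carry the geometry
    for the correlation analyses (subtract-and-clip exists only to produce
    valid MDS distances).
    """
    from .decoding import condition_pair_id

    frame = accuracy_table.to_frame()
    rows = frame[
        (frame["participant"] == participant)
        & (frame["region"] == region)
        & (frame["analysis"] == analysis_id)
    ]
    lookup = dict(zip(rows["pair"], rows["accuracy"]))
    categories = sorted({
        part.split("|")[0] for key in lookup for part in key.split("--")
    })
    values = []
    for a, b in itertools.combinations(categories, 2):
        key = condition_pair_id((a, task), (b, task))
        if key not in lookup:
            raise GeometryError(f"missing condition pair {key}")
        values.append(lookup[key])
    return np.array(values)


# ----------------------------------------------------------------------
# Second-order structure
# ----------------------------------------------------------------------
def second_order_rdm(vectors: dict) -> RDM:
    """Correlation-distance RDM (1 - Pearson r) over category similarity
    vectors keyed by e.g. (region, task)."""
    keys = sorted(vectors)
    if len(keys) < 2:
        raise GeometryError("need at least 2 similarity vectors")
    mats = [np.asarray(vectors[k], dtype=float) for k in keys]
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise GeometryError("similarity vectors differ in length")
    for k, m in zip(keys, mats):
        if m.std() == 0:
            raise GeometryError(f"zero-variance similarity vector for {k}")
    n = len(keys)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        r = stats.pearsonr(mats[i], mats[j])[0]
        d[i, j] = d[j, i] = 1.0 - r
    return RDM(keys, d)


# ----------------------------------------------------------------------
# Reliability-corrected between-task geometry change
# ----------------------------------------------------------------------
def geometry_variance_explained(per_participant_vectors: dict) -> GeometryResult:
    """Leave-one-participant-out within/between-task RDM correlations.

    ``per_participant_vectors`` maps participant id -> {task: 28-vector}.
    Per participant: *within* is the mean correlation of their own task-t
    vector with the remaining participants' average task-t vector (over both
    tasks); *between* crosses the tasks.  Variance explained is
    (between / group-mean within) squared — negative ratios are squared as
    is (sign retained in ``between_task_correlation``), since the one-tailed
    test direction downstream is unaffected.
    """
    pids = sorted(per_participant_vectors)
    if len(pids) < 3:
        raise GeometryError("need >= 3 participants")
    tasks = sorted(next(iter(per_participant_vectors.values())))
    if len(tasks) != 2:
        raise GeometryError(f"need exactly 2 tasks, got {tasks}")
    stacked = {
        t: np.stack([np.asarray(per_participant_vectors[p][t], dtype=float)
                     for p in pids])
        for t in tasks
    }
    for t, m in stacked.items():
        if np.any(m.std(axis=1) == 0):
            raise GeometryError(f"zero-variance similarity vector in task {t}")
    n = len(pids)
    within = np.empty(n)
    between = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        ref = {t: stacked[t][others].mean(axis=0) for t in tasks}
        w = [stats.pearsonr(stacked[t][i], ref[t])[0] for t in tasks]
        b = [stats.pearsonr(stacked[tasks[0]][i], ref[tasks[1]])[0],
             stats.pearsonr(stacked[tasks[1]][i], ref[tasks[0]])[0]]
        within[i] = np.mean(w)
        between[i] = np.mean(b)
    mean_within = float(np.mean(within))
    if mean_within == 0:
        raise GeometryError("zero mean within-task correlation: ratio undefined")
    ve = (between / mean_within) ** 2
    return GeometryResult(within, between, ve, mean_within)


def within_participant_between_task_correlation(vectors_by_task: dict) -> float:
    """A participant's own between-task category-RDM correlation (no group
    reference), the within-participant geometry-change metric."""
    tasks = sorted(vectors_by_task)
    a = np.asarray(vectors_by_task[tasks[0]], dtype=float)
    b = np.asarray(vectors_by_task[tasks[1]], dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise GeometryError("zero-variance similarity vector")
    return float(stats.pearsonr(a, b)[0])


def pdd_geometry_correlation(pdd_accuracy, between_task_rdm_correlation):
    """Across participants: Pearson r (and two-tailed p) between interaction
    strength (pattern-difference accuracy) and between-task RDM correlation.

    A negative r means stronger interactions go with larger representational
    content changes between tasks.
    """
    a = np.asarray(pdd_accuracy, dtype=float)
    b = np.asarray(between_task_rdm_correlation, dtype=float)
    if a.size != b.size or a.size < 3:
        raise GeometryError("need >= 3 paired participant values")
    if a.std() == 0 or b.std() == 0:
        raise GeometryError("zero variance in one of the inputs")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
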