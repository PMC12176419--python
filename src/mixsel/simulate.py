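"""Synthetic factorial (category x task) voxel-pattern cohorts with known tuning.

The generator emulates the block design of a two-task fMRI experiment: each
participant performs ``2 * n_runs_per_task`` runs, tasks alternating run by run
(with the two middle runs sharing a task so neither task occurs systematically
earlier), and each run contains exactly one analyzed block per category.

Every block pattern is

    baseline + category template + task template (+ interaction) + noise

with templates drawn once per cohort from seeded Gaussians and carried into
each participant's voxel space by a participant-specific rotation (so all
participants share the same representational geometry, as human cohorts
roughly do, while voxel-level tuning is idiosyncratic).

Geometry regimes (``geometry_mode``):

``additive``
    No interaction: the task adds a common pattern shift, category difference
    vectors are identical across tasks.
``oblique``
    Still additive, but the task shift has a component along one category
    difference axis larger than that pair's half-separation, so a max-margin
    boundary trained in one task misclassifies one class of the other task
    even though no interaction is present.
``rotation``
    Task 2 category templates are an orthogonal transform of task 1 templates:
    an interaction is present (difference vectors change across tasks) but all
    pairwise distances — the representational content — are preserved.
``reshape``
    Task 2 templates are task 1 templates with category-dependent rescaling:
    the interaction alters the pairwise distance structure itself.

``interaction_gain`` dials the rotation angle / rescaling spread and must be 0
in the additive and oblique regimes.

When ``normalize_additivity_domain="znormed"`` the additive structure is made
exact in the *analyzed* (per-block z-scored) space: all templates are centered
across voxels, category templates share a common norm, and task templates are
orthogonal to the category span with equal norms.  Per-block z-scoring is
equivariant under rotations of the zero-mean subspace, so under this
construction the expected difference vectors are exactly context-independent
and pattern-difference decoding has no systematic signal to find.  With
``"raw"`` the additive structure holds in raw units instead and z-scoring can
introduce a small condition-dependent rescaling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import PatternDataset, write_dataset, read_dataset

DEFAULT_TASKS = ("Oddball", "Oneback")
GEOMETRY_MODES = ("additive", "rotation", "reshape", "oblique")


@dataclass
class SimulationConfig:
    """Full generative recipe for a synthetic cohort.

    ``category_gain`` / ``task_gain`` set the per-voxel RMS amplitude of the
    category and task templates relative to unit-SD noise; the defaults put
    within-task pairwise category decoding in the 0.7-0.8 range typical of
    object-selective cortex at 100 voxels.
    """

    n_participants: int = 13
    n_runs_per_task: int = 10
    n_categories: int = 8
    n_tasks: int = 2
    n_voxels: int = 100
    category_gain: float = 0.22
    task_gain: float = 0.11
    geometry_dim: int = 2
    baseline_gain: float = 0.5
    interaction_gain: float = 0.0
    geometry_mode: str = "additive"
    noise_sd: float = 1.0
    normalize_additivity_domain: str = "znormed"
    seed: int = 0
    tasks: tuple[str, str] = DEFAULT_TASKS
    oblique_shift_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.geometry_mode not in GEOMETRY_MODES:
            raise ValueError(f"unknown geometry_mode {self.geometry_mode!r}")
        if self.normalize_additivity_domain not in ("raw", "znormed"):
            raise ValueError(
                f"unknown normalize_additivity_domain "
                f"{self.normalize_additivity_domain!r}"
            )
        if self.n_tasks != 2:
            raise ValueError("exactly 2 tasks are supported")
        if self.n_categories < 2 or self.n_voxels < 2 or self.n_runs_per_task < 2:
            raise ValueError("need >= 2 categories, >= 2 voxels, >= 2 runs per task")
        if self.n_participants < 1:
            raise ValueError("need >= 1 participant")
        for name in ("category_gain", "task_gain", "interaction_gain", "noise_sd",
                     "baseline_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.geometry_mode in ("additive", "oblique") and self.interaction_gain != 0:
            raise ValueError(
                f"interaction_gain must be 0 in {self.geometry_mode!r} mode "
                "(no interaction term exists there)"
            )
        if (self.normalize_additivity_domain == "znormed"
                and self.n_voxels < self.n_categories + 4):
            raise ValueError(
                "znormed additivity needs n_voxels >= n_categories + 4 for the "
                "orthogonalized template construction"
            )

    @property
    def category_labels(self) -> list[str]:
        return [f"cat{i + 1:02d}" for i in range(self.n_categories)]


@dataclass
class GroundTruth:
    """Noiseless condition means and distance structure of a simulated cohort.

    ``category_templates_per_task`` has shape (n_tasks, n_categories,
    n_voxels) in the shared (pre-participant-rotation) voxel space;
    ``pairwise_distance_table`` holds the Euclidean distances among category
    templates within each task.
    """

    category_templates_per_task: np.ndarray
    pairwise_distance_table: dict[str, np.ndarray]
    interaction_present: bool
    tasks: tuple[str, str] = DEFAULT_TASKS
    category_labels: list[str] = field(default_factory=list)

    def distance(self, task: str, i: int, j: int) -> float:
        return float(self.pairwise_distance_table[task][i, j])


def run_schedule(n_runs_per_task: int, tasks=DEFAULT_TASKS) -> list[str]:
    """Task performed in each of the 2n runs.

    Tasks alternate run by run; for even n the two middle runs share a task
    (so that, averaged over the session, neither task occurs earlier than the
    other), and every adjacent run pair (2i-1, 2i) contains one run of each
    task.  For odd n plain alternation already balances the halves.
    """
    n_total = 2 * n_runs_per_task
    if n_runs_per_task % 2 == 0:
        first = [tasks[i % 2] for i in range(n_runs_per_task)]
        second_start = first[-1]
        start_idx = tasks.index(second_start)
        second = [tasks[(start_idx + i) % 2] for i in range(n_runs_per_task)]
        schedule = first + second
    else:
        schedule = [tasks[i % 2] for i in range(n_total)]
    assert schedule.count(tasks[0]) == schedule.count(tasks[1])
    return schedule


def _centered(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=-1, keepdims=True)


def _project_out(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove from v its projection onto the row-space of `basis`."""
    if basis.size == 0:
        return v
    q, _ = np.linalg.qr(basis.T)
    return v - (v @ q) @ q.T


def _hyperplane_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n x (n-1)) of the zero-mean subspace of R^n."""
    ones = np.ones((n, 1)) / np.sqrt(n)
    full = np.linalg.qr(np.hstack([ones, np.eye(n)[:, : n - 1]]))[0]
    return full[:, 1:]


def _random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _build_templates(config: SimulationConfig, rng: np.random.Generator):
    """Group-level baseline, per-task category templates, task templates."""
    n_vox, n_cat = config.n_voxels, config.n_categories
    scale = np.sqrt(n_vox)
    znormed = config.normalize_additivity_domain == "znormed"

    # category geometry lives in a low-dimensional latent subspace: random
    # unit directions in `geometry_dim` dimensions have strongly varied
    # pairwise angles, giving a structured distance pattern shared by all
    # participants (full-rank Gaussians would make the RDM nearly constant)
    latent = rng.standard_normal((n_cat, config.geometry_dim))
    latent /= np.linalg.norm(latent, axis=1, keepdims=True)
    embed = _centered(rng.standard_normal((n_vox, config.geometry_dim)).T).T
    embed = np.linalg.qr(embed)[0]
    cats = latent @ embed.T
    task_vecs = rng.standard_normal((2, n_vox))
    base = rng.standard_normal(n_vox)

    cats = cats * (config.category_gain * scale)
    if znormed:
        task_vecs = _project_out(_centered(task_vecs), cats)
        task_vecs /= np.linalg.norm(task_vecs, axis=1, keepdims=True)
        task_vecs *= config.task_gain * scale
        base = _project_out(_centered(base)[None, :], np.vstack([cats, task_vecs]))[0]
        if np.linalg.norm(base) > 0:
            base = base / np.linalg.norm(base) * (config.baseline_gain * scale)
    else:
        task_vecs = task_vecs * config.task_gain
        base = base * config.baseline_gain

    cats_by_task = np.stack([cats, cats.copy()])

    if config.geometry_mode == "rotation" and config.interaction_gain > 0:
        # tilt each latent axis by `interaction_gain` radians into a fresh
        # orthogonal voxel dimension: an exact isometry of the category
        # geometry (all pairwise distances preserved) that still changes
        # every category's difference vectors across tasks
        fresh = rng.standard_normal((n_vox, config.geometry_dim))
        fresh = _centered(fresh.T).T
        fresh = fresh - embed @ (embed.T @ fresh)
        fresh = np.linalg.qr(fresh)[0]
        gamma = config.interaction_gain
        rotated_basis = np.cos(gamma) * embed + np.sin(gamma) * fresh
        cats_by_task[1] = (latent @ rotated_basis.T) * (config.category_gain * scale)
    elif config.geometry_mode == "reshape" and config.interaction_gain > 0:
        scales = np.exp(config.interaction_gain * rng.standard_normal(n_cat))
        cats_by_task[1] = cats * scales[:, None]
    elif config.geometry_mode == "oblique":
        d = cats[0] - cats[1]
        sep = np.linalg.norm(d)
        shift = config.oblique_shift_factor * 0.5 * sep * (d / sep)
        task_vecs[1] = task_vecs[0] + shift

    return base, cats_by_task, task_vecs


def _ground_truth(config: SimulationConfig, cats_by_task: np.ndarray) -> GroundTruth:
    tables = {}
    for k, task in enumerate(config.tasks):
        t = cats_by_task[k]
        diff = t[:, None, :] - t[None, :, :]
        tables[task] = np.linalg.norm(diff, axis=-1)
    interaction = (
        config.geometry_mode in ("rotation", "reshape") and config.interaction_gain > 0
    )
    return GroundTruth(
        category_templates_per_task=cats_by_task.copy(),
        pairwise_distance_table=tables,
        interaction_present=interaction,
        tasks=tuple(config.tasks),
        category_labels=config.category_labels,
    )


def generate_dataset(config: SimulationConfig) -> tuple[list[PatternDataset], GroundTruth]:
    """Simulate one cohort; returns one :class:`PatternDataset` per participant.

    Identical config (including seed) gives a bit-identical cohort.
    """
    root = np.random.SeedSequence(config.seed)
    template_ss, *participant_ss = root.spawn(1 + config.n_participants)
    rng = np.random.default_rng(template_ss)
    base, cats_by_task, task_vecs = _build_templates(config, rng)
    truth = _ground_truth(config, cats_by_task)

    schedule = run_schedule(config.n_runs_per_task, config.tasks)
    categories = config.category_labels
    task_index = {t: k for k, t in enumerate(config.tasks)}

    datasets = []
    for p, ss in enumerate(participant_ss):
        prng = np.random.default_rng(ss)
        # participant-specific voxel rotation within the zero-mean subspace,
        # plus restoration of the group mean component: preserves geometry
        basis = _hyperplane_basis(config.n_voxels)
        rot = basis @ _random_rotation(config.n_voxels - 1, prng) @ basis.T
        mean_part = np.eye(config.n_voxels) - basis @ basis.T
        mix = rot + mean_part

        p_base = mix @ base
        p_cats = np.einsum("vw,ktw->ktv", mix, cats_by_task.transpose(0, 1, 2))
        p_tasks = task_vecs @ mix.T

        rows = []
        betas = []
        for run_idx, task in enumerate(schedule, start=1):
            order = prng.permutation(config.n_categories)
            k = task_index[task]
            for pos, cat_idx in enumerate(order, start=1):
                mean = p_base + p_cats[k, cat_idx] + p_tasks[k]
                noise = prng.standard_normal(config.n_voxels) * config.noise_sd
                betas.append(mean + noise)
                rows.append(
                    dict(run=run_idx, task=task, category=categories[cat_idx],
                         block_position=pos)
                )
        labels = pd.DataFrame(rows)
        datasets.append(
            PatternDataset(f"sub{p + 1:02d}", "SIM", np.array(betas), labels)
        )
    return datasets, truth


# ----------------------------------------------------------------------
# Deterministic two-signal-dimension toy geometries
# ----------------------------------------------------------------------
def fig2c_toy_fixtures(
    n_runs_per_task: int = 16,
    n_voxels: int = 12,
    noise_sd: float = 0.05,
    seed: int = 2023,
) -> dict[str, PatternDataset]:
    """Four toy geometries dissociating cross-decoding from interaction effects.

    Two categories x two tasks, with condition means laid out in a 2-D signal
    plane (embedded in ``n_voxels`` dimensions; the decoy dimensions carry
    zero mean).  Analyze these with per-block normalization *disabled* —
    z-scoring a 2-informative-dimension pattern destroys the constructed
    geometry.

    ``additive_orthogonal``
        Rectangle: cross-decoding generalizes, no interaction.
    ``oblique_parallelogram``
        The task shifts the pair 1.5 separations along the category axis:
        cross-decoding fails although no interaction is present.
    ``interaction_generalizing``
        Task 2 doubles the category separation: interaction present, yet
        cross-decoding still succeeds.
    ``interaction_reversed``
        Task 2 reverses the category difference vector: interaction present
        and cross-decoding is fully inverted (below chance).
    """
    layouts = {
        "additive_orthogonal": {
            ("A", 0): (0.0, 0.0), ("B", 0): (1.0, 0.0),
            ("A", 1): (0.0, 1.0), ("B", 1): (1.0, 1.0),
        },
        "oblique_parallelogram": {
            ("A", 0): (0.0, 0.0), ("B", 0): (1.0, 0.0),
            ("A", 1): (1.5, 0.5), ("B", 1): (2.5, 0.5),
        },
        "interaction_generalizing": {
            # task 2 doubles the separation symmetrically about the task-1
            # midpoint, so the trained boundary still generalizes
            ("A", 0): (0.0, 0.0), ("B", 0): (1.0, 0.0),
            ("A", 1): (-0.5, 1.0), ("B", 1): (1.5, 1.0),
        },
        "interaction_reversed": {
            ("A", 0): (0.0, 0.0), ("B", 0): (1.0, 0.0),
            ("A", 1): (1.0, 1.0), ("B", 1): (0.0, 1.0),
        },
    }
    schedule = run_schedule(n_runs_per_task)
    out = {}
    for name, layout in sorted(layouts.items()):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, abs(hash_name(name))])
        )
        rows, betas = [], []
        for run_idx, task in enumerate(schedule, start=1):
            k = DEFAULT_TASKS.index(task)
            for pos, cat in enumerate(("A", "B"), start=1):
                mean = np.zeros(n_voxels)
                mean[0], mean[1] = layout[(cat, k)]
                betas.append(mean + rng.standard_normal(n_voxels) * noise_sd)
                rows.append(dict(run=run_idx, task=task, category=cat,
                                 block_position=pos))
        out[name] = PatternDataset(
            "toy", name, np.array(betas), pd.DataFrame(rows)
        )
    return out


def hash_name(name: str) -> int:
    """Stable small integer from a string (used to derive named substreams)."""
    import zlib

    return zlib.crc32(name.encode()) % (2**31)


# ----------------------------------------------------------------------
# Fixture I/O
# ----------------------------------------------------------------------
def write_fixture(dataset: PatternDataset, ground_truth: GroundTruth | None,
                  directory) -> dict[str, str]:
    """Write a dataset (+ optional ground truth) into `directory`.

    Files: ``<participant>_<region>_labels.csv``, ``..._betas.h5`` and, when
    ground truth is given, ``ground_truth.json``.  Round-trips bit-exactly
    through :func:`mixsel.datasets.read_dataset`.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"directory does not exist: {directory}")
    stem = f"{dataset.participant_id}_{dataset.region_id}"
    label_path = os.path.join(directory, f"{stem}_labels.csv")
    array_path = os.path.join(directory, f"{stem}_betas.h5")
    write_dataset(dataset, label_path, array_path)
    paths = {"labels": label_path, "betas": array_path}
    if ground_truth is not None:
        gt_path = os.path.join(directory, "ground_truth.json")
        payload = {
            "category_templates_per_task":
                ground_truth.category_templates_per_task.tolist(),
            "pairwise_distance_table":
                {t: m.tolist() for t, m in ground_truth.pairwise_distance_table.items()},
            "interaction_present": ground_truth.interaction_present,
            "tasks": list(ground_truth.tasks),
            "category_labels": list(ground_truth.category_labels),
        }
        with open(gt_path, "w") as handle:
            json.dump(payload, handle)
        paths["ground_truth"] = gt_path
    return paths


def read_fixture(directory, participant_id: str, region_id: str) -> PatternDataset:
    stem = f"{participant_id}_{region_id}"
    return read_dataset(
        os.path.join(directory, f"{stem}_labels.csv"),
        os.path.join(directory, f"{stem}_betas.h5"),
    )
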