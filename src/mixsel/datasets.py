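"""Block-wise multivoxel pattern datasets: container, validation, I/O, normalization.

The unit of analysis is a *block pattern*: the vector of per-voxel response
estimates ("betas") for one stimulus block.  A :class:`PatternDataset` holds all
block patterns for one participant in one region of interest, together with the
block labels (run, task, category, within-run position) that every downstream
decoding analysis keys on.

Before any decoding, patterns are z-scored across voxels within each block
(:func:`znormalize_blocks`), which removes per-block response-amplitude
differences between stimulus conditions, blocks and regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

LABEL_COLUMNS = ["participant", "region", "run", "task", "category", "block_position"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class PatternDataset:
    """Labeled block-wise voxel patterns for one participant and one region.

    Parameters
    ----------
    participant_id, region_id:
        Identifiers carried through every result table.
    betas:
        Array of shape ``(n_blocks, n_voxels)``, arbitrary real units.
    labels:
        One record per block with columns ``run`` (int >= 1), ``task`` (one of
        two string codes), ``category`` (string code) and ``block_position``
        (int, position of the block within its run).

    Invariants (checked on construction): every run carries exactly one task,
    and no (run, category) combination repeats within a run.
    """

    participant_id: str
    region_id: str
    betas: np.ndarray
    labels: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2:
            raise DatasetError("betas must be a 2-D (n_blocks, n_voxels) array")
        self.labels = self.labels.reset_index(drop=True)
        if self.validate:
            self._check()

    # ------------------------------------------------------------------
    def _check(self) -> None:
        required = {"run", "task", "category", "block_position"}
        missing = required - set(self.labels.columns)
        if missing:
            raise DatasetError(f"label columns missing: {sorted(missing)}")
        if len(self.labels) != self.betas.shape[0]:
            raise DatasetError(
                f"label rows ({len(self.labels)}) != beta rows ({self.betas.shape[0]})"
            )
        if self.labels[["run", "task", "category"]].isna().any().any():
            raise DatasetError("missing labels are not allowed")
        if not pd.api.types.is_integer_dtype(self.labels["run"]):
            raise DatasetError("run must be integer-typed")
        for col in ("task", "category"):
            if not all(isinstance(v, str) for v in self.labels[col]):
                raise DatasetError(
                    f"{col} labels must be strings (integer codes are rejected "
                    "to prevent silent misalignment)"
                )
        tasks_per_run = self.labels.groupby("run")["task"].nunique()
        bad = tasks_per_run[tasks_per_run > 1]
        if len(bad):
            raise DatasetError(f"runs with more than one task: {list(bad.index)}")
        dup = self.labels.duplicated(subset=["run", "category"])
        if dup.any():
            row = self.labels[dup].iloc[0]
            raise DatasetError(
                f"duplicate category {row['category']!r} in run {row['run']}"
            )

    # ------------------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    @property
    def tasks(self) -> list[str]:
        return sorted(self.labels["task"].unique())

    @property
    def categories(self) -> list[str]:
        return sorted(self.labels["category"].unique())

    @property
    def runs(self) -> list[int]:
        return sorted(self.labels["run"].unique())

    def run_task_map(self) -> dict[int, str]:
        """Task performed in each run (each run carries exactly one task)."""
        return dict(self.labels.groupby("run")["task"].first())


def subset(dataset: PatternDataset, predicate, **conditions) -> PatternDataset:
    """Select blocks by a label predicate or by keyword equality conditions.

    ``predicate`` is a callable mapping the label frame to a boolean mask, or
    ``None`` when only keyword conditions are given (e.g. ``task="Oddball"``;
    a list/tuple value selects membership).
    """
    mask = np.ones(dataset.n_blocks, dtype=bool)
    if predicate is not None:
        mask &= np.asarray(predicate(dataset.labels), dtype=bool)
    for col, value in conditions.items():
        if col not in dataset.labels.columns:
            raise DatasetError(f"unknown label column {col!r}")
        if isinstance(value, (list, tuple, set, frozenset)):
            mask &= dataset.labels[col].isin(list(value)).to_numpy()
        else:
            mask &= (dataset.labels[col] == value).to_numpy()
    if not mask.any():
        raise DatasetError(
            f"selection is empty (predicate={predicate!r}, conditions={conditions!r})"
        )
    return PatternDataset(
        dataset.participant_id,
        dataset.region_id,
        dataset.betas[mask],
        dataset.labels.loc[mask].reset_index(drop=True),
        validate=False,
    )


def znormalize_blocks(dataset: PatternDataset) -> PatternDataset:
    """Z-score each block across voxels (mean 0, sample SD 1, divisor n-1).

    Removes per-block additive offsets and multiplicative gains, so response
    amplitude differences between conditions cannot drive decoding.  The
    divisor (n-1 vs n) is a uniform rescaling and cannot change max-margin
    classifier decisions.

    Raises
    ------
    DatasetError
        If any block has zero voxel variance (identifies the block).
    """
    betas = dataset.betas
    if betas.shape[1] < 2:
        raise DatasetError("z-normalization needs at least 2 voxels")
    mean = betas.mean(axis=1, keepdims=True)
    sd = betas.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise DatasetError(f"zero-variance block(s) at row index {zero.tolist()}")
    return replace(dataset, betas=(betas - mean) / sd, validate=False)


# ----------------------------------------------------------------------
# Sector maps
# ----------------------------------------------------------------------
@dataclass
class SectorMap:
    """Grouping of regions into sectors whose statistics are averaged.

    A region may belong to at most one sector; member lists are non-empty
    and ordered.
    """

    sectors: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sector, regions in self.sectors.items():
            if not regions:
                raise DatasetError(f"sector {sector!r} has no regions")
            for region in regions:
                if region in seen:
                    raise DatasetError(
                        f"region {region!r} assigned to both {seen[region]!r} "
                        f"and {sector!r}"
                    )
                seen[region] = sector

    def __getitem__(self, sector: str) -> list[str]:
        return list(self.sectors[sector])

    def items(self):
        return {s: list(r) for s, r in self.sectors.items()}.items()


# ----------------------------------------------------------------------
# I/O: labels as CSV, patterns as HDF5 (dataset "betas")
# ----------------------------------------------------------------------
def write_dataset(dataset: PatternDataset, label_path, array_path) -> None:
    """Write one (participant, region) dataset as a label CSV + HDF5 array pair."""
    for path in (label_path, array_path):
        parent = os.path.dirname(os.path.abspath(path))
        if not os.path.isdir(parent):
            raise FileNotFoundError(f"directory does not exist: {parent}")
    frame = dataset.labels.copy()
    frame.insert(0, "participant", dataset.participant_id)
    frame.insert(1, "region", dataset.region_id)
    frame[LABEL_COLUMNS].to_csv(label_path, index=False)
    with h5py.File(array_path, "w") as handle:
        handle.create_dataset("betas", data=dataset.betas)


def read_dataset(label_path, array_path) -> PatternDataset:
    """Read a dataset written by :func:`write_dataset`; row order must match."""
    frame = pd.read_csv(
        label_path, dtype={"task": str, "category": str, "participant": str, "region": str}
    )
    missing = set(LABEL_COLUMNS) - set(frame.columns)
    if missing:
        raise DatasetError(f"label file missing columns: {sorted(missing)}")
    with h5py.File(array_path, "r") as handle:
        if "betas" not in handle:
            raise DatasetError(f"{array_path}: no 'betas' dataset")
        betas = handle["betas"][()]
    if betas.shape[0] != len(frame):
        raise DatasetError(
            f"label rows ({len(frame)}) != beta rows ({betas.shape[0]}) "
            f"between {label_path} and {array_path}"
        )
    participants = frame["participant"].unique()
    regions = frame["region"].unique()
    if len(participants) != 1 or len(regions) != 1:
        raise DatasetError("one (participant, region) pair per file pair")
    labels = frame[["run", "task", "category", "block_position"]].copy()
    return PatternDataset(str(participants[0]), str(regions[0]), betas, labels)
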