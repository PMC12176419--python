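import numpy as np
import pandas as pd
import pytest

from mixsel import DecodingSpec, PatternDataset
from mixsel.simulate import SimulationConfig, fig2c_toy_fixtures, generate_dataset


@pytest.fixture(scope="session")
def toy_fixtures():
    """The four deterministic two-signal-dimension geometries."""
    return fig2c_toy_fixtures()


@pytest.fixture(scope="session")
def toy_spec():
    """Toy geometries are analyzed without per-block normalization."""
    return DecodingSpec(normalize=False)


@pytest.fixture(scope="session")
def spec():
    return DecodingSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap additive cohort: 3 participants, 4 categories, 4 runs/task."""
    cfg = SimulationConfig(
        n_participants=3, n_categories=4, n_runs_per_task=4, n_voxels=24,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def full_dataset():
    """One participant at the full design (8 categories, 10 runs/task)."""
    cfg = SimulationConfig(n_participants=1, seed=5)
    return generate_dataset(cfg)[0][0]


def make_tiny_dataset(values, runs, tasks, categories, positions=None):
    """Hand-assembled dataset from explicit rows (helper for edge cases)."""
    betas = np.asarray(values, dtype=float)
    labels = pd.DataFrame({
        "run": runs,
        "task": tasks,
        "category": categories,
        "block_position": positions or list(range(1, len(runs) + 1)),
    })
    return PatternDataset("p1", "r1", betas, labels)
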