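"""Shared fixtures: tiny arenas, toy datasets, and a small trained model.

Everything is generated programmatically; heavier artifacts are session
scoped so the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from placegrid import arena as arena_mod
from placegrid.arena import ArenaConfig, build_bag_dataset, place_boxes
from placegrid.experiment import ExperimentSpec, train_variant


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # JIT compile the ray-casting kernel once, outside any timed assertions
    arena_mod.warmup_kernels()


@pytest.fixture(scope="session")
def tiny_config() -> ArenaConfig:
    """10-box arena on a 6x6 grid: fast enough for oracle comparisons."""
    return ArenaConfig(grid_cells=6, n_boxes=10, seed=42)


@pytest.fixture(scope="session")
def tiny_boxes(tiny_config):
    return place_boxes(tiny_config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tiny_boxes):
    return build_bag_dataset(tiny_config, tiny_boxes, v=1, normalize=False)


@pytest.fixture(scope="session")
def small_spec() -> ExperimentSpec:
    """Trainable-in-seconds experiment used by the model-dependent tests."""
    return ExperimentSpec(
        arena=ArenaConfig(grid_cells=10, n_boxes=20, seed=7),
        epochs=25,
        batch_size=1000,
        learning_rate=0.015,
    )


@pytest.fixture(scope="session")
def trained_small_model(small_spec):
    """A lifetime-sparse 5-layer model trained at a 9-sector mask width."""
    weights, dataset, history = train_variant(
        small_spec, "Norm-LT3.33%-LT3.33%-Mask", v=9
    )
    return weights, dataset, history


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
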