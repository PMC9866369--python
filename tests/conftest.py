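"""Shared fixtures: scene configs and the trained end-to-end reference runs.

The expensive full training runs (U-Net and FCRN on the 64x64 counting
task, plus a repeat of the U-Net run for the determinism check) are
session-scoped so every test that needs them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import graincount as gc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


# Study conditions of the scaled-down counting task: 64x64 frames carrying
# 5-15 well-separated grains (centers >= 6 px apart, semi-axes 1.5-3 px),
# dots at least 8 px (= the kernel truncation radius) from every border.
SMALL_SCENE = gc.SceneConfig(
    image_height=64,
    image_width=64,
    count_range=(5, 15),
    grain_axis_range=(1.5, 3.0),
    min_center_margin=8.0,
    min_center_separation=6.0,
    seed=0,
)

KERNEL = gc.KernelSpec(sigma=2.0, truncation_radius=8, normalization="unit_integral")

TRAIN_CONFIG = gc.TrainConfig(
    epochs=30,
    batch_size=8,
    patch_size=64,
    seed=0,
)


@pytest.fixture(scope="session")
def small_scene_config() -> gc.SceneConfig:
    return SMALL_SCENE


@pytest.fixture(scope="session")
def kernel() -> gc.KernelSpec:
    return KERNEL


@pytest.fixture(scope="session")
def counting_task():
    """240 train + 60 test synthetic scenes for the end-to-end runs."""
    scenes = [gc.generate_scene(SMALL_SCENE, SMALL_SCENE.seed + i) for i in range(300)]
    by_id = {s.identifier: s for s in scenes}
    train_ids, test_ids = gc.split_dataset(list(by_id), 0.8, seed=0)
    return [by_id[i] for i in train_ids], [by_id[i] for i in test_ids]


def _train_cell(family: str, train_set, test_set):
    spec = gc.ArchitectureSpec(family=family, base_channels=16)
    network = gc.build_network(spec, seed=TRAIN_CONFIG.seed)
    log = gc.train(network, train_set, KERNEL, TRAIN_CONFIG)
    report = gc.evaluate(
        network, test_set, KERNEL,
        target_scale=TRAIN_CONFIG.target_scale, patch_size=TRAIN_CONFIG.patch_size,
    )
    return log, report


@pytest.fixture(scope="session")
def unet_run(counting_task):
    """Trained U-Net cell: (TrainLog, EvalReport) on the counting task."""
    train_set, test_set = counting_task
    return _train_cell("unet", train_set, test_set)


@pytest.fixture(scope="session")
def unet_run_repeat(counting_task):
    """Second, independent run of the identical U-Net cell (same seeds)."""
    train_set, test_set = counting_task
    return _train_cell("unet", train_set, test_set)


@pytest.fixture(scope="session")
def fcrn_run(counting_task):
    """Trained FCRN cell: (TrainLog, EvalReport) on the counting task."""
    train_set, test_set = counting_task
    return _train_cell("fcrn", train_set, test_set)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
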