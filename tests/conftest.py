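"""Shared fixtures: a small phantom, a 10-case cohort, and trained
checkpoints, all at desk scale (16x32x32 grid, width-8 depth-2 nets)
so the whole suite stays CPU-friendly."""

from pathlib import Path

import numpy as np
import pytest

from arcdose.nets import TrainConfig, train_stage1, train_stage2
from arcdose.phantom import PhantomConfig, generate_cohort, generate_phantom

SMALL_SHAPE = (16, 32, 32)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(shape=SMALL_SHAPE, seed=11)


@pytest.fixture(scope="session")
def phantom_case(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def train_config() -> TrainConfig:
    return TrainConfig(epochs=20, width=8, depth=2, seed=0)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(10, PhantomConfig(shape=SMALL_SHAPE, seed=7), out)
    return out


@pytest.fixture(scope="session")
def stage1_ckpt(cohort_dir, train_config, tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("ckpt") / "stage1.npz"
    train_stage1(cohort_dir, train_config, path)
    return path


@pytest.fixture(scope="session")
def stage2_ckpt(cohort_dir, stage1_ckpt, train_config, tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("ckpt") / "stage2.npz"
    train_stage2(cohort_dir, stage1_ckpt, train_config, path)
    return path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
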