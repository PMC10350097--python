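"""Shared fixtures: small phantoms and a desk-scale trained model.

The trained model is expensive (a few minutes of CPU), so it is built
once per session and shared by every test that exercises end-to-end
behaviour.
"""

from __future__ import annotations

import numpy as np
import pytest

from dwiseg.gradients import b0_normalize
from dwiseg.phantom import PhantomSpec, TractSpec, random_crossing_spec, simulate_dwi
from dwiseg.segmentation import ModelConfig, build_model, train
from dwiseg.subsets import make_training_sampler

# Desk-scale study conditions: 32³ grids, two crossing tracts, 30
# directions + 3 b0 at b=1000, SNR 20 — a miniature of a DTI-style scan.
DESK_GRID = 32
DESK_SNR = 20.0
N_TRAIN, N_VAL, N_TEST = 8, 2, 2


def make_phantom_case(seed: int, snr: float | None = DESK_SNR,
                      grid: int = DESK_GRID):
    """One (b0-normalized DWI, label volume) pair from a random
    two-tract crossing geometry."""
    spec = random_crossing_spec(seed, grid=grid, snr=snr)
    dwi, labels = simulate_dwi(spec)
    return b0_normalize(dwi), labels


@pytest.fixture(scope="session")
def desk_config() -> ModelConfig:
    return ModelConfig(
        patch_shape=(DESK_GRID,) * 3, out_labels=2, depth=2, base_width=8,
        learning_rate=1e-3, epochs=5, iters_per_epoch=60, seed=0,
    )


@pytest.fixture(scope="session")
def phantom_split():
    train_cases = [make_phantom_case(s) for s in range(N_TRAIN)]
    val_cases = [make_phantom_case(100 + s) for s in range(N_VAL)]
    test_cases = [make_phantom_case(200 + s) for s in range(N_TEST)]
    return train_cases, val_cases, test_cases


@pytest.fixture(scope="session")
def trained_model(desk_config, phantom_split):
    """The desk-scale model: depth 2, width 8, 32³ patches, trained with
    6–12 subset augmentation on 8 two-tract phantoms."""
    train_cases, val_cases, _ = phantom_split
    model = build_model(desk_config)
    sampler = make_training_sampler(train_cases[0][0].gtab, 6, 12, rng_seed=7)
    model, log = train(model, train_cases, val_cases, desk_config, sampler)
    assert np.isfinite(log["val_loss"]).all()
    return model


@pytest.fixture
def straight_tube_spec() -> PhantomSpec:
    """Noiseless single straight tube along x, radius 2 voxels."""
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        tracts=[TractSpec(1, ((2.0, 12.0, 12.0), (22.0, 12.0, 12.0)), 2.0)],
        snr=None,
        n_directions=30,
    )
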