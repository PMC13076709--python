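import numpy as np
import pytest

from adcphantom import (
    NominalADCModel,
    PipelineConfig,
    build_phantom_layout,
    default_protocol,
    simulate_dwi_series,
)
from adcphantom.pipeline import run_study


@pytest.fixture(scope="session")
def model():
    return NominalADCModel.default()


@pytest.fixture(scope="session")
def small_protocol():
    # 64 x 64 grid, 3 slices: fast but still resolves every vial
    return default_protocol("ffov", matrix=64, n_slices=3, noise_sigma=4.0)


@pytest.fixture(scope="session")
def ffov_layout():
    return build_phantom_layout("ffov")


@pytest.fixture(scope="session")
def noiseless_stack(ffov_layout, model):
    proto = default_protocol("ffov", matrix=64, n_slices=3, noise_sigma=0.0)
    return simulate_dwi_series(ffov_layout, proto, model, 21.0, seed=0)


@pytest.fixture(scope="session")
def noisy_stack(ffov_layout, small_protocol, model):
    return simulate_dwi_series(ffov_layout, small_protocol, model, 21.0, seed=7)


def scaled_config(seed: int, **overrides) -> PipelineConfig:
    """One-session, three-repeat study on a 96 x 96 x 5 grid (the scaled-down
    acceptance design)."""
    base = dict(
        sequences=("ffov",),
        matrix=96,
        n_slices=5,
        n_repeats=3,
        sessions=(("S1", 21.0),),
        seed=seed,
        output_dir="scratch/unused",
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def scaled_studies():
    """Scaled-down noisy studies for seeds 0..9, shared across acceptance tests."""
    return {seed: run_study(scaled_config(seed), write=False) for seed in range(10)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
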