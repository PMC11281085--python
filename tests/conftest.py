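import numpy as np
import pytest

from phubsense import (
    AccelWindow,
    ModelConfig,
    SyntheticDatasetSpec,
    gen_accel,
    gen_dataset,
    REGIMES,
)


@pytest.fixture(scope="session")
def walking_window() -> AccelWindow:
    samples = gen_accel(REGIMES["walking"], 6.0, 50.0, seed=7)
    return AccelWindow(t_start=0.0, t_end=6.0, samples=samples, rate=50.0)


@pytest.fixture(scope="session")
def static_window() -> AccelWindow:
    samples = gen_accel(REGIMES["static"], 6.0, 50.0, seed=7)
    return AccelWindow(t_start=0.0, t_end=6.0, samples=samples, rate=50.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 18 pairs at a small image side: quick to materialize."""
    return gen_dataset(
        SyntheticDatasetSpec(n_subjects=2, pairs_per_subject=18, image_side=64, seed=11)
    )


@pytest.fixture()
def small_model_config() -> ModelConfig:
    """A 32-px, quarter-width config that exercises the full graph cheaply."""
    return ModelConfig(
        alpha=0.25,
        beta=1.0,
        base_resolution=32,
        gadf_input_side=32,
        se_ratio=8,
        stat_dim_out=16,
        seed=5,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
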