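"""Shared fixtures: synthetic records and a fast micro model configuration."""

import numpy as np
import pytest

from csecg import ModelConfig, NoiseConfig, SyntheticConfig, synthesize_record


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free 30 s record at 60 bpm with analytic fiducials."""
    config = SyntheticConfig(
        seed=11, duration_s=30.0, mean_hr_bpm=60.0, hr_jitter=0.02,
        class_proportions=(1.0, 0.0, 0.0, 0.0, 0.0),
        noise=NoiseConfig(baseline_amp=0.0, powerline_amp=0.0,
                          white_sigma=0.0),
    )
    return synthesize_record(config)


@pytest.fixture(scope="session")
def noisy_record():
    """A mixed-class 60 s record with all three noise sources enabled."""
    config = SyntheticConfig(
        seed=5, duration_s=60.0, mean_hr_bpm=75.0,
        class_proportions=(0.7, 0.1, 0.12, 0.05, 0.03),
    )
    return synthesize_record(config)


@pytest.fixture()
def micro_model_config():
    """A tiny architecture so training-path tests stay fast."""
    return ModelConfig(
        conv_blocks=((4, 3, 0.0), (8, 3, 0.0)),
        transition_filters=((2, 2, 4),),
        pool_size=4, pool_stride=4,
        fc_units=8,
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
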