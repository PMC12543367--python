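"""Shared fixtures: small synthetic configurations used across test modules."""

import numpy as np
import pytest

from scoskit import synthetic as syn


def uniform_count_channels(mean_counts: float = 4000.0):
    """Default sensitivity profile but equal baseline brightness per channel."""
    return tuple(
        syn.ChannelSpec(
            c.sd_distance_cm, c.scalp_sensitivity, c.brain_sensitivity, mean_counts
        )
        for c in syn.default_channels()
    )


def noiseless_model() -> syn.NoiseModel:
    """Moment-exact speckle, no shot/read noise, no offset."""
    return syn.NoiseModel(
        read_sigma=0.0,
        dark_offset=0.0,
        conversion_factor=1.0,
        gain=1.0,
        shot_noise=False,
        speckle_sampling="deterministic",
    )


@pytest.fixture(scope="session")
def small_occlusion_config() -> syn.SyntheticCohortConfig:
    """Cheap default-noise occlusion cohort (small regions) for unit tests."""
    return syn.SyntheticCohortConfig(
        n_subjects=2, seed=42, region_shape=(24, 24), heart_rate_hz=(1.0, 1.15)
    )


@pytest.fixture(scope="session")
def small_occlusion_subject(small_occlusion_config):
    """One synthesized subject (stack, ground truth) shared across tests."""
    return syn.synthesize_frames(small_occlusion_config, 0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
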