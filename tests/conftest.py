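"""Shared fixtures.

Expensive artifacts (motor-babble pre-training) are session-scoped and built
once; tests that mutate a model take a copy.
"""

from __future__ import annotations

import pytest

from ofcarm import (ArmParameters, BabbleConfig, ExperimentConfig,
                    LearnerConfig, NoiseModel, create_learner,
                    generate_babble_data, seed_stream)

SEED = 1


@pytest.fixture(scope="session")
def params() -> ArmParameters:
    return ArmParameters().validate()


@pytest.fixture(scope="session")
def extended_noise() -> NoiseModel:
    return NoiseModel(kind="extended").validate()


@pytest.fixture(scope="session")
def standard_noise() -> NoiseModel:
    return NoiseModel(kind="standard").validate()


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseModel:
    return NoiseModel(kind="none").validate()


@pytest.fixture(scope="session")
def config() -> ExperimentConfig:
    return ExperimentConfig().validate()


@pytest.fixture(scope="session")
def small_babble(params, extended_noise):
    """A modest extended-SDN babble set for learner unit tests."""
    cfg = BabbleConfig(n_samples=12_000)
    rng = seed_stream(SEED, "test-babble")
    return generate_babble_data(params, extended_noise, cfg, rng)


@pytest.fixture(scope="session")
def trained_model(small_babble):
    model = create_learner(LearnerConfig())
    Z, Y = small_babble
    model.update_batch(Z, Y)
    return model


@pytest.fixture(scope="session")
def pretrained_extended(config):
    """Full-protocol extended-SDN pre-trained model (shared, copy to mutate)."""
    from ofcarm import pretrain_dynamics
    return pretrain_dynamics(config, "extended", SEED)


@pytest.fixture(scope="session")
def pretrained_standard(config):
    from ofcarm import pretrain_dynamics
    return pretrain_dynamics(config, "standard", SEED)
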