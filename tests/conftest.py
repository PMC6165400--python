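import numpy as np
import pytest

from enosecp import (
    FeatureMatrix,
    SimulationConfig,
    build_feature_matrix,
    make_class_profiles,
    simulate_dataset,
)


def scaled_dataset(n_classes, per_class, n_sensors, separation, seed, **sim_over):
    """Scaled-resolution synthetic dataset (10 Hz, 34 s records)."""
    sim = SimulationConfig(samples_per_class=per_class, seed=seed, **sim_over)
    profiles = make_class_profiles(
        n_classes, n_sensors, separation, seed=seed, timescale=sim.timescale
    )
    return simulate_dataset(profiles, sim)


def scaled_features(n_classes, per_class, n_sensors, separation, seed, **sim_over):
    return build_feature_matrix(
        scaled_dataset(n_classes, per_class, n_sensors, separation, seed, **sim_over)
    )


@pytest.fixture(scope="session")
def small_features() -> FeatureMatrix:
    """3 well-separated classes x 6 samples, 4 sensors: fast shared fixture."""
    return scaled_features(3, 6, 4, 1.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
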