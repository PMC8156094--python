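import numpy as np
import pytest

import tugfall as tf


@pytest.fixture(scope="session")
def default_params() -> tf.SimulationParams:
    return tf.SimulationParams(seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_params) -> tf.Cohort:
    """Ten-subject cohort shared by I/O / preprocessing / pipeline tests."""
    return tf.simulate_cohort(10, 0.5, default_params)


@pytest.fixture(scope="session")
def neck_gyro_segments(small_cohort):
    """Prepared (segments, features, labels) for the small cohort."""
    config = tf.ExperimentConfig(n_subjects=10, seed=11)
    return tf.prepare_segments(small_cohort, "neck", "gyro", config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
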