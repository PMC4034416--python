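import numpy as np
import pytest

import retinomeg as rm

# the standard desk-scale study geometry used across the suite: 120 labeled
# vertices per hemisphere (12 of them V3A) plus 48 unlabeled background
# vertices, chosen so every angular subregion and eccentricity band has
# exactly the same size (18 vertices per V1-V3 subregion, 12 per V3A side)
STD_GEOMETRY = {"n_v3a": 12, "n_background": 48}


@pytest.fixture(scope="session")
def space():
    return rm.build_source_space(120, 0.004, STD_GEOMETRY)


@pytest.fixture(scope="session")
def atlas(space):
    return rm.build_retinotopic_atlas(space)


@pytest.fixture(scope="session")
def sensors():
    return rm.build_sensor_array(60, 60)


@pytest.fixture(scope="session")
def leadfield(space, sensors):
    return rm.compute_lead_field(space, sensors)


@pytest.fixture(scope="session")
def quadrant_data(atlas, leadfield):
    """One simulated quadrant subject, 24 trials per stimulus."""
    return rm.simulate_subject(
        [(s, 24) for s in rm.quadrant_stimuli()], atlas, leadfield, seed=7,
    )


@pytest.fixture(scope="session")
def quadrant_filtered(quadrant_data):
    return rm.bandpass(quadrant_data, 1.0, 40.0)


@pytest.fixture(scope="session")
def noise_cov(quadrant_filtered):
    return rm.estimate_noise_covariance(quadrant_filtered, (-500.0, 0.0), 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
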