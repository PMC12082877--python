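import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoquant.simulate import CohortSimConfig, ImageSimConfig, generate_mito_image

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CELLS = [("male", "WT"), ("female", "WT"), ("male", "KO"), ("female", "KO")]


@pytest.fixture(scope="session")
def noiseless_config():
    """Small noiseless field of intact capsules."""
    return ImageSimConfig(
        field_size_px=(128, 128),
        n_objects=8,
        noise_poisson=False,
        noise_gaussian_sd=0.0,
        background_level=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_image(noiseless_config):
    return generate_mito_image(noiseless_config)


@pytest.fixture(scope="session")
def noisy_image():
    cfg = ImageSimConfig(field_size_px=(128, 128), n_objects=10, seed=7)
    return generate_mito_image(cfg)


@pytest.fixture
def balanced_cohort_config():
    """Equal animals per cell, equal neurons per animal, interior variance."""
    return CohortSimConfig(
        n_animals={c: 6 for c in CELLS},
        neurons_per_animal={c: 12 for c in CELLS},
        sd_animal={"aspect_ratio": 0.3, "m2": 0.05, "mito_count": 8.0},
        seed=2,
    )


def pearson_oracle(a, b):
    """Reference Pearson via numpy.corrcoef."""
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
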