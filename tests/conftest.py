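import logging

import pytest

from sahelcarbon import synthetic
from sahelcarbon.allometry import default_models

logging.getLogger("sahelcarbon").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def small_landscape():
    """A ~2,300-tree landscape spanning all four rainfall zones."""
    config = synthetic.LandscapeConfig(extent=(0.0, 0.0, 4000.0, 250.0), seed=42)
    rainfall, crowns = synthetic.gen_landscape(config)
    return config, rainfall, crowns


@pytest.fixture(scope="session")
def field_samples_default():
    return synthetic.gen_field_samples(synthetic.FieldSampleConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_samples():
    return synthetic.gen_field_samples(
        synthetic.FieldSampleConfig(noise_sigma=0.0, seed=7)
    )
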