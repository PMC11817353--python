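import numpy as np
import pytest

from coromix.ecg_io import LEAD_NAMES, ECGRecord
from coromix.synthetic import GeneratorConfig, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_record(rng):
    """A small random (but valid) 12-lead record."""
    leads = {name: rng.normal(0, 0.5, 250) for name in LEAD_NAMES}
    return ECGRecord(record_id="rand-1", fs=500.0, leads=leads, label="LAD",
                     meta={"age": "61"})


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free generator settings for deterministic morphology checks."""
    return GeneratorConfig(noise_sd_mv=0.0, baseline_wander_mv=0.0)


@pytest.fixture(scope="session")
def rca_record_clean(clean_config):
    return generate_record("RCA", clean_config, seed=1)


@pytest.fixture(scope="session")
def lad_record_clean(clean_config):
    return generate_record("LAD", clean_config, seed=1)
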