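import logging

import pytest

from mpclock import SimConfig


@pytest.fixture(autouse=True)
def _quiet_logging():
    logging.getLogger("mpclock").setLevel(logging.WARNING)


@pytest.fixture
def tiny_seq_config() -> SimConfig:
    """A small sequencing config for fast unit tests."""
    return SimConfig(n_loci=300, n_samples=3, coverage_mean=25.0, seed=7)


@pytest.fixture
def clean_seq_config() -> SimConfig:
    """Error-free chemistry: perfect conversion, no miscalls, no capture bias."""
    return SimConfig(
        n_loci=300,
        n_samples=3,
        conversion_efficiency=1.0,
        seq_error_rate=0.0,
        capture_bias=0.0,
        seed=11,
    )
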