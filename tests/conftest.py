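import pytest

from ddvcn import SimConfig, simulate_well

# Table of bulk VCN, adjusted VCN (2 d.p.) and flow transduction % for the
# six sorted CAR-T products used as reference inputs throughout the tests.
PRODUCT_TABLE = {
    "S1": (8.47, 8.47, 78.6),
    "S2": (2.23, 2.50, 52.3),
    "S3": (9.00, 9.00, 91.5),
    "S4": (0.57, 1.31, 27.2),
    "S5": (1.07, 1.63, 37.5),
    "S6": (2.97, 3.13, 66.2),
}


@pytest.fixture
def default_config():
    return SimConfig(wpre_conc=500.0, tert_conc=400.0, seed=20240)


@pytest.fixture
def default_well(default_config):
    return simulate_well(default_config)
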