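import numpy as np
import pandas as pd
import pytest

from nampod.synthetic import (FixtureConfig, generate_assay_table,
                              generate_downstream_tables, generate_universe)


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(n_chemicals=100, n_assays=20, seed=7)


@pytest.fixture(scope="session")
def universe(fixture_config):
    return generate_universe(fixture_config)


@pytest.fixture(scope="session")
def chemicals(universe):
    return universe[0]


@pytest.fixture(scope="session")
def fingerprints(universe):
    return universe[1]


@pytest.fixture(scope="session")
def assay_table(fixture_config, chemicals):
    return generate_assay_table(fixture_config, chemicals)


@pytest.fixture(scope="session")
def downstream_tables(fixture_config, chemicals):
    return generate_downstream_tables(fixture_config, chemicals)


def random_bit_pair(rng, length=64):
    return (rng.random(length) < 0.3).astype(np.uint8), (rng.random(length) < 0.3).astype(np.uint8)
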